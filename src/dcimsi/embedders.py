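"""t-SNE and UMAP wrappers with fixed MSI-appropriate configuration.

Both wrappers reduce a datacube's spectra to 3-D with cosine distance in the
input space — the convention that works best for MSI spectra. Only the two
hyperparameters that dominate embedding character are swept: t-SNE's
perplexity and exaggeration, and UMAP's neighbour count.

"Exaggeration" here is t-SNE's early-exaggeration factor (the multiplier on
attractive forces during the exploration phase). Sweeping it to large
values (hundreds) intentionally probes far outside its usual 4–12 range.

Embeddings can be cached to disk keyed by (cube content hash, parameters),
which makes grid searches resumable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .datacube import Embedding, MSIDataCube
from .errors import ValidationError

__all__ = ["TSNEParams", "UMAPParams", "run_tsne", "run_umap", "cube_hash"]


@dataclass
class TSNEParams:
    """t-SNE configuration: 3 components, cosine metric, random init,
    learning_rate='auto'; perplexity and exaggeration are the swept knobs.

    ``max_iter`` defaults to the library's 1000; the first 250 iterations
    are the exaggerated exploration phase.
    """

    perplexity: float = 30.0
    exaggeration: float = 12.0
    n_components: int = 3
    metric: str = "cosine"
    init: str = "random"
    learning_rate: str | float = "auto"
    seed: int = 0
    max_iter: int = 1000

    def validate(self, n_pixels: int) -> None:
        if self.perplexity <= 0:
            raise ValidationError("perplexity must be positive")
        if self.perplexity >= n_pixels:
            raise ValidationError(
                f"perplexity ({self.perplexity}) must be < n_pixels ({n_pixels})"
            )
        if self.exaggeration < 1:
            raise ValidationError("exaggeration must be >= 1")


@dataclass
class UMAPParams:
    """UMAP configuration: 3 components, cosine metric, spectral init;
    the neighbour count is the swept knob."""

    n_neighbours: int = 15
    n_components: int = 3
    metric: str = "cosine"
    init: str = "spectral"
    seed: int = 0

    def validate(self, n_pixels: int) -> None:
        if self.n_neighbours < 2:
            raise ValidationError("n_neighbours must be >= 2")
        if self.n_neighbours >= n_pixels:
            raise ValidationError(
                f"n_neighbours ({self.n_neighbours}) must be < n_pixels ({n_pixels})"
            )


def cube_hash(cube: MSIDataCube) -> str:
    """Content hash of a cube's arrays (for embedding cache keys)."""
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(cube.intensities).tobytes())
    h.update(np.ascontiguousarray(cube.mz_axis).tobytes())
    return h.hexdigest()[:16]


def _cache_path(cache_dir: Path, cube: MSIDataCube, algo: str, params) -> Path:
    key = json.dumps({"algo": algo, **asdict(params)}, sort_keys=True, default=str)
    digest = hashlib.sha1(key.encode()).hexdigest()[:16]
    return cache_dir / f"{algo}-{cube_hash(cube)}-{digest}.npz"


def _with_cache(cache_dir, cube, algo, params, compute):
    if cache_dir is None:
        return Embedding(compute(), params={"algorithm": algo, **asdict(params)})
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = _cache_path(cache_dir, cube, algo, params)
    if path.exists():
        with np.load(path) as data:
            coords = data["coordinates"]
    else:
        coords = compute()
        np.savez(path, coordinates=coords)
    return Embedding(coords, params={"algorithm": algo, **asdict(params)})


def run_tsne(
    cube: MSIDataCube, params: TSNEParams | None = None, cache_dir: str | Path | None = None
) -> Embedding:
    """Embed a cube's spectra with t-SNE; rows align with the cube."""
    from sklearn.manifold import TSNE

    params = params or TSNEParams()
    params.validate(cube.n_pixels)

    def compute() -> np.ndarray:
        tsne = TSNE(
            n_components=params.n_components,
            perplexity=params.perplexity,
            early_exaggeration=params.exaggeration,
            learning_rate=params.learning_rate,
            init=params.init,
            metric=params.metric,
            random_state=params.seed,
            max_iter=params.max_iter,
        )
        return np.asarray(tsne.fit_transform(cube.intensities), dtype=np.float64)

    return _with_cache(cache_dir, cube, "tsne", params, compute)


def run_umap(
    cube: MSIDataCube, params: UMAPParams | None = None, cache_dir: str | Path | None = None
) -> Embedding:
    """Embed a cube's spectra with UMAP; rows align with the cube."""
    import umap

    params = params or UMAPParams()
    params.validate(cube.n_pixels)

    def compute() -> np.ndarray:
        reducer = umap.UMAP(
            n_neighbors=params.n_neighbours,
            n_components=params.n_components,
            metric=params.metric,
            init=params.init,
            random_state=params.seed,
        )
        coords = reducer.fit_transform(cube.intensities)
        return np.asarray(coords, dtype=np.float64)

    return _with_cache(cache_dir, cube, "umap", params, compute)
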