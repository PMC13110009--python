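"""Rendering: 3-D embeddings as spatial RGB images, metric grids as heatmaps.

A 3-D embedding maps naturally onto color: dim1→R, dim2→G, dim3→B (fixed,
arbitrary). Each dimension is percentile-clipped (default 1st–99th) before
min–max scaling so a single anomalously embedded pixel cannot flatten the
dynamic range of the whole image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datacube import Embedding, MSIDataCube
from .errors import ValidationError

__all__ = ["RenderConfig", "embedding_to_rgb", "plot_metric_grid"]


@dataclass
class RenderConfig:
    clip_percentiles: tuple[float, float] = (1.0, 99.0)
    background: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        lo, hi = self.clip_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValidationError("clip percentiles must satisfy 0 <= low < high <= 100")


def embedding_to_rgb(
    embedding: Embedding, cube: MSIDataCube, cfg: RenderConfig | None = None
) -> np.ndarray:
    """Render a 3-D embedding on the cube's pixel grid as an RGB uint8 image.

    Returns an ``(height, width, 3)`` array; cells without a pixel get the
    background color. A constant dimension renders as mid-gray (0.5).
    """
    cfg = cfg or RenderConfig()
    if embedding.n_dims != 3:
        raise ValidationError(f"need a 3-D embedding, got {embedding.n_dims} dims")
    if embedding.n_points != cube.n_pixels:
        raise ValidationError("embedding rows must match cube pixels")
    lo_p, hi_p = cfg.clip_percentiles
    scaled = np.empty_like(embedding.coordinates)
    for j in range(3):
        col = embedding.coordinates[:, j]
        lo, hi = np.percentile(col, [lo_p, hi_p])
        col = np.clip(col, lo, hi)
        scaled[:, j] = 0.5 if hi == lo else (col - lo) / (hi - lo)
    width, height = cube.mask_shape
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = np.asarray(cfg.background, dtype=np.uint8)
    x, y = cube.coords[:, 0], cube.coords[:, 1]
    img[y, x] = np.round(scaled * 255).astype(np.uint8)
    return img


def save_rgb(img: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(img, mode="RGB").save(path)


def plot_metric_grid(table, value_col: str = "dci", ax=None, log_axes: bool = True):
    """Heatmap of a metric over the perplexity × exaggeration grid.

    ``table`` is the tidy frame from :func:`dcimsi.optimize.grid_search`.
    Axes are log-scaled (hyperparameter sweeps span decades); missing cells
    (NaN) are drawn in a distinct hatch color.
    """
    import matplotlib.pyplot as plt

    if len(table) == 0:
        raise ValidationError("empty score table")
    pivot = table.pivot_table(index="exaggeration", columns="perplexity", values=value_col,
                              dropna=False)
    if ax is None:
        _, ax = plt.subplots()
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgray")
    x = pivot.columns.to_numpy(dtype=float)
    y = pivot.index.to_numpy(dtype=float)
    mesh = ax.pcolormesh(
        _edges(x, log_axes), _edges(y, log_axes),
        np.ma.masked_invalid(pivot.to_numpy(dtype=float)), cmap=cmap, shading="flat",
    )
    if log_axes:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("perplexity")
    ax.set_ylabel("exaggeration")
    ax.figure.colorbar(mesh, ax=ax, label=value_col)
    return ax


def plot_convergence(trace, window: int = 5, ax=None):
    """Per-iteration objective scores with a sliding-window moving average."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scores = trace.records["score"]
    ax.plot(scores.index + 1, scores, ".", alpha=0.6, label="iteration score")
    ax.plot(scores.index + 1, trace.moving_average(window), "-",
            label=f"moving average (window {window})")
    ax.set_xlabel("iteration")
    ax.set_ylabel("DCI")
    ax.legend()
    return ax


def _edges(centers: np.ndarray, log: bool) -> np.ndarray:
    c = np.log(centers) if log else centers.astype(float)
    if c.size == 1:
        e = np.array([c[0] - 0.5, c[0] + 0.5])
    else:
        mid = (c[:-1] + c[1:]) / 2
        e = np.concatenate([[c[0] - (mid[0] - c[0])], mid, [c[-1] + (c[-1] - mid[-1])]])
    return np.exp(e) if log else e
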