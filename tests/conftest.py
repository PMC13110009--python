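"""Shared fixtures.

The expensive session fixtures (the desk-scale synthetic cube and its t-SNE
grid) are computed once and shared: the grid is the basis for every trend
assertion, so all trend tests see the same embeddings.
"""

from __future__ import annotations

import numpy as np
import pytest

from dcimsi import DCIParams, SyntheticSpec, make_cube
from dcimsi.optimize import grid_search

#: desk-scale study conditions: ~1900 px, 150 channels, 8 regions, 10% CV
DESK_SPEC = SyntheticSpec(grid=(64, 42), n_regions=8, species_per_region=2,
                          n_matrix_peaks=6, noise_cv=0.10, seed=7)

GRID_PERPLEXITIES = [5, 30, 200, 600]
GRID_EXAGGERATIONS = [1, 12, 100]
GRID_SEEDS = [0, 1, 2]
TSNE_MAX_ITER = 500


@pytest.fixture(scope="session")
def desk_cube():
    return make_cube(DESK_SPEC)


@pytest.fixture(scope="session")
def tiny_cube():
    """A fast ~300-pixel cube for contract tests."""
    spec = SyntheticSpec(grid=(24, 18), n_regions=4, species_per_region=2,
                         n_matrix_peaks=4, noise_cv=0.1, seed=3)
    return make_cube(spec)


@pytest.fixture(scope="session")
def grid_cache_dir(tmp_path_factory):
    """One shared embedding cache so trend tests reuse the grid's t-SNE runs."""
    return tmp_path_factory.mktemp("emb_cache")


@pytest.fixture(scope="session")
def tsne_grid(desk_cube, grid_cache_dir):
    """DCI score tables for the perplexity × exaggeration grid, one per seed."""
    cache = grid_cache_dir
    tables = {}
    for seed in GRID_SEEDS:
        tables[seed] = grid_search(
            desk_cube,
            GRID_PERPLEXITIES,
            GRID_EXAGGERATIONS,
            DCIParams(kmeans_seed=seed),
            tsne_seed=seed,
            cache_dir=cache,
            max_iter=TSNE_MAX_ITER,
        )
    return tables


def random_points(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    """Generic positive point cloud (safe under cosine)."""
    return rng.uniform(0.1, 2.0, size=(n, d))
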