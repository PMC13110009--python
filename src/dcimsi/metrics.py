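"""Comparator metrics for embedding quality.

Five established metrics to benchmark against DCI: two unsupervised local /
global structure scores (co-k-nearest-neighbour accuracy, random-triplet
accuracy), the Spearman rank correlation of pairwise distances, and two
label-requiring scores (centroid-distance correlation and the mean-based
Dunn index). Distance conventions mirror DCI: cosine in the high-dimensional
space, Euclidean in the low-dimensional space (both overridable for
identity checks).

Tie handling is deterministic and standard: neighbour ties broken by index,
tied triplet comparisons score 0.5, Spearman uses average ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "MetricConfig",
    "knn_accuracy",
    "random_triplet_accuracy",
    "spearman_pairwise",
    "centroid_distance_correlation",
    "mean_dunn_index",
]


@dataclass
class MetricConfig:
    """Shared configuration of the comparator metrics.

    ``subsample`` may carry the index set used by a DCI run so all metrics
    are computed over the same points (and O(n²) cost stays bounded).
    """

    knn_k: int = 10
    triplets_per_point: int = 5
    triplet_seed: int = 0
    subsample: np.ndarray | None = None
    high_metric: str = "cosine"
    low_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.triplets_per_point < 1:
            raise ValidationError("triplets_per_point must be >= 1")


def _maybe_subsample(cfg: MetricConfig, *arrays: np.ndarray):
    if cfg.subsample is None:
        return arrays
    idx = np.asarray(cfg.subsample, dtype=np.int64)
    return tuple(a[idx] for a in arrays)


def _square_distances(points: np.ndarray, metric: str) -> np.ndarray:
    return squareform(pdist(np.asarray(points, dtype=np.float64), metric=metric))


# ---------------------------------------------------------------------------

def knn_accuracy(high: np.ndarray, low: np.ndarray, cfg: MetricConfig | None = None) -> float:
    """Co-k-nearest-neighbour accuracy: local structure preservation.

    For every point, the fraction of its k nearest neighbours (self
    excluded) shared between the two spaces, averaged over points.
    Distance ties are broken by index (stable argsort).
    """
    cfg = cfg or MetricConfig()
    high, low = _maybe_subsample(cfg, np.asarray(high), np.asarray(low))
    n = high.shape[0]
    if low.shape[0] != n:
        raise ValidationError("high and low must be row-aligned")
    if n <= cfg.knn_k:
        raise ValidationError(f"need n > knn_k ({cfg.knn_k}), got n={n}")
    dh = _square_distances(high, cfg.high_metric)
    dl = _square_distances(low, cfg.low_metric)
    np.fill_diagonal(dh, np.inf)
    np.fill_diagonal(dl, np.inf)
    nh = np.argsort(dh, axis=1, kind="stable")[:, : cfg.knn_k]
    nl = np.argsort(dl, axis=1, kind="stable")[:, : cfg.knn_k]
    overlap = [
        len(set(nh[i].tolist()) & set(nl[i].tolist())) / cfg.knn_k for i in range(n)
    ]
    return float(np.mean(overlap))


def random_triplet_accuracy(
    high: np.ndarray, low: np.ndarray, cfg: MetricConfig | None = None
) -> float:
    """Random-triplet accuracy: global relative-order preservation.

    For seeded random triplets (i, j, l) — ``triplets_per_point`` per
    anchor i — score 1 if sign(d_high(i,j) − d_high(i,l)) matches
    sign(d_low(i,j) − d_low(i,l)), 0.5 if either sign is zero, else 0.
    """
    cfg = cfg or MetricConfig()
    high, low = _maybe_subsample(cfg, np.asarray(high), np.asarray(low))
    n = high.shape[0]
    if low.shape[0] != n:
        raise ValidationError("high and low must be row-aligned")
    if n < 3:
        raise ValidationError("need at least 3 points for triplets")
    dh = _square_distances(high, cfg.high_metric)
    dl = _square_distances(low, cfg.low_metric)
    rng = np.random.default_rng(cfg.triplet_seed)
    scores = []
    for i in range(n):
        others = np.delete(np.arange(n), i)
        for _ in range(cfg.triplets_per_point):
            j, l = rng.choice(others, size=2, replace=False)
            sh = np.sign(dh[i, j] - dh[i, l])
            sl = np.sign(dl[i, j] - dl[i, l])
            scores.append(1.0 if (sh == sl and sh != 0) else (0.5 if (sh == 0 or sl == 0) else 0.0))
    return float(np.mean(scores))


def spearman_pairwise(
    high: np.ndarray, low: np.ndarray, cfg: MetricConfig | None = None
) -> float:
    """Spearman rank correlation between the condensed distance vectors."""
    cfg = cfg or MetricConfig()
    high, low = _maybe_subsample(cfg, np.asarray(high), np.asarray(low))
    n = high.shape[0]
    if low.shape[0] != n:
        raise ValidationError("high and low must be row-aligned")
    if n < 3:
        raise ValidationError("need at least 3 points (3 pairs)")
    dh = pdist(np.asarray(high, dtype=np.float64), metric=cfg.high_metric)
    dl = pdist(np.asarray(low, dtype=np.float64), metric=cfg.low_metric)
    if _effectively_constant(dh) or _effectively_constant(dl):
        raise DegenerateInputError("constant distance vector: Spearman undefined")
    rho = spearmanr(dh, dl).statistic
    return float(rho)


def _effectively_constant(d: np.ndarray) -> bool:
    # constant up to float rounding (e.g. an equilateral point set)
    return np.ptp(d) <= 1e-12 * max(1.0, float(np.max(np.abs(d)))) if d.size else True


def centroid_distance_correlation(
    high: np.ndarray,
    low: np.ndarray,
    labels: np.ndarray,
    cfg: MetricConfig | None = None,
) -> float:
    """Spearman correlation of inter-centroid distances across spaces.

    Per-class arithmetic-mean centroids are formed in each space; the
    correlation is between their condensed distance vectors (cosine high /
    Euclidean low by default). Requires ≥ 3 classes; ≥ 4 recommended for a
    meaningful rank correlation.
    """
    cfg = cfg or MetricConfig()
    high, low, labels = _maybe_subsample(cfg, np.asarray(high), np.asarray(low), np.asarray(labels))
    classes = np.unique(labels)
    if classes.size < 3:
        raise ValidationError(f"need >= 3 classes, got {classes.size}")
    ch = np.vstack([high[labels == c].mean(axis=0) for c in classes])
    cl = np.vstack([low[labels == c].mean(axis=0) for c in classes])
    dh = pdist(ch, metric=cfg.high_metric)
    dl = pdist(cl, metric=cfg.low_metric)
    if _effectively_constant(dh) or _effectively_constant(dl):
        raise DegenerateInputError("constant centroid distances: correlation undefined")
    return float(spearmanr(dh, dl).statistic)


def mean_dunn_index(
    low: np.ndarray, labels: np.ndarray, cfg: MetricConfig | None = None
) -> float:
    """Mean-based Dunn index: mean inter- over mean intra-cluster distance.

    Euclidean distances in the (low-dimensional) space; values > 1 indicate
    separated clusters. Singleton classes have no intra pairs and raise;
    coincident within-cluster points give a zero intra mean and raise.
    """
    cfg = cfg or MetricConfig()
    (low, labels) = _maybe_subsample(cfg, np.asarray(low), np.asarray(labels))
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("need >= 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise DegenerateInputError(f"class {c!r} is a singleton; intra-class mean undefined")
    D = _square_distances(low, "euclidean")
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    intra = D[iu][same[iu]]
    inter = D[iu][~same[iu]]
    intra_mean = float(intra.mean())
    if intra_mean == 0.0:
        raise DegenerateInputError("intra-cluster mean distance is zero; ratio undefined")
    return float(inter.mean()) / intra_mean
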