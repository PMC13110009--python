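"""Dimensional Cophenetic Integrity (DCI).

DCI scores how well a low-dimensional embedding preserves the hierarchical
cluster relationships of its high-dimensional source. The pipeline:

1. **Sampling** — k-means (k = n × ``sample_fraction``, default 1%) on the
   *low-dimensional* space; the pixel nearest each centroid becomes a
   representative. Sampling in the embedding keeps the subset spread over
   whatever structure the embedding actually shows.
2. **Dual hierarchical clustering** — pairwise distances over the sampled
   points: cosine in the high-dimensional datacube, Euclidean in the
   embedding; average linkage (UPGMA) in each space.
3. **Cophenetic distances** — for every sampled pair, the height of the
   lowest dendrogram merge that unites them, in each space.
4. **Normalized mutual information** — each condensed cophenetic vector is
   treated as a categorical labelling (distinct merge heights are distinct
   categories; heights are replicated bit-exactly within one dendrogram, so
   exact-value equality needs no binning) and compared with arithmetic-mean
   NMI, giving a score in [0, 1].

A score of 1 means the two dendrograms induce identical pair partitions —
cluster relationships are fully preserved; 0 means the partitions are
independent. The score is invariant under isometries of the embedding and
under any strictly increasing transform of either cophenetic vector.

Degenerate-embedding conventions (documented because constant or collapsed
embeddings occur in practice): both cophenetic vectors constant → 1.0;
exactly one constant → 0.0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

from .datacube import Embedding, MSIDataCube
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "DCIParams",
    "DCIResult",
    "sample_representatives",
    "condensed_pairwise",
    "average_linkage",
    "cophenetic_distances",
    "normalized_mutual_information",
    "dci",
]


@dataclass
class DCIParams:
    """Tunables of the DCI pipeline.

    ``sample_fraction`` defaults to 0.01 (k = n/100); fractions between
    0.5% and 25% give very similar scores, so 1% is used for speed.
    ``high_metric``/``low_metric`` default to cosine/Euclidean; the
    overrides exist mainly so identity checks can use one metric in both
    spaces.
    """

    sample_fraction: float = 0.01
    high_metric: str = "cosine"
    low_metric: str = "euclidean"
    linkage_method: str = "average"
    kmeans_seed: int = 0
    min_samples: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValidationError("sample_fraction must be in (0, 1]")
        if self.min_samples < 2:
            raise ValidationError("min_samples must be >= 2")


@dataclass
class DCIResult:
    """A DCI score plus full provenance."""

    score: float
    sample_indices: np.ndarray
    coph_high: np.ndarray
    coph_low: np.ndarray
    params: DCIParams

    def to_json(self) -> str:
        return json.dumps(
            {
                "score": self.score,
                "sample_indices": self.sample_indices.tolist(),
                "coph_high": self.coph_high.tolist(),
                "coph_low": self.coph_low.tolist(),
                "params": self.params.__dict__,
            }
        )

    def coph_matrix(self, space: str = "high") -> np.ndarray:
        """Square cophenetic matrix for inspection/export."""
        vec = self.coph_high if space == "high" else self.coph_low
        return squareform(vec)


# ---------------------------------------------------------------------------
# Stage 1: representative sampling
# ---------------------------------------------------------------------------

def sample_representatives(embedding: Embedding, params: DCIParams) -> np.ndarray:
    """Pick ~n·fraction representative pixels via k-means on the embedding.

    k-means (k-means++ init, 10 restarts, seeded) clusters the embedding;
    for each centroid the Euclidean-nearest point is taken (ties by lowest
    index). Two centroids can claim the same point; duplicates are removed,
    so the returned count may be smaller than k.
    """
    n = embedding.n_points
    if n < params.min_samples:
        raise ValidationError(
            f"need at least min_samples={params.min_samples} points, got {n}"
        )
    k = max(params.min_samples, int(round(n * params.sample_fraction)))
    k = min(k, n)
    X = embedding.coordinates
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=params.kmeans_seed)
    with warnings.catch_warnings():
        # duplicate embedding points can collapse centroids; handled below
        warnings.simplefilter("ignore")
        km.fit(X)
    reps = []
    for c in km.cluster_centers_:
        d2 = ((X - c) ** 2).sum(axis=1)
        reps.append(int(np.argmin(d2)))  # argmin ties -> lowest index
    # dedupe preserving order
    seen: set[int] = set()
    out = [i for i in reps if not (i in seen or seen.add(i))]
    return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# Stage 2: condensed pairwise distances and average linkage
# ---------------------------------------------------------------------------

def condensed_pairwise(points: np.ndarray, metric: str) -> np.ndarray:
    """Condensed (i < j lexicographic) pairwise distance vector.

    Cosine distance is ``1 − u·v/(|u||v|)``; rows of zero norm are
    meaningless under cosine and raise :class:`DegenerateInputError`.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValidationError("need a 2-D array of at least two points")
    if metric == "cosine":
        norms = np.linalg.norm(points, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise DegenerateInputError(
                f"row(s) {bad.tolist()} have zero norm; cosine distance is "
                "undefined (apply ROI filtering to drop empty spectra)"
            )
    d = pdist(points, metric=metric)
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite pairwise distances")
    # cosine can go infinitesimally negative through rounding
    return np.maximum(d, 0.0)


def average_linkage(d: np.ndarray) -> np.ndarray:
    """UPGMA agglomeration of a condensed distance vector.

    Returns the standard ``(m−1, 4)`` linkage matrix ``[a, b, height,
    size]``. At each step the two clusters with minimal mean inter-cluster
    distance merge at that mean; average linkage is monotone, so heights are
    verified non-decreasing.
    """
    d = np.asarray(d, dtype=np.float64)
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite distances in condensed vector")
    Z = linkage(d, method="average")
    heights = Z[:, 2]
    if np.any(np.diff(heights) < -1e-12):
        raise ValidationError("average-linkage heights are not non-decreasing")
    return Z


def cophenetic_distances(tree: np.ndarray) -> np.ndarray:
    """Condensed cophenetic vector of a linkage matrix.

    Entry (i, j) is the height of the lowest merge uniting leaves i and j.
    """
    tree = np.asarray(tree, dtype=np.float64)
    if tree.ndim != 2 or tree.shape[1] != 4:
        raise ValidationError("expected an (m-1, 4) linkage matrix")
    if tree.shape[0] == 0:
        raise ValidationError("linkage over fewer than two leaves")
    return cophenet(tree)


# ---------------------------------------------------------------------------
# Stage 4: NMI over cophenetic structure
# ---------------------------------------------------------------------------

def _labels_from_values(vec: np.ndarray) -> np.ndarray:
    """Categorical labels by exact value equality."""
    _, inv = np.unique(np.asarray(vec, dtype=np.float64), return_inverse=True)
    return inv


def normalized_mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Arithmetic-mean NMI between two condensed cophenetic vectors.

    Each distinct value is one category. Conventions for zero-entropy
    vectors: both constant → 1.0 (identical trivial partitions); exactly
    one constant → 0.0 (no shared information).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("cophenetic vectors must be 1-D and of equal length")
    la, lb = _labels_from_values(a), _labels_from_values(b)
    na, nb = la.max() + 1, lb.max() + 1
    if na == 1 and nb == 1:
        return 1.0
    if na == 1 or nb == 1:
        return 0.0
    return float(normalized_mutual_info_score(la, lb, average_method="arithmetic"))


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------

def dci(
    cube: MSIDataCube,
    embedding: Embedding,
    params: DCIParams | None = None,
    sample_indices: np.ndarray | None = None,
) -> DCIResult:
    """Dimensional Cophenetic Integrity of ``embedding`` w.r.t. ``cube``.

    ``sample_indices`` may be supplied to hold the sampled subset fixed
    across embeddings (e.g. for invariance checks or fair comparisons);
    by default representatives are re-sampled from this embedding.
    """
    params = params or DCIParams()
    if embedding.n_points != cube.n_pixels:
        raise ValidationError(
            f"embedding rows ({embedding.n_points}) != cube pixels ({cube.n_pixels})"
        )
    if sample_indices is None:
        idx = sample_representatives(embedding, params)
        if idx.size < params.min_samples:
            # centroid collapse (e.g. constant embedding): top the sample
            # back up with the lowest unused pixel indices so the low-space
            # structure is still computable (it will be degenerate/constant)
            extra = [i for i in range(cube.n_pixels) if i not in set(idx.tolist())]
            idx = np.concatenate(
                [idx, np.asarray(extra[: params.min_samples - idx.size], dtype=np.int64)]
            )
    else:
        idx = np.asarray(sample_indices, dtype=np.int64)
        if idx.size < 2:
            raise ValidationError("need at least two sample indices")

    high = cube.intensities[idx]
    low = embedding.coordinates[idx]
    d_high = condensed_pairwise(high, params.high_metric)
    d_low = condensed_pairwise(low, params.low_metric)
    coph_high = cophenetic_distances(average_linkage(d_high))
    coph_low = cophenetic_distances(average_linkage(d_low))
    score = normalized_mutual_information(coph_high, coph_low)
    return DCIResult(
        score=score,
        sample_indices=idx,
        coph_high=coph_high,
        coph_low=coph_low,
        params=params,
    )
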