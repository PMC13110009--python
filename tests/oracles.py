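"""Independent brute-force oracles used to verify the fast implementations.

These deliberately share no code with the package: cophenetic distances are
recovered by replaying the merge sequence with explicit leaf sets, and the
neighbour/triplet scores by exhaustive enumeration over square distance
matrices computed by hand.
"""

from __future__ import annotations

import itertools

import numpy as np


def cophenetic_by_traversal(Z: np.ndarray) -> np.ndarray:
    """Replay a linkage matrix, recording the first-union height per pair.

    Cluster ids follow the scipy convention: leaves 0..m-1, the i-th merge
    creates cluster m+i. Returns the condensed (i<j lexicographic) vector.
    """
    m = Z.shape[0] + 1
    members: dict[int, list[int]] = {i: [i] for i in range(m)}
    coph = np.full((m, m), np.nan)
    for step, (a, b, height, _size) in enumerate(Z):
        left, right = members.pop(int(a)), members.pop(int(b))
        for i in left:
            for j in right:
                coph[min(i, j), max(i, j)] = height
        members[m + step] = left + right
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            out.append(coph[i, j])
    assert not np.any(np.isnan(out))
    return np.asarray(out)


def average_linkage_naive(d_condensed: np.ndarray, m: int) -> np.ndarray:
    """Quadratic UPGMA: repeatedly merge the pair with minimal mean distance.

    Ties broken by the smallest (a, b) cluster-id pair. Returns a scipy-style
    linkage matrix.
    """
    D = np.zeros((m, m))
    iu = np.triu_indices(m, 1)
    D[iu] = d_condensed
    D += D.T
    clusters: dict[int, list[int]] = {i: [i] for i in range(m)}
    Z = []
    next_id = m
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for a, b in itertools.combinations(ids, 2):
            mean_d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or mean_d < best[0] - 1e-15:
                best = (mean_d, a, b)
        mean_d, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = merged
        Z.append([a, b, mean_d, len(merged)])
        next_id += 1
    return np.asarray(Z)


def knn_accuracy_naive(dh: np.ndarray, dl: np.ndarray, k: int) -> float:
    """Exhaustive co-k-NN over two square distance matrices (ties by index)."""
    n = dh.shape[0]
    scores = []
    for i in range(n):
        order_h = sorted((dh[i, j], j) for j in range(n) if j != i)
        order_l = sorted((dl[i, j], j) for j in range(n) if j != i)
        nh = {j for _, j in order_h[:k]}
        nl = {j for _, j in order_l[:k]}
        scores.append(len(nh & nl) / k)
    return float(np.mean(scores))


def triplet_scores_all(dh: np.ndarray, dl: np.ndarray) -> float:
    """Mean triplet agreement over every anchored triplet (i, j, l), j != l."""
    n = dh.shape[0]
    scores = []
    for i in range(n):
        for j in range(n):
            for l in range(n):
                if len({i, j, l}) != 3:
                    continue
                sh = np.sign(dh[i, j] - dh[i, l])
                sl = np.sign(dl[i, j] - dl[i, l])
                if sh == 0 or sl == 0:
                    scores.append(0.5)
                else:
                    scores.append(1.0 if sh == sl else 0.0)
    return float(np.mean(scores))
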