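"""Hyperparameter search with DCI as the objective.

Two strategies over the t-SNE (perplexity, exaggeration) plane:

* :func:`grid_search` — exhaustive evaluation of a small grid, with
  embeddings cached so a grid can be extended or re-plotted cheaply;
* :func:`bayes_optimize` — sequential model-based optimization: a Gaussian-
  process surrogate (Matérn 5/2 kernel) over the integer box, expected-
  improvement acquisition, Sobol quasi-random initial design. DCI is
  maximized by minimizing −DCI.

Failed objective evaluations (e.g. an invalid parameter combination) are
recorded — as a missing grid cell with a reason, or as the worst observed
value in the Bayesian trace — rather than aborting the whole search.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .datacube import MSIDataCube
from .dci import DCIParams, dci
from .embedders import TSNEParams, run_tsne
from .errors import ValidationError

__all__ = ["SearchSpace", "OptimizationTrace", "grid_search", "bayes_optimize"]


@dataclass
class SearchSpace:
    """Integer box for Bayesian optimization of t-SNE hyperparameters.

    Defaults follow the proof-of-concept configuration: perplexity in
    [5, 10000], exaggeration in [1, 1000], 120 calls with 60 initial
    points, seed 42. The perplexity upper bound is clipped below the pixel
    count at run time.
    """

    perplexity_range: tuple[int, int] = (5, 10000)
    exaggeration_range: tuple[int, int] = (1, 1000)
    n_calls: int = 120
    n_initial_points: int = 60
    seed: int = 42

    def __post_init__(self) -> None:
        if self.perplexity_range[0] > self.perplexity_range[1]:
            raise ValidationError("empty perplexity range")
        if self.exaggeration_range[0] > self.exaggeration_range[1]:
            raise ValidationError("empty exaggeration range")
        if not 1 <= self.n_initial_points <= self.n_calls:
            raise ValidationError("need 1 <= n_initial_points <= n_calls")


@dataclass
class OptimizationTrace:
    """Per-iteration record of a Bayesian optimization run."""

    records: pd.DataFrame  # columns: perplexity, exaggeration, score, wall_time, failed
    best_params: dict
    best_score: float

    def to_json(self) -> str:
        return self.records.assign(best_score=self.best_score).to_json(orient="records")

    def moving_average(self, window: int = 5) -> pd.Series:
        """Sliding-window mean of the per-iteration scores (convergence plot)."""
        return self.records["score"].rolling(window, min_periods=1).mean()


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def grid_search(
    cube: MSIDataCube,
    perplexities: Sequence[float],
    exaggerations: Sequence[float],
    dci_params: DCIParams | None = None,
    tsne_seed: int = 0,
    cache_dir: str | Path | None = None,
    max_iter: int = 1000,
    extra_metrics: dict[str, Callable] | None = None,
) -> pd.DataFrame:
    """DCI over a perplexity × exaggeration grid of t-SNE embeddings.

    Returns a tidy DataFrame with one row per cell (columns ``perplexity``,
    ``exaggeration``, ``dci``, ``error`` plus any ``extra_metrics``, which
    are called as ``f(cube, embedding)``). Invalid cells get ``dci = NaN``
    and the failure reason; they do not abort the grid.
    """
    if len(perplexities) == 0 or len(exaggerations) == 0:
        raise ValidationError("perplexity and exaggeration lists must be non-empty")
    dci_params = dci_params or DCIParams()
    rows = []
    for p in perplexities:
        for e in exaggerations:
            row: dict = {"perplexity": p, "exaggeration": e, "dci": np.nan, "error": ""}
            try:
                emb = run_tsne(
                    cube,
                    TSNEParams(perplexity=p, exaggeration=e, seed=tsne_seed, max_iter=max_iter),
                    cache_dir=cache_dir,
                )
                row["dci"] = dci(cube, emb, dci_params).score
                for name, f in (extra_metrics or {}).items():
                    row[name] = f(cube, emb)
            except Exception as exc:  # recorded, not raised
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian optimization (GP + expected improvement)
# ---------------------------------------------------------------------------

def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float, xi: float = 0.01):
    """EI for minimization: improvement below the incumbent ``best``."""
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu - xi) / sigma
    return (best - mu - xi) * norm.cdf(z) + sigma * norm.pdf(z)


def bayes_optimize(
    cube: MSIDataCube | None,
    space: SearchSpace,
    dci_params: DCIParams | None = None,
    objective: Callable[[int, int], float] | None = None,
    cache_dir: str | Path | None = None,
    max_iter: int = 1000,
    n_candidates: int = 2048,
) -> OptimizationTrace:
    """Maximize DCI (or a custom ``objective(perplexity, exaggeration)``)
    over the integer search box.

    The first ``n_initial_points`` evaluations are a Sobol quasi-random
    design; afterwards a Matérn-5/2 GP is refit each iteration on the
    observed points (scaled to the unit square) and the next point is the
    expected-improvement argmax over a random candidate set, never repeating
    an evaluated point. Failed evaluations are recorded with the worst
    observed score and excluded from ``best``.
    """
    dci_params = dci_params or DCIParams()
    if objective is None:
        if cube is None:
            raise ValidationError("either a cube or an explicit objective is required")

        p_hi = min(space.perplexity_range[1], cube.n_pixels - 1)
        lo, hi = space.perplexity_range[0], p_hi

        def objective(p: int, e: int) -> float:
            emb = run_tsne(
                cube,
                TSNEParams(perplexity=p, exaggeration=e, seed=space.seed, max_iter=max_iter),
                cache_dir=cache_dir,
            )
            return dci(cube, emb, dci_params).score
    else:
        lo, hi = space.perplexity_range
    e_lo, e_hi = space.exaggeration_range
    if lo > hi:
        raise ValidationError("perplexity range collapsed below its lower bound")

    rng = np.random.default_rng(space.seed)
    sobol = qmc.Sobol(d=2, scramble=True, rng=rng)
    n_init = min(space.n_initial_points, space.n_calls)
    with warnings.catch_warnings():
        # balance of the Sobol design is irrelevant for a seeding scatter
        warnings.simplefilter("ignore", UserWarning)
        unit = sobol.random(n_init)
    init_pts = np.column_stack(
        [
            np.clip(np.floor(lo + unit[:, 0] * (hi - lo + 1)), lo, hi),
            np.clip(np.floor(e_lo + unit[:, 1] * (e_hi - e_lo + 1)), e_lo, e_hi),
        ]
    ).astype(int)

    def to_unit(X: np.ndarray) -> np.ndarray:
        out = np.empty_like(X, dtype=float)
        out[:, 0] = (X[:, 0] - lo) / max(hi - lo, 1)
        out[:, 1] = (X[:, 1] - e_lo) / max(e_hi - e_lo, 1)
        return out

    evaluated: set[tuple[int, int]] = set()
    X_obs: list[tuple[int, int]] = []
    y_obs: list[float] = []  # -score (minimization)
    records = []

    kernel = ConstantKernel(1.0) * Matern(length_scale=[0.3, 0.3], nu=2.5) + WhiteKernel(1e-6)

    def evaluate(p: int, e: int) -> None:
        t0 = time.time()
        failed = False
        try:
            score = float(objective(int(p), int(e)))
        except Exception as exc:
            failed = True
            score = np.nan
            reason = f"{type(exc).__name__}: {exc}"
        else:
            reason = ""
        wall = time.time() - t0
        evaluated.add((int(p), int(e)))
        if failed:
            finite = [v for v in y_obs]
            y = max(finite) if finite else 0.0  # worst observed; placeholder for the GP
        else:
            y = -score
        X_obs.append((int(p), int(e)))
        y_obs.append(y)
        records.append(
            {
                "perplexity": int(p),
                "exaggeration": int(e),
                "score": score,
                "wall_time": wall,
                "failed": failed,
                "error": reason,
            }
        )

    for p, e in init_pts:
        if (int(p), int(e)) in evaluated:
            p, e = _fresh_point(rng, lo, hi, e_lo, e_hi, evaluated)
        evaluate(p, e)

    n_total_cells = (hi - lo + 1) * (e_hi - e_lo + 1)
    for _ in range(space.n_calls - n_init):
        if len(evaluated) >= n_total_cells:
            break
        X = to_unit(np.asarray(X_obs, dtype=float))
        y = np.asarray(y_obs, dtype=float)
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, alpha=1e-8,
                                      n_restarts_optimizer=1, random_state=space.seed)
        try:
            with warnings.catch_warnings():
                # kernel hyperparameter fits hitting their bounds are routine
                # on small designs and do not affect the acquisition argmax
                warnings.simplefilter("ignore")
                gp.fit(X, y)
            cand = np.column_stack(
                [rng.integers(lo, hi + 1, n_candidates), rng.integers(e_lo, e_hi + 1, n_candidates)]
            )
            mu, sigma = gp.predict(to_unit(cand.astype(float)), return_std=True)
            ei = _expected_improvement(mu, sigma, best=float(np.min(y)))
            for idx in np.argsort(-ei):
                p, e = int(cand[idx, 0]), int(cand[idx, 1])
                if (p, e) not in evaluated:
                    break
            else:
                p, e = _fresh_point(rng, lo, hi, e_lo, e_hi, evaluated)
        except Exception:
            p, e = _fresh_point(rng, lo, hi, e_lo, e_hi, evaluated)
        evaluate(p, e)

    df = pd.DataFrame(records)
    ok = df[~df["failed"]]
    if ok.empty:
        raise RuntimeError("every objective evaluation failed")
    best_row = ok.loc[ok["score"].idxmax()]
    return OptimizationTrace(
        records=df,
        best_params={
            "perplexity": int(best_row["perplexity"]),
            "exaggeration": int(best_row["exaggeration"]),
        },
        best_score=float(best_row["score"]),
    )


def _fresh_point(rng, lo, hi, e_lo, e_hi, evaluated):
    for _ in range(10000):
        p = int(rng.integers(lo, hi + 1))
        e = int(rng.integers(e_lo, e_hi + 1))
        if (p, e) not in evaluated:
            return p, e
    raise RuntimeError("search space exhausted")
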