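"""Hyperparameter search: exhaustive grid plus GP-MI Bayesian optimization.

The search strategy mirrors how these models are tuned in practice: most
axes (latent dimension, Laplacian weights, learning rate, rescoring
parameters) take a handful of log2-spaced candidate values and are swept
exhaustively, while the two prior precisions -- tied together,
``lambda_d = lambda_t`` -- and the drug Laplacian weight ``alpha`` are
optimized on each fixed-axes slice by Gaussian-process Bayesian
optimization with the mutual-information acquisition (GP-MI): pick the
candidate maximizing

    mu(x) + sqrt(ln(2/delta)) * (sqrt(sigma2(x) + g) - sqrt(g)),

where ``g`` accumulates the predictive variances of the points selected
so far and ``delta`` is a (tiny) confidence parameter.  The surrogate is
a squared-exponential GP over log2-transformed coordinates with length
scale set to the median pairwise candidate distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .dataset_io import InteractionDataset
from .evaluation import cross_validate
from .nrlmf_core import Hyperparameters

__all__ = ["SearchSpace", "grid_search", "gp_mi_optimize", "combined_search"]


def _pow2(lo: int, hi: int) -> list[float]:
    return [float(2.0**k) for k in range(lo, hi + 1)]


def _default_axes() -> dict:
    return {
        "c": [5.0],
        "K1": [5],
        "K2": [5],
        "r": [50, 100],
        "alpha": _pow2(-5, 2),
        "beta": _pow2(-5, 0),
        "lambda": _pow2(-5, 1),
        "theta": _pow2(-3, 0),
        "eta1": _pow2(5, 9),
        "eta2": _pow2(2, 5),
    }


@dataclass
class SearchSpace:
    """Candidate grids per hyperparameter axis.

    ``lambda`` is a single axis: the drug and target prior precisions move
    together.  ``bo_axes`` names the axes handed to the Bayesian-optimization
    inner loop; the rest form the outer exhaustive sweep.  ``delta`` is the
    GP-MI confidence parameter (default 1e-100).
    """

    fixed_axes: dict = field(default_factory=_default_axes)
    bo_axes: tuple = ("lambda", "alpha")
    delta: float = 1e-100

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        for name, vals in self.fixed_axes.items():
            if len(list(vals)) == 0:
                raise ValueError(f"axis {name!r} has no candidate values")
        unknown = set(self.bo_axes) - set(self.fixed_axes)
        if unknown:
            raise ValueError(f"bo_axes not present in fixed_axes: {sorted(unknown)}")

    def hyperparameters(self, assignment: dict) -> Hyperparameters:
        """Materialize one grid point as a validated record."""
        kw = dict(assignment)
        lam = kw.pop("lambda")
        kw["lambda_d"] = kw["lambda_t"] = lam
        kw["K1"] = int(kw.get("K1", 5))
        kw["K2"] = int(kw.get("K2", 5))
        kw["r"] = int(kw.get("r", 50))
        return Hyperparameters(**kw)


def _iter_grid(axes: dict):
    names = list(axes)
    for combo in product(*(axes[n] for n in names)):
        yield dict(zip(names, combo))


def grid_search(
    ds: InteractionDataset,
    space: SearchSpace,
    scenario: str = "CVS1",
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    objective: str = "mean_auc",
    rescoring: bool = True,
):
    """Exhaustive cross-validated sweep over the full Cartesian grid.

    Returns ``(best Hyperparameters, best value, table)`` where the table
    holds one row per grid point with its CV metrics (ties broken by
    iteration order).
    """
    if objective not in ("mean_auc", "mean_aupr"):
        raise ValueError("objective must be 'mean_auc' or 'mean_aupr'")
    rows = []
    best_hp, best_val = None, -np.inf
    for assignment in _iter_grid(space.fixed_axes):
        hp = space.hyperparameters(assignment)
        res = cross_validate(
            ds, hp, scenario, n_folds=folds, n_repetitions=repeats,
            base_seed=seed, rescoring=rescoring,
        )
        val = getattr(res, objective)
        rows.append({**assignment, "mean_auc": res.mean_auc, "mean_aupr": res.mean_aupr})
        if np.isfinite(val) and val > best_val:
            best_hp, best_val = hp, val
    return best_hp, best_val, pd.DataFrame(rows)


class _GP:
    """Minimal noise-free-ish squared-exponential GP surrogate."""

    def __init__(self, length_scale: float, noise: float = 1e-8):
        self.ls = length_scale
        self.noise = noise
        self._X = None

    def _k(self, A, B):
        d2 = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-np.maximum(d2, 0.0) / (2.0 * self.ls**2))

    def fit(self, X, y):
        self._X = np.atleast_2d(X)
        self._y = np.asarray(y, dtype=float)
        self._mean = self._y.mean()
        K = self._k(self._X, self._X) + self.noise * np.eye(len(self._y))
        self._chol = np.linalg.cholesky(K)
        self._alpha = np.linalg.solve(
            self._chol.T, np.linalg.solve(self._chol, self._y - self._mean)
        )

    def predict(self, X):
        X = np.atleast_2d(X)
        if self._X is None:
            return np.zeros(len(X)), np.ones(len(X))
        Ks = self._k(X, self._X)
        mu = self._mean + Ks @ self._alpha
        v = np.linalg.solve(self._chol, Ks.T)
        var = np.clip(1.0 - np.sum(v**2, axis=0), 0.0, None)
        return mu, var


def gp_mi_optimize(
    evaluate,
    candidates,
    delta: float = 1e-100,
    n_iterations: int = 15,
    seed: int = 0,
):
    """Sequential GP-MI Bayesian optimization over a finite candidate set.

    Never evaluates a candidate twice; with ``n_iterations`` at least the
    number of candidates it degenerates to exhaustive search.  Returns
    ``(best point, best value, history)`` with history a list of
    ``(point, value)`` in evaluation order.  Deterministic given ``seed``
    (used only to break acquisition ties).
    """
    candidates = [tuple(np.atleast_1d(c)) for c in candidates]
    if not candidates:
        raise ValueError("need at least one candidate")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if n_iterations > len(candidates):
        warnings.warn(
            "n_iterations exceeds the number of candidates; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        n_iterations = len(candidates)

    X = np.array(candidates, dtype=float)
    ls = _median_distance(X)
    gp = _GP(length_scale=ls)
    rng = np.random.default_rng(seed)
    sqrt_alpha = np.sqrt(np.log(2.0 / delta))

    evaluated: dict = {}
    history = []
    gamma_hat = 0.0
    for _ in range(n_iterations):
        remaining = [i for i, c in enumerate(candidates) if c not in evaluated]
        mu, var = gp.predict(X[remaining])
        acq = mu + sqrt_alpha * (np.sqrt(var + gamma_hat) - np.sqrt(gamma_hat))
        best = np.flatnonzero(acq >= acq.max() - 1e-12)
        pick = remaining[int(rng.choice(best))]
        gamma_hat += float(var[remaining.index(pick)])
        val = float(evaluate(candidates[pick]))
        evaluated[candidates[pick]] = val
        history.append((candidates[pick], val))
        xs = np.array([c for c in evaluated], dtype=float)
        ys = np.array([evaluated[c] for c in evaluated], dtype=float)
        gp.fit(xs, ys)
    best_point = max(evaluated, key=evaluated.get)
    return best_point, evaluated[best_point], history


def _median_distance(X: np.ndarray) -> float:
    if len(X) < 2:
        return 1.0
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    d = np.sqrt(np.maximum(d2, 0.0))
    m = float(np.median(d[np.triu_indices_from(d, k=1)]))
    return m if m > 0 else 1.0


def combined_search(
    ds: InteractionDataset,
    space: SearchSpace,
    scenario: str = "CVS1",
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    bo_iterations: int = 15,
    rescoring: bool = True,
    return_table: bool = False,
):
    """Outer exhaustive sweep with inner GP-MI optimization of the BO axes.

    For every combination of the non-BO axes, the BO axes (by default the
    tied prior precision ``lambda`` and the Laplacian weight ``alpha``)
    are optimized by :func:`gp_mi_optimize` over their log2-spaced grid,
    using cross-validated mean AUC as the objective; the best point seen
    anywhere is returned as a validated record.
    """
    outer_axes = {n: v for n, v in space.fixed_axes.items() if n not in space.bo_axes}
    bo_names = list(space.bo_axes)
    bo_grid = list(product(*(space.fixed_axes[n] for n in bo_names)))
    log2_grid = [tuple(np.log2(p)) for p in bo_grid]
    point_of = dict(zip(log2_grid, bo_grid))

    best_hp, best_val = None, -np.inf
    rows = []
    for outer in _iter_grid(outer_axes):

        def evaluate(log2_point) -> float:
            raw = point_of[tuple(log2_point)]
            hp = space.hyperparameters({**outer, **dict(zip(bo_names, raw))})
            res = cross_validate(
                ds, hp, scenario, n_folds=folds, n_repetitions=repeats,
                base_seed=seed, rescoring=rescoring,
            )
            return res.mean_auc if np.isfinite(res.mean_auc) else -np.inf

        point, val, history = gp_mi_optimize(
            evaluate, log2_grid, delta=space.delta,
            n_iterations=min(bo_iterations, len(log2_grid)), seed=seed,
        )
        for p, v in history:
            raw = point_of[tuple(p)]
            rows.append({**outer, **dict(zip(bo_names, raw)), "mean_auc": v})
        if val > best_val:
            raw = point_of[tuple(point)]
            best_hp = space.hyperparameters({**outer, **dict(zip(bo_names, raw))})
            best_val = val
    if return_table:
        return best_hp, pd.DataFrame(rows)
    return best_hp
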