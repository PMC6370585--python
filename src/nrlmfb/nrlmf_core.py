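"""Neighborhood regularized logistic matrix factorization (NRLMF).

The model represents each drug ``i`` by a latent vector ``u_i`` and each
target ``j`` by ``v_j`` (both in R^r) and posits an interaction
probability ``p_ij = logistic(u_i . v_j)``.  Observed interactions are
up-weighted by a factor ``c`` in the Bernoulli likelihood; zero-mean
Gaussian priors with precisions ``lambda_d`` / ``lambda_t`` regularize the
latents; and graph-Laplacian penalties built from the K1 nearest neighbors
of each entity in the similarity matrices pull similar entities' latents
together.  The MAP objective is

    sum_ij (1 + c*y_ij - y_ij) * ln(1 + exp(u_i.v_j)) - c*y_ij*(u_i.v_j)
    + 1/2 tr[U^T (lambda_d I + alpha Ld) U]
    + 1/2 tr[V^T (lambda_t I + beta Lt) V]

minimized by alternating AdaGrad descent.  After fitting, the latent
vector of every cold-start (all-zero-row/column) entity is replaced by a
similarity-weighted average of its K2 most similar *positive* entities,
and the prediction score is the logistic of the smoothed inner products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .dataset_io import InteractionDataset

__all__ = [
    "Hyperparameters",
    "NeighborhoodGraph",
    "LatentModel",
    "interaction_probability",
    "build_neighborhood_graph",
    "objective",
    "gradients",
    "fit",
    "smooth_negatives",
    "score",
]


@dataclass(frozen=True)
class Hyperparameters:
    """All tunables of the model in one validated record.

    Parameters
    ----------
    c
        Importance weight on observed interactions in the likelihood.
    K1
        Number of nearest neighbors for the Laplacian regularizers.
    K2
        Number of nearest positive neighbors for cold-start smoothing.
    r
        Latent dimension.
    lambda_d, lambda_t
        Gaussian prior precisions for drug / target latents.
    alpha, beta
        Weights of the drug / target neighborhood Laplacian penalties.
    theta
        AdaGrad learning rate.
    eta1, eta2
        Rescoring parameters: the beta concentration of a pair with
        interaction-information count ``gamma`` is ``gamma*eta1 + eta2``.
        ``eta2 > 2`` keeps the beta density bell-shaped.
    max_iter
        Number of alternating-descent rounds (fixed budget, no early stop).
    """

    c: float = 5.0
    K1: int = 5
    K2: int = 5
    r: int = 50
    lambda_d: float = 0.125
    lambda_t: float = 0.125
    alpha: float = 0.25
    beta: float = 0.125
    theta: float = 0.5
    eta1: float = 128.0
    eta2: float = 8.0
    max_iter: int = 100

    def __post_init__(self) -> None:
        for name in ("c", "lambda_d", "lambda_t", "alpha", "beta", "theta", "eta1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("K1", "K2", "r", "max_iter"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.eta2 <= 2:
            raise ValueError("eta2 must exceed 2 (bell-shaped beta requires a,b > 1)")

    def replace(self, **kw) -> "Hyperparameters":
        return replace(self, **kw)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Hyperparameters":
        """Build from a flat key/value mapping; unknown keys are errors."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown hyperparameter(s): {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class NeighborhoodGraph:
    """Directed K1-nearest-neighbor graph and its Laplacian.

    ``A[i, l]`` holds the similarity of ``l`` to ``i`` when ``l`` is one of
    the K1 most similar entities to ``i`` (self excluded), else 0.  The
    Laplacian is ``L = (D + Dt) - (A + A.T)`` with ``D`` / ``Dt`` the
    diagonal matrices of row / column sums of ``A``; it satisfies
    ``x.T L x = sum_il A[i,l] ||x_i - x_l||^2``.
    """

    A: np.ndarray
    L: np.ndarray


@dataclass
class LatentModel:
    """Fitted latent factors plus their cold-start-smoothed variants."""

    U: np.ndarray
    V: np.ndarray
    U_smoothed: np.ndarray
    V_smoothed: np.ndarray
    hyperparams: Hyperparameters
    objective_trace: list = field(default_factory=list)


def interaction_probability(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Elementwise logistic of the latent inner products, overflow-safe."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if not (np.isfinite(U).all() and np.isfinite(V).all()):
        raise ValueError("latent matrices contain non-finite entries")
    Z = U @ V.T
    # scipy.special.expit underflows to exactly 0 for very negative logits;
    # that is acceptable downstream but we keep it explicit here
    from scipy.special import expit

    return expit(Z)


def _knn_rows(S: np.ndarray, k: int, candidates: np.ndarray | None = None):
    """Indices of the k most-similar candidates per row, self excluded.

    Ties are broken toward the smallest index via a stable sort on
    (-similarity, index).
    """
    n = S.shape[0]
    out = []
    for i in range(n):
        cand = np.arange(n) if candidates is None else candidates
        cand = cand[cand != i]
        order = np.lexsort((cand, -S[i, cand]))
        out.append(cand[order[:k]])
    return out


def build_neighborhood_graph(S: np.ndarray, K1: int) -> NeighborhoodGraph:
    """K1-nearest-neighbor adjacency and Laplacian from a similarity matrix."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not 1 <= K1 < n:
        raise ValueError(f"K1 must satisfy 1 <= K1 < n (got K1={K1}, n={n})")
    A = np.zeros_like(S)
    for i, nbrs in enumerate(_knn_rows(S, K1)):
        A[i, nbrs] = S[i, nbrs]
    np.fill_diagonal(A, 0.0)
    D = np.diag(A.sum(axis=1))
    Dt = np.diag(A.sum(axis=0))
    L = (D + Dt) - (A + A.T)
    return NeighborhoodGraph(A=A, L=L)


def _weights(Y: np.ndarray, c: float) -> np.ndarray:
    # (1 + c*y - y): observed pairs weighted c, unknown pairs weighted 1
    return 1.0 + (c - 1.0) * Y


def objective(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    Ld: np.ndarray,
    Lt: np.ndarray,
    hp: Hyperparameters,
) -> float:
    """MAP objective value (weighted logistic loss + prior and Laplacian terms)."""
    # overflow to inf is deliberately allowed: fit() detects it and reports
    # a divergent learning rate instead of warning
    with np.errstate(over="ignore", invalid="ignore"):
        Z = U @ V.T
        W = _weights(Y, hp.c)
        # ln(1 + exp(z)) computed stably for large |z|
        log1pexp = np.logaddexp(0.0, Z)
        loss = float(np.sum(W * log1pexp - hp.c * Y * Z))
        reg_u = 0.5 * float(
            np.trace(U.T @ ((hp.lambda_d * np.eye(len(Ld)) + hp.alpha * Ld) @ U))
        )
        reg_v = 0.5 * float(
            np.trace(V.T @ ((hp.lambda_t * np.eye(len(Lt)) + hp.beta * Lt) @ V))
        )
        return loss + reg_u + reg_v


def gradients(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    Ld: np.ndarray,
    Lt: np.ndarray,
    hp: Hyperparameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`objective` with respect to U and V."""
    P = interaction_probability(U, V)
    W = _weights(Y, hp.c)
    G = W * P - hp.c * Y
    gU = G @ V + (hp.lambda_d * U + hp.alpha * (Ld @ U))
    gV = G.T @ U + (hp.lambda_t * V + hp.beta * (Lt @ V))
    return gU, gV


def smooth_negatives(
    X: np.ndarray,
    S: np.ndarray,
    K2: int,
    positive_mask: np.ndarray,
) -> np.ndarray:
    """Replace cold-entity rows by weighted averages of similar positive rows.

    Rows flagged positive are returned unchanged.  Each negative row ``i``
    becomes the similarity-weighted mean of the K2 positive entities most
    similar to ``i`` (K2 truncated to the number of positives).  If every
    selected similarity is zero there is nothing to average against, so the
    unsmoothed row is kept and a warning is emitted.
    """
    X = np.asarray(X, dtype=float)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    positives = np.flatnonzero(positive_mask)
    if positives.size == 0:
        raise ValueError("cannot smooth: no positive entities at all")
    out = X.copy()
    k = min(K2, positives.size)
    for i in np.flatnonzero(~positive_mask):
        cand = positives[positives != i]
        if cand.size == 0:
            continue
        order = np.lexsort((cand, -S[i, cand]))
        nbrs = cand[order[:k]]
        w = S[i, nbrs]
        tot = w.sum()
        if tot <= 0:
            warnings.warn(
                f"entity {i} has zero similarity to every selected positive "
                "neighbor; keeping its unsmoothed latent vector",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out[i] = (w / tot) @ X[nbrs]
    return out


def fit(ds: InteractionDataset, hp: Hyperparameters, seed: int = 0) -> LatentModel:
    """MAP-estimate the latent factors by alternating AdaGrad descent.

    Each round updates all of U holding V fixed, then all of V holding the
    new U fixed, with per-coordinate steps ``theta * g / sqrt(G + eps)``
    where ``G`` accumulates squared gradients.  The objective is recorded
    once per round.  Fully deterministic given ``seed``.
    """
    nd, nt = ds.n_drugs, ds.n_targets
    if not (hp.K1 < nd and hp.K1 < nt):
        raise ValueError(f"K1={hp.K1} must be smaller than both nd={nd} and nt={nt}")
    rng = np.random.default_rng(seed)
    # sd 1/sqrt(r) keeps initial logits O(1)
    U = rng.standard_normal((nd, hp.r)) / np.sqrt(hp.r)
    V = rng.standard_normal((nt, hp.r)) / np.sqrt(hp.r)

    Ld = build_neighborhood_graph(ds.Sd, hp.K1).L
    Lt = build_neighborhood_graph(ds.St, hp.K1).L
    Y = ds.Y

    eps = 1e-8
    accU = np.zeros_like(U)
    accV = np.zeros_like(V)
    trace: list[float] = []
    for it in range(hp.max_iter):
        # a divergent theta may overflow the accumulators; the objective
        # check below turns that into a diagnostic rather than a warning
        with np.errstate(over="ignore", invalid="ignore"):
            gU, _ = gradients(U, V, Y, Ld, Lt, hp)
            accU += gU**2
            U = U - hp.theta * gU / np.sqrt(accU + eps)
            _, gV = gradients(U, V, Y, Ld, Lt, hp)
            accV += gV**2
            V = V - hp.theta * gV / np.sqrt(accV + eps)
        val = objective(U, V, Y, Ld, Lt, hp)
        if not np.isfinite(val):
            raise FloatingPointError(
                f"objective became non-finite at iteration {it}; "
                "the AdaGrad rate theta is likely too large"
            )
        trace.append(val)

    pos_drugs = Y.sum(axis=1) > 0
    pos_targets = Y.sum(axis=0) > 0
    if pos_drugs.any():
        U_s = smooth_negatives(U, ds.Sd, hp.K2, pos_drugs)
    else:
        U_s = U.copy()
    if pos_targets.any():
        V_s = smooth_negatives(V, ds.St, hp.K2, pos_targets)
    else:
        V_s = V.copy()
    return LatentModel(
        U=U,
        V=V,
        U_smoothed=U_s,
        V_smoothed=V_s,
        hyperparams=hp,
        objective_trace=trace,
    )


def score(model: LatentModel) -> np.ndarray:
    """Prediction scores: logistic of the smoothed latent inner products."""
    return interaction_probability(model.U_smoothed, model.V_smoothed)
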