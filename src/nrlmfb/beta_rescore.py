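"""Beta-distribution rescoring of factorization scores (the NRLMFbeta step).

The factorization's score for a pair is treated as the *mode* of a beta
distribution whose *concentration* ``a + b = gamma*eta1 + eta2`` grows
with the pair's interaction information ``gamma`` (row sum plus column sum
of the training adjacency).  The rescored value is the *mean* ``a/(a+b)``
of that distribution:

    s' = (s * (gamma*eta1 + eta2 - 2) + 1) / (gamma*eta1 + eta2)

Because the beta distribution is the conjugate prior of the Bernoulli
likelihood underlying the factorization, this is a Bayesian shrinkage of
low-evidence scores toward 1/2: pairs with little interaction information
(small gamma) are shrunk hard, well-supported pairs barely move, and in
the limit eta1 -> infinity the score is returned unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GammaMatrix",
    "BetaParams",
    "interaction_information",
    "beta_parameters",
    "rescore",
    "rescore_matrix",
]


@dataclass(frozen=True)
class GammaMatrix:
    """Interaction-information counts: ``gamma[i, j] = rowsum_i(Y) + colsum_j(Y)``.

    A pair with ``y_ij = 1`` contributes to both its row and column sum, so
    it is counted twice -- the count is used exactly as defined.
    """

    gamma: np.ndarray


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a bell-shaped beta distribution (a, b > 1)."""

    a: float
    b: float

    @property
    def mode(self) -> float:
        return (self.a - 1.0) / (self.a + self.b - 2.0)

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


def interaction_information(Y: np.ndarray) -> GammaMatrix:
    """Row-sum-plus-column-sum evidence count for every pair of the training matrix."""
    Y = np.asarray(Y, dtype=float)
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("Y must be binary")
    gamma = Y.sum(axis=1, keepdims=True) + Y.sum(axis=0, keepdims=True)
    return GammaMatrix(gamma=gamma.astype(int))


def beta_parameters(s: float, concentration: float) -> BetaParams:
    """Solve mode ``(a-1)/(a+b-2) = s`` and concentration ``a+b`` for (a, b).

    Requires an interior mode ``0 < s < 1`` and concentration > 2 so that
    both shapes exceed 1 (bell-shaped density with a unique interior mode).
    """
    if not 0.0 < s < 1.0:
        raise ValueError("score must lie strictly inside (0, 1)")
    if concentration <= 2.0:
        raise ValueError("concentration must exceed 2 for a bell-shaped beta")
    a = s * (concentration - 2.0) + 1.0
    return BetaParams(a=a, b=concentration - a)


def rescore(s, gamma, eta1: float, eta2: float):
    """Rescore ``s`` as the beta posterior mean at concentration ``gamma*eta1 + eta2``.

    Accepts scalars or arrays (broadcast elementwise).  The endpoints
    ``s = 0`` and ``s = 1`` are accepted: the formula is defined there and
    maps them to ``1/conc`` and ``(conc-1)/conc`` respectively.
    """
    if eta1 <= 0:
        raise ValueError("eta1 must be positive")
    if eta2 <= 2:
        raise ValueError("eta2 must exceed 2")
    s = np.asarray(s, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if (gamma < 0).any():
        raise ValueError("gamma counts must be nonnegative")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    conc = gamma * eta1 + eta2
    out = (s * (conc - 2.0) + 1.0) / conc
    return out if out.ndim else float(out)


def rescore_matrix(
    scores: np.ndarray,
    Y_train: np.ndarray,
    eta1: float,
    eta2: float,
) -> np.ndarray:
    """Rescore a full score matrix using counts from the *training* adjacency.

    ``Y_train`` must be the training matrix (test entries zeroed); using
    the full adjacency would leak held-out labels into the evidence counts.
    """
    scores = np.asarray(scores, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    if scores.shape != Y_train.shape:
        raise ValueError(
            f"scores shape {scores.shape} != adjacency shape {Y_train.shape}"
        )
    gamma = interaction_information(Y_train).gamma
    return rescore(scores, gamma, eta1, eta2)
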