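"""Cross-validation protocol: scenario splitters, masking, AUC/AUPR, CIs.

Three 10-fold cross-validation scenarios are supported:

* **CVS1** -- random pairs: all ``nd * nt`` drug-target pairs are
  partitioned into folds (the standard matrix-completion setting).
* **CVS2** -- whole drugs: the drug set is partitioned; a test fold is
  ``D' x T``, so every test drug is cold at training time.
* **CVS3** -- whole targets: symmetric to CVS2 over targets.

Training data for a fold is the adjacency with all test-pair entries set
to zero; evaluation ranks test pairs against the true adjacency, treating
unknowns as negatives (the convention of this benchmark family).  Each
scenario is repeated with fresh fold seeds, and the repetition means are
summarized by a mean and a 95% Student-t confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .beta_rescore import rescore_matrix
from .dataset_io import InteractionDataset
from .nrlmf_core import Hyperparameters, fit, score

__all__ = [
    "CVSplit",
    "CVResult",
    "make_split",
    "mask_training",
    "auc",
    "aupr",
    "cross_validate",
    "nested_validate",
]

SCENARIOS = ("CVS1", "CVS2", "CVS3")


@dataclass
class CVSplit:
    """Folds of one cross-validation repetition.

    ``folds[k]`` is the set of test (drug index, target index) pairs of
    fold ``k``.  Whatever the scenario, the folds are an exact partition
    of the pair grid (CVS1), the drug rows (CVS2) or the target columns
    (CVS3), with sizes differing by at most one unit.
    """

    scenario: str
    folds: list
    seed: int


@dataclass
class CVResult:
    """Per-fold metrics with repetition-level aggregation.

    ``per_fold_auc`` / ``per_fold_aupr`` have shape (repetitions, folds);
    entries are NaN where a fold's test labels were single-class (the
    metric is undefined there).  ``ci_auc`` / ``ci_aupr`` are 95%
    Student-t half-widths over the per-repetition means (NaN for a single
    repetition, where the t-distribution has zero degrees of freedom).
    """

    per_fold_auc: np.ndarray
    per_fold_aupr: np.ndarray
    mean_auc: float
    ci_auc: float
    mean_aupr: float
    ci_aupr: float
    config: dict = field(default_factory=dict)


def make_split(
    ds: InteractionDataset,
    scenario: str,
    n_folds: int = 10,
    seed: int = 0,
) -> CVSplit:
    """Randomly partition pairs (CVS1), drugs (CVS2) or targets (CVS3) into folds."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    nd, nt = ds.n_drugs, ds.n_targets
    n_units = {"CVS1": nd * nt, "CVS2": nd, "CVS3": nt}[scenario]
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > n_units:
        raise ValueError(
            f"{n_folds} folds requested but only {n_units} {scenario} units available"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_units)
    chunks = np.array_split(perm, n_folds)
    if scenario == "CVS1":
        folds = [{(int(u // nt), int(u % nt)) for u in chunk} for chunk in chunks]
    elif scenario == "CVS2":
        folds = [{(int(d), t) for d in chunk for t in range(nt)} for chunk in chunks]
    else:
        folds = [{(d, int(t)) for t in chunk for d in range(nd)} for chunk in chunks]
    return CVSplit(scenario=scenario, folds=folds, seed=seed)


def mask_training(Y: np.ndarray, test_pairs) -> np.ndarray:
    """Copy of ``Y`` with every test pair's entry replaced by 0."""
    Y = np.asarray(Y, dtype=float)
    Yt = Y.copy()
    pairs = list(test_pairs)
    if pairs:
        rows, cols = zip(*pairs)
        rows, cols = np.asarray(rows), np.asarray(cols)
        if (
            (rows < 0).any()
            or (rows >= Y.shape[0]).any()
            or (cols < 0).any()
            or (cols >= Y.shape[1]).any()
        ):
            raise IndexError("test pair outside the adjacency matrix bounds")
        Yt[rows, cols] = 0.0
    return Yt


def auc(labels, scores) -> float:
    """Ranking AUC (Mann-Whitney; ties count one half).

    Returns NaN with a warning when the labels are single-class.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warnings.warn("AUC undefined for single-class labels", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(roc_auc_score(labels, scores))


def aupr(labels, scores) -> float:
    """Area under the precision-recall curve, step-wise (non-interpolated).

    Returns NaN with a warning when there is no positive label.
    """
    labels = np.asarray(labels)
    if labels.sum() == 0:
        warnings.warn("AUPR undefined without positive labels", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(average_precision_score(labels, scores))


def _t_ci(rep_means: np.ndarray) -> float:
    """95% Student-t half-width over repetition means (NaN for one repetition)."""
    rep_means = rep_means[np.isfinite(rep_means)]
    n = rep_means.size
    if n < 2:
        return float("nan")
    return float(
        stats.t.ppf(0.975, n - 1) * np.std(rep_means, ddof=1) / np.sqrt(n)
    )


def _aggregate(per_fold_auc: np.ndarray, per_fold_aupr: np.ndarray, config: dict) -> CVResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rep_auc = np.nanmean(per_fold_auc, axis=1)
        rep_aupr = np.nanmean(per_fold_aupr, axis=1)
    return CVResult(
        per_fold_auc=per_fold_auc,
        per_fold_aupr=per_fold_aupr,
        mean_auc=float(np.nanmean(rep_auc)),
        ci_auc=_t_ci(rep_auc),
        mean_aupr=float(np.nanmean(rep_aupr)),
        ci_aupr=_t_ci(rep_aupr),
        config=config,
    )


def _fold_seed(base_seed: int, rep: int, fold: int) -> int:
    return int((base_seed + 1_000_003 * (rep + 1) + 1_009 * (fold + 1)) % (2**31 - 1))


def _evaluate_pairs(Y, scores, pairs):
    idx = np.array(sorted(pairs))
    labels = Y[idx[:, 0], idx[:, 1]]
    s = scores[idx[:, 0], idx[:, 1]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return auc(labels, s), aupr(labels, s)


def cross_validate(
    ds: InteractionDataset,
    hp: Hyperparameters,
    scenario: str,
    n_folds: int = 10,
    n_repetitions: int = 5,
    base_seed: int = 0,
    rescoring: bool = False,
) -> CVResult:
    """Repeated scenario cross-validation of the factorization model.

    For every repetition (fold seed ``base_seed + repetition``) and fold:
    mask the test pairs out of the adjacency, fit on the masked matrix,
    score all pairs, optionally rescore with evidence counts from the
    masked matrix, then compute AUC/AUPR over the fold's test pairs
    against the true adjacency.
    """
    per_auc = np.full((n_repetitions, n_folds), np.nan)
    per_aupr = np.full((n_repetitions, n_folds), np.nan)
    for rep in range(n_repetitions):
        split = make_split(ds, scenario, n_folds, seed=base_seed + rep)
        for k, pairs in enumerate(split.folds):
            Y_train = mask_training(ds.Y, pairs)
            model = fit(ds.with_adjacency(Y_train), hp, seed=_fold_seed(base_seed, rep, k))
            s = score(model)
            if rescoring:
                s = rescore_matrix(s, Y_train, hp.eta1, hp.eta2)
            a, p = _evaluate_pairs(ds.Y, s, pairs)
            per_auc[rep, k] = a
            per_aupr[rep, k] = p
    config = {
        "scenario": scenario,
        "n_folds": n_folds,
        "n_repetitions": n_repetitions,
        "base_seed": base_seed,
        "rescoring": rescoring,
        "hyperparameters": asdict(hp),
    }
    return _aggregate(per_auc, per_aupr, config)


def nested_validate(
    ds: InteractionDataset,
    hp_grid,
    scenario: str,
    outer_folds: int = 10,
    inner_folds: int = 5,
    n_repetitions: int = 5,
    base_seed: int = 0,
    rescoring: bool = False,
):
    """Nested (external) cross-validation with inner model selection.

    For each outer fold, every candidate in ``hp_grid`` is scored by inner
    pair-wise (CVS1) cross-validation run on the outer-training adjacency
    only -- the outer test entries are zeroed before the inner split ever
    sees them, so selection cannot read held-out labels.  The candidate
    with the highest inner mean AUC is refit on the outer-training matrix
    and evaluated once on the outer test fold.

    Returns ``(CVResult, selections)`` where ``selections[rep][fold]`` is
    the chosen :class:`Hyperparameters`.
    """
    hp_grid = list(hp_grid)
    if not hp_grid:
        raise ValueError("empty hyperparameter grid")
    per_auc = np.full((n_repetitions, outer_folds), np.nan)
    per_aupr = np.full((n_repetitions, outer_folds), np.nan)
    selections = []
    for rep in range(n_repetitions):
        split = make_split(ds, scenario, outer_folds, seed=base_seed + rep)
        picks = []
        for k, pairs in enumerate(split.folds):
            Y_train = mask_training(ds.Y, pairs)
            ds_train = ds.with_adjacency(Y_train)
            inner_seed = _fold_seed(base_seed, rep, k)
            best_hp, best_val = None, -np.inf
            for hp in hp_grid:
                res = cross_validate(
                    ds_train,
                    hp,
                    "CVS1",
                    n_folds=inner_folds,
                    n_repetitions=1,
                    base_seed=inner_seed,
                    rescoring=rescoring,
                )
                val = res.mean_auc
                if np.isfinite(val) and val > best_val:
                    best_hp, best_val = hp, val
            if best_hp is None:
                best_hp = hp_grid[0]
            picks.append(best_hp)
            model = fit(ds_train, best_hp, seed=_fold_seed(base_seed, rep, k))
            s = score(model)
            if rescoring:
                s = rescore_matrix(s, Y_train, best_hp.eta1, best_hp.eta2)
            a, p = _evaluate_pairs(ds.Y, s, pairs)
            per_auc[rep, k] = a
            per_aupr[rep, k] = p
        selections.append(picks)
    config = {
        "scenario": scenario,
        "outer_folds": outer_folds,
        "inner_folds": inner_folds,
        "n_repetitions": n_repetitions,
        "base_seed": base_seed,
        "rescoring": rescoring,
        "grid_size": len(hp_grid),
    }
    return _aggregate(per_auc, per_aupr, config), selections
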