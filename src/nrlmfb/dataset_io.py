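"""Reading, validation and summary statistics for interaction benchmarks.

A dataset is three tab-separated matrices: a binary drug-target adjacency
matrix ``Y``, a drug-drug similarity matrix ``Sd`` and a target-target
similarity matrix ``St``, each with one header row of column identifiers
and a leading column of row identifiers (the dialect used by the public
gold-standard drug-target benchmarks).  Internally ``Y`` is always stored
drugs-as-rows; the public benchmark adjacency files store targets on rows,
so the loader takes an explicit ``orientation`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InteractionDataset",
    "DatasetStats",
    "DatasetValidationError",
    "load_dataset",
    "dataset_statistics",
    "write_scores",
    "load_matrix",
]

#: entries this far outside [0, 1] are clamped; larger violations are errors
_SIM_TOL = 1e-9
#: self-similarity must be at least this close to 1
_DIAG_TOL = 1e-6


class DatasetValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class InteractionDataset:
    """A drug-target interaction dataset.

    Attributes
    ----------
    drug_ids, target_ids
        Ordered identifiers for the ``nd`` drugs and ``nt`` targets.
    Y
        ``nd x nt`` binary adjacency; ``Y[i, j] == 1`` iff an interaction
        between drug ``i`` and target ``j`` has been observed.
    Sd, St
        Drug-drug (``nd x nd``) and target-target (``nt x nt``) similarity
        matrices with entries in [0, 1] and unit diagonal.  They are not
        forcibly symmetrized: all neighbor lookups read rows only.
    """

    drug_ids: list[str]
    target_ids: list[str]
    Y: np.ndarray
    Sd: np.ndarray
    St: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.Sd = _validate_similarity(np.asarray(self.Sd, dtype=float), "Sd")
        self.St = _validate_similarity(np.asarray(self.St, dtype=float), "St")
        nd, nt = len(self.drug_ids), len(self.target_ids)
        if self.Y.shape != (nd, nt):
            raise DatasetValidationError(
                f"Y has shape {self.Y.shape}, expected ({nd}, {nt})"
            )
        if self.Sd.shape != (nd, nd):
            raise DatasetValidationError(
                f"Sd has shape {self.Sd.shape}, expected ({nd}, {nd})"
            )
        if self.St.shape != (nt, nt):
            raise DatasetValidationError(
                f"St has shape {self.St.shape}, expected ({nt}, {nt})"
            )
        bad = ~np.isin(self.Y, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DatasetValidationError(
                f"adjacency entry at row {i} ({self.drug_ids[i]!r}), "
                f"column {j} ({self.target_ids[j]!r}) is {self.Y[i, j]!r}, "
                "expected 0 or 1"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def with_adjacency(self, Y: np.ndarray) -> "InteractionDataset":
        """Return a copy of this dataset with ``Y`` replaced (same ids/similarities)."""
        return InteractionDataset(self.drug_ids, self.target_ids, np.array(Y), self.Sd, self.St)


@dataclass(frozen=True)
class DatasetStats:
    """Summary counts for an :class:`InteractionDataset`.

    ``n_negative_drugs`` / ``n_negative_targets`` count the cold-start
    entities: drugs (rows) and targets (columns) of ``Y`` with no observed
    interaction at all.
    """

    n_drugs: int
    n_targets: int
    n_interactions: int
    density: float
    n_negative_drugs: int
    n_negative_targets: int


def _validate_similarity(S: np.ndarray, name: str) -> np.ndarray:
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise DatasetValidationError(f"{name} must be square, got shape {S.shape}")
    if not np.isfinite(S).all():
        raise DatasetValidationError(f"{name} contains non-finite entries")
    low, high = S.min(initial=0.0), S.max(initial=1.0)
    if low < -_SIM_TOL or high > 1.0 + _SIM_TOL:
        i, j = np.argwhere((S < -_SIM_TOL) | (S > 1.0 + _SIM_TOL))[0]
        raise DatasetValidationError(
            f"{name}[{i}, {j}] = {S[i, j]!r} lies outside [0, 1]"
        )
    S = np.clip(S, 0.0, 1.0)
    d = np.diag(S)
    if (d < 1.0 - _DIAG_TOL).any():
        i = int(np.argmin(d))
        raise DatasetValidationError(
            f"{name}[{i}, {i}] = {d[i]!r}: self-similarity must be ~1"
        )
    return S


def load_matrix(path) -> pd.DataFrame:
    """Read one TSV matrix with a header row and a leading label column."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_dataset(
    adjacency_path,
    drug_sim_path,
    target_sim_path,
    orientation: str = "targets_as_rows",
) -> InteractionDataset:
    """Load the three benchmark matrices and return a validated dataset.

    Parameters
    ----------
    orientation
        ``"targets_as_rows"`` (the layout of the public ``*_admat_dgc.txt``
        files) or ``"drugs_as_rows"``.  The returned dataset always holds
        ``Y`` drugs-as-rows.
    """
    if orientation not in ("drugs_as_rows", "targets_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    adf = load_matrix(adjacency_path)
    if orientation == "targets_as_rows":
        adf = adf.T
    drug_ids = list(adf.index)
    target_ids = list(adf.columns)

    sd = load_matrix(drug_sim_path)
    st = load_matrix(target_sim_path)
    _check_labels("drug", drug_ids, list(sd.index))
    _check_labels("target", target_ids, list(st.index))

    Y = adf.to_numpy(dtype=float)
    bad = ~np.isin(Y, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DatasetValidationError(
            f"adjacency entry at row {drug_ids[i]!r}, column {target_ids[j]!r} "
            f"is {Y[i, j]!r}, expected the literal characters 0 or 1"
        )
    return InteractionDataset(
        drug_ids=drug_ids,
        target_ids=target_ids,
        Y=Y,
        Sd=sd.to_numpy(dtype=float),
        St=st.to_numpy(dtype=float),
    )


def _check_labels(kind: str, expected: list[str], got: list[str]) -> None:
    if expected == got:
        return
    missing = set(expected) - set(got)
    extra = set(got) - set(expected)
    offender = sorted(missing | extra)[0] if (missing or extra) else got[0]
    raise DatasetValidationError(
        f"{kind} identifiers in similarity file do not match the adjacency "
        f"file (offending identifier: {offender!r})"
    )


def dataset_statistics(ds: InteractionDataset) -> DatasetStats:
    """Count interactions, density and cold-start rows/columns."""
    n = int(ds.Y.sum())
    nd, nt = ds.n_drugs, ds.n_targets
    return DatasetStats(
        n_drugs=nd,
        n_targets=nt,
        n_interactions=n,
        density=n / (nd * nt),
        n_negative_drugs=int((ds.Y.sum(axis=1) == 0).sum()),
        n_negative_targets=int((ds.Y.sum(axis=0) == 0).sum()),
    )


def write_scores(scores: np.ndarray, drug_ids, target_ids, path) -> None:
    """Write a real matrix in the benchmark TSV dialect at full float precision.

    Round-trips exactly: reloading with :func:`load_matrix` reproduces the
    values bitwise (17 significant digits suffice for IEEE doubles).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(drug_ids), len(target_ids)):
        raise ValueError(
            f"scores shape {scores.shape} does not match id lists "
            f"({len(drug_ids)}, {len(target_ids)})"
        )
    df = pd.DataFrame(scores, index=list(drug_ids), columns=list(target_ids))
    df.to_csv(path, sep="\t", float_format="%.17g")
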