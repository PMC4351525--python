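"""Drug-ADE reference standard and similarity-based multi-ADE score matrices.

The predictive model is a similarity-weighted label propagation: given a
drug-drug similarity matrix ``Ma`` (zero diagonal, the leave-one-out
convention) and a binary drug-ADE reference standard ``Mb``, the score of a
(drug, ADE) cell is an aggregate of the drug's similarities to the drugs
known to cause that ADE.  Three aggregation rules are provided:

``max``
    similarity to the nearest causing drug (the headline algorithm); the
    identity of that drug is retained as per-cell provenance.
``double``
    maximum similarity to the causing drugs minus maximum similarity to the
    non-causing drugs.
``average``
    mean similarity to the causing drugs.

Because the similarity diagonal is zero, a drug's own label never
contributes to its own score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "ReferenceStandard",
    "ScoreMatrix",
    "build_reference",
    "align_drug_sets",
    "predict_max",
    "predict_double",
    "predict_average",
    "predict",
]


class InputError(ValueError):
    """Raised for malformed or inconsistent user inputs."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class SimilarityMatrix:
    """Square drug-drug similarity matrix with values in [0, 1].

    ``S[i, j]`` is the similarity between ``drugs[i]`` and ``drugs[j]``.
    In leave-one-out mode the diagonal is identically zero so that a drug
    never supports its own label.
    """

    drugs: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.drugs)
        if self.S.shape != (n, n):
            raise InputError(
                f"similarity matrix shape {self.S.shape} does not match "
                f"{n} drug identifiers"
            )
        if len(set(self.drugs)) != n:
            raise InputError("duplicate drug_id in similarity matrix")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def validate(self, *, symmetric_tol: float = 1e-9) -> None:
        """Check symmetry, [0, 1] bounds and the zero diagonal."""
        if np.abs(self.S - self.S.T).max(initial=0.0) > symmetric_tol:
            raise InputError("similarity matrix is not symmetric")
        if self.S.min(initial=0.0) < -1e-12 or self.S.max(initial=0.0) > 1 + 1e-12:
            raise InputError("similarity values outside [0, 1]")

    def zeroed_diagonal(self) -> "SimilarityMatrix":
        S = self.S.copy()
        np.fill_diagonal(S, 0.0)
        return SimilarityMatrix(list(self.drugs), S)

    def subset(self, drugs: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.drugs.index(d) for d in drugs]
        return SimilarityMatrix(list(drugs), self.S[np.ix_(idx, idx)])


@dataclass
class ReferenceStandard:
    """Binary drug × ADE matrix (1 = association present in the standard)."""

    drugs: list[str]
    ades: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M)
        if self.M.shape != (len(self.drugs), len(self.ades)):
            raise InputError("reference standard shape mismatch")
        if not np.isin(self.M, (0, 1)).all():
            raise InputError("reference standard entries must be 0/1")
        self.M = self.M.astype(np.int8)

    @property
    def n_positives(self) -> int:
        return int(self.M.sum())

    @property
    def prevalence(self) -> float:
        return self.n_positives / self.M.size

    def to_long(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.M)
        return pd.DataFrame(
            {
                "drug_id": [self.drugs[i] for i in rows],
                "ade_id": [self.ades[j] for j in cols],
            }
        )

    def subset_drugs(self, drugs: Sequence[str]) -> "ReferenceStandard":
        idx = [self.drugs.index(d) for d in drugs]
        return ReferenceStandard(list(drugs), list(self.ades), self.M[idx, :])


@dataclass
class ScoreMatrix:
    """Drug × ADE predictive scores with optional per-cell provenance.

    ``provenance[i, k]`` names the most similar causing drug behind the
    score of cell ``(i, k)`` — the drug whose label propagated.  Only the
    ``max`` algorithm produces provenance.
    """

    drugs: list[str]
    ades: list[str]
    C: np.ndarray
    algorithm: str
    provenance: np.ndarray | None = field(default=None)

    def score(self, drug_id: str, ade_id: str) -> float:
        return float(self.C[self.drugs.index(drug_id), self.ades.index(ade_id)])

    def provenance_of(self, drug_id: str, ade_id: str) -> str | None:
        if self.provenance is None:
            return None
        p = self.provenance[self.drugs.index(drug_id), self.ades.index(ade_id)]
        return None if p is None else str(p)

    def to_long(self) -> pd.DataFrame:
        n_d, n_a = self.C.shape
        di, ai = np.meshgrid(np.arange(n_d), np.arange(n_a), indexing="ij")
        out = pd.DataFrame(
            {
                "drug_id": np.asarray(self.drugs, dtype=object)[di.ravel()],
                "ade_id": np.asarray(self.ades, dtype=object)[ai.ravel()],
                "score": self.C.ravel(),
                "algorithm": self.algorithm,
            }
        )
        if self.provenance is not None:
            out["provenance_drug"] = self.provenance.ravel()
        return out


# ---------------------------------------------------------------------------
# Reference standard construction
# ---------------------------------------------------------------------------


def build_reference(
    long_table: pd.DataFrame | Iterable[tuple[str, str]],
    min_drugs_per_ade: int = 5,
) -> ReferenceStandard:
    """Build the binary reference standard from (drug_id, ade_id) pairs.

    Duplicate pairs are collapsed; ADE columns with fewer than
    ``min_drugs_per_ade`` positive drugs are dropped.  Drug rows and ADE
    columns keep first-appearance order.

    Raises
    ------
    InputError
        If the table is empty, or no ADE survives the filter.
    """
    if not isinstance(long_table, pd.DataFrame):
        long_table = pd.DataFrame(long_table, columns=["drug_id", "ade_id"])
    if long_table.empty:
        raise InputError("empty drug-ADE table")
    df = long_table[["drug_id", "ade_id"]].astype(str).drop_duplicates()

    drugs = list(dict.fromkeys(df["drug_id"]))
    ades = list(dict.fromkeys(df["ade_id"]))
    d_idx = {d: i for i, d in enumerate(drugs)}
    a_idx = {a: j for j, a in enumerate(ades)}
    M = np.zeros((len(drugs), len(ades)), dtype=np.int8)
    M[df["drug_id"].map(d_idx), df["ade_id"].map(a_idx)] = 1

    keep = M.sum(axis=0) >= min_drugs_per_ade
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d/%d ADEs with fewer than %d positive drugs",
            n_dropped, len(ades), min_drugs_per_ade,
        )
    if not keep.any():
        raise InputError(
            f"no ADE has at least {min_drugs_per_ade} positive drugs"
        )
    rs = ReferenceStandard(drugs, [a for a, k in zip(ades, keep) if k], M[:, keep])
    logger.info(
        "reference standard: %d drugs x %d ADEs, %d positives (prevalence %.3f)",
        len(rs.drugs), len(rs.ades), rs.n_positives, rs.prevalence,
    )
    return rs


def align_drug_sets(
    ma: SimilarityMatrix, mb: ReferenceStandard
) -> tuple[SimilarityMatrix, ReferenceStandard]:
    """Intersect the drug sets of Ma and Mb, preserving Ma's order.

    Drugs present on only one side are dropped with a logged report.
    """
    common = [d for d in ma.drugs if d in set(mb.drugs)]
    if not common:
        raise InputError("similarity matrix and reference standard share no drugs")
    if len(common) < len(ma.drugs) or len(common) < len(mb.drugs):
        logger.warning(
            "drug sets differ: %d only in similarity matrix, %d only in "
            "reference standard; intersected to %d drugs",
            len(ma.drugs) - len(common), len(mb.drugs) - len(common), len(common),
        )
    return ma.subset(common), mb.subset_drugs(common)


# ---------------------------------------------------------------------------
# Score-matrix algorithms
# ---------------------------------------------------------------------------


def _check_aligned(ma: SimilarityMatrix, mb: ReferenceStandard) -> None:
    if ma.drugs != mb.drugs:
        raise InputError(
            "drug sets of similarity matrix and reference standard differ "
            "or are ordered differently; use align_drug_sets() first"
        )


def predict_max(ma: SimilarityMatrix, mb: ReferenceStandard) -> ScoreMatrix:
    """Nearest-causing-drug score: C[i,k] = max_{j positive for k, j != i} Ma[i,j].

    Equivalent to retaining the maximum of the element-wise products
    Ma[i,·]·Mb[·,k]; the zero diagonal of Ma implements leave-one-out.
    Per-cell provenance records the arg-max causing drug (ties broken by
    smallest drug index in input order).
    """
    _check_aligned(ma, mb)
    n_d, n_a = len(ma.drugs), len(mb.ades)
    C = np.zeros((n_d, n_a))
    prov = np.empty((n_d, n_a), dtype=object)
    drugs_arr = np.asarray(ma.drugs, dtype=object)
    for k in range(n_a):
        pos = np.nonzero(mb.M[:, k] == 1)[0]
        sub = ma.S[:, pos]  # (n_d, n_pos)
        # a drug must not be its own provenance: mask self-columns
        self_mask = pos[None, :] == np.arange(n_d)[:, None]
        sub = np.where(self_mask, -1.0, sub)
        best = np.argmax(sub, axis=1)
        C[:, k] = np.maximum(sub[np.arange(n_d), best], 0.0)
        prov[:, k] = drugs_arr[pos[best]]
        # a drug that is the sole positive has no donor drug at all
        lone = self_mask.all(axis=1)
        prov[lone, k] = None
    return ScoreMatrix(list(ma.drugs), list(mb.ades), C, "max", prov)


def predict_double(ma: SimilarityMatrix, mb: ReferenceStandard) -> ScoreMatrix:
    """Double similarity score: max over positives minus max over negatives.

    When the negative group of an ADE is empty after leave-one-out, the
    score falls back to the max score for the affected cells (with a
    warning): the non-causing drugs are unknown rather than confirmed
    negatives, so the positive-side signal is retained.
    """
    _check_aligned(ma, mb)
    n_d, n_a = len(ma.drugs), len(mb.ades)
    C = np.zeros((n_d, n_a))
    for k in range(n_a):
        pos = mb.M[:, k] == 1
        neg = ~pos
        for i in range(n_d):
            p = pos.copy()
            p[i] = False
            n = neg.copy()
            n[i] = False
            pmax = ma.S[i, p].max() if p.any() else 0.0
            if not n.any():
                logger.warning(
                    "ADE %s: empty negative group after leave-one-out; "
                    "falling back to max score", mb.ades[k],
                )
                C[i, k] = pmax
            else:
                C[i, k] = pmax - ma.S[i, n].max()
    return ScoreMatrix(list(ma.drugs), list(mb.ades), C, "double")


def predict_average(ma: SimilarityMatrix, mb: ReferenceStandard) -> ScoreMatrix:
    """Average similarity against the positive group (query drug excluded).

    A drug that is itself a positive for the ADE is left out of the
    positive set before averaging, for consistency with leave-one-out.
    An empty positive set scores 0 with a warning.
    """
    _check_aligned(ma, mb)
    n_d, n_a = len(ma.drugs), len(mb.ades)
    C = np.zeros((n_d, n_a))
    for k in range(n_a):
        pos = mb.M[:, k] == 1
        for i in range(n_d):
            p = pos.copy()
            p[i] = False
            if not p.any():
                logger.warning(
                    "drug %s / ADE %s: positive group empty after "
                    "leave-one-out; score set to 0", ma.drugs[i], mb.ades[k],
                )
                C[i, k] = 0.0
            else:
                C[i, k] = ma.S[i, p].mean()
    return ScoreMatrix(list(ma.drugs), list(mb.ades), C, "average")


_ALGORITHMS = {"max": predict_max, "double": predict_double, "average": predict_average}


def predict(ma: SimilarityMatrix, mb: ReferenceStandard, algorithm: str = "max") -> ScoreMatrix:
    """Dispatch to one of the ``max`` / ``double`` / ``average`` algorithms."""
    try:
        fn = _ALGORITHMS[algorithm]
    except KeyError:
        raise InputError(
            f"unknown algorithm {algorithm!r}; expected one of {sorted(_ALGORITHMS)}"
        ) from None
    return fn(ma, mb)
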