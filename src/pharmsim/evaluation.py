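"""Ranking-quality evaluation: AUROC, precision@k, enrichment, hold-out.

Global performance pools every drug-ADE cell of a score matrix against the
binary reference standard; per-ADE performance treats each ADE column as
its own outcome.  An ADE with a single class among its scored pairs has no
defined ROC curve and is reported as undefined rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ade_predictor import InputError, ReferenceStandard, ScoreMatrix

__all__ = [
    "EvaluationReport",
    "auroc",
    "precision_at_k",
    "enrichment_factor",
    "prevalence",
    "holdout_split",
    "summarize_per_ade",
    "ranked_pairs",
    "evaluate",
]

DEFAULT_KS = tuple(range(100, 1001, 100))
AUROC_HISTOGRAM_BINS = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class EvaluationReport:
    global_auroc: float | None
    per_ade_auroc: dict[str, float | None]
    median: float
    q1: float
    q3: float
    auroc_histogram: dict[str, int]
    n_auroc_above_0_6: int
    n_auroc_above_0_75: int
    precision_at_k: dict[int, float]
    enrichment_factor_at_k: dict[int, float]
    prevalence: float
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "global_auroc": self.global_auroc,
            "per_ade_auroc": self.per_ade_auroc,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "auroc_histogram": self.auroc_histogram,
            "n_auroc_above_0_6": self.n_auroc_above_0_6,
            "n_auroc_above_0_75": self.n_auroc_above_0_75,
            "precision_at_k": {str(k): v for k, v in self.precision_at_k.items()},
            "enrichment_factor_at_k": {
                str(k): v for k, v in self.enrichment_factor_at_k.items()
            },
            "prevalence": self.prevalence,
            "n_cells": self.n_cells,
        }


def auroc(scores, labels) -> float | None:
    """Area under the ROC curve (Mann-Whitney formulation, midrank ties).

    Returns ``None`` when only one class is present — the curve is
    undefined, which per-ADE summaries treat as "excluded", not zero.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise InputError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, scores))


def ranked_pairs(df: pd.DataFrame, score_col: str = "score", ascending: bool = False) -> pd.DataFrame:
    """Deterministic ranking of (drug_id, ade_id, score) rows.

    Primary key: the score (descending unless ``ascending``); ties broken
    by (drug_id, ade_id) so repeated runs produce identical orderings.
    """
    return df.sort_values(
        [score_col, "drug_id", "ade_id"],
        ascending=[ascending, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def precision_at_k(ranked: pd.DataFrame, truth: set[tuple[str, str]], k: int) -> float:
    """Fraction of true associations among the top-k ranked pairs."""
    if k <= 0:
        raise InputError(f"k must be positive, got {k}")
    if k > len(ranked):
        raise InputError(f"k={k} exceeds the {len(ranked)} ranked pairs")
    top = ranked.iloc[:k]
    hits = sum((d, a) in truth for d, a in zip(top["drug_id"], top["ade_id"]))
    return hits / k


def prevalence(n_positives: int, n_drugs: int, n_ades: int) -> float:
    """Fraction of positive cells in an n_drugs × n_ades association matrix."""
    if n_drugs <= 0 or n_ades <= 0:
        raise InputError("matrix dimensions must be positive")
    return n_positives / (n_drugs * n_ades)


def enrichment_factor(prev_subset: float, prev_reference: float) -> float:
    """Ratio of a subset's positive prevalence to the reference prevalence."""
    if prev_reference <= 0:
        raise InputError("reference prevalence must be positive")
    return prev_subset / prev_reference


def holdout_split(
    pairs: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint train/test partition of drug-ADE cells.

    Splitting is over cells, not drugs; reproducible for a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise InputError("train_fraction must be in (0, 1)")
    n = len(pairs)
    if n < 2:
        raise InputError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return (
        pairs.iloc[np.sort(perm[:n_train])].reset_index(drop=True),
        pairs.iloc[np.sort(perm[n_train:])].reset_index(drop=True),
    )


def summarize_per_ade(per_ade_auroc: dict[str, float | None]) -> dict:
    """Quartiles and histogram of the defined per-ADE AUROCs.

    Quantiles use linear interpolation; histogram bins are the 20 intervals
    of width 0.05 on [0, 1]; the >0.6 / >0.75 counts are strict.
    """
    vals = np.array([v for v in per_ade_auroc.values() if v is not None], dtype=float)
    if vals.size == 0:
        raise InputError("no defined per-ADE AUROC to summarize")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    counts, _ = np.histogram(vals, bins=AUROC_HISTOGRAM_BINS)
    hist = {
        f"{lo:.2f}-{hi:.2f}": int(c)
        for lo, hi, c in zip(AUROC_HISTOGRAM_BINS[:-1], AUROC_HISTOGRAM_BINS[1:], counts)
    }
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "histogram": hist,
        "n_above_0_6": int((vals > 0.6).sum()),
        "n_above_0_75": int((vals > 0.75).sum()),
        "n_defined": int(vals.size),
    }


def evaluate(
    mc: ScoreMatrix,
    mb: ReferenceStandard,
    ks: tuple[int, ...] = DEFAULT_KS,
) -> EvaluationReport:
    """Full evaluation of a score matrix against the reference standard.

    The global ROC pools all drug × ADE cells; SIDER-style positives are
    the cells with a 1 in the standard, all remaining cells count as
    negatives.  ``ks`` values beyond the number of cells are skipped.
    """
    if mc.drugs != mb.drugs or mc.ades != mb.ades:
        raise InputError("score matrix and reference standard are not aligned")
    y = mb.M.ravel().astype(int)
    s = mc.C.ravel()
    global_auroc = auroc(s, y)

    per_ade: dict[str, float | None] = {}
    for k_idx, ade in enumerate(mb.ades):
        per_ade[ade] = auroc(mc.C[:, k_idx], mb.M[:, k_idx].astype(int))

    long = mc.to_long()
    ranked = ranked_pairs(long)
    truth = set(map(tuple, mb.to_long()[["drug_id", "ade_id"]].itertuples(index=False)))
    prev = mb.prevalence
    p_at_k = {k: precision_at_k(ranked, truth, k) for k in ks if 0 < k <= len(ranked)}
    ef_at_k = {k: enrichment_factor(p, prev) for k, p in p_at_k.items()}

    summary = summarize_per_ade(per_ade) if any(
        v is not None for v in per_ade.values()
    ) else {"median": float("nan"), "q1": float("nan"), "q3": float("nan"),
            "histogram": {}, "n_above_0_6": 0, "n_above_0_75": 0}
    return EvaluationReport(
        global_auroc=global_auroc,
        per_ade_auroc=per_ade,
        median=summary["median"],
        q1=summary["q1"],
        q3=summary["q3"],
        auroc_histogram=summary["histogram"],
        n_auroc_above_0_6=summary["n_above_0_6"],
        n_auroc_above_0_75=summary["n_above_0_75"],
        precision_at_k=p_at_k,
        enrichment_factor_at_k=ef_at_k,
        prevalence=prev,
        n_cells=int(mc.C.size),
    )
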