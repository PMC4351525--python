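"""Re-ranking of pharmacovigilance signals with the similarity predictor.

A disproportionality signal table (Offsides-style rows of drug_id, ade_id,
EBGM, t-statistic, p-value) is inner-joined with the predictor's score
matrix; the common drug-ADE pairs are then ranked by each statistic and by
the 3D similarity score, and the rankings are compared with AUROC and
precision@k against reference-standard truth labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .ade_predictor import InputError, ReferenceStandard, ScoreMatrix
from .evaluation import DEFAULT_KS, auroc, precision_at_k, ranked_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "RANK_METHODS",
    "RankingComparison",
    "read_signal_table",
    "merge_signals",
    "truth_labels",
    "rank_and_score",
    "compare_rankings",
]

# ranking direction per method: True = smaller is stronger evidence
RANK_METHODS: dict[str, bool] = {"ebgm": False, "t": False, "p": True, "sim3d": False}
_METHOD_COLUMNS = {"ebgm": "ebgm", "t": "t", "p": "p", "sim3d": "score"}


def _normalize_ids(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.casefold()


def read_signal_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a signal table (drug_id, ade_id, ebgm, t, p).

    Keys must be unique after case-folding/trimming; EBGM must be positive
    and p-values in (0, 1].
    """
    required = {"drug_id", "ade_id", "ebgm", "t", "p"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"signal table missing columns: {sorted(missing)}")
    out = df.copy()
    out["drug_id"] = _normalize_ids(out["drug_id"])
    out["ade_id"] = _normalize_ids(out["ade_id"])
    if out.duplicated(["drug_id", "ade_id"]).any():
        raise InputError("signal table has duplicate (drug_id, ade_id) keys")
    if (out["ebgm"] <= 0).any():
        raise InputError("EBGM values must be positive")
    if ((out["p"] <= 0) | (out["p"] > 1)).any():
        raise InputError("p-values must lie in (0, 1]")
    return out


def merge_signals(signals: pd.DataFrame, mc: ScoreMatrix) -> pd.DataFrame:
    """Inner join of the signal table with the predictor's scores.

    Identifiers are matched exactly after case-folding and whitespace
    trimming.  Returns the joined table; counts of retained/dropped pairs,
    drugs and ADEs are logged.
    """
    signals = read_signal_table(signals)
    scores = mc.to_long()[["drug_id", "ade_id", "score"]].copy()
    scores["drug_id"] = _normalize_ids(scores["drug_id"])
    scores["ade_id"] = _normalize_ids(scores["ade_id"])
    joined = signals.merge(scores, on=["drug_id", "ade_id"], how="inner")
    if joined.empty:
        raise InputError(
            "no drug-ADE pairs in common between the signal table and the "
            f"score matrix (signals: {signals['drug_id'].nunique()} drugs / "
            f"{signals['ade_id'].nunique()} ADEs; scores: "
            f"{scores['drug_id'].nunique()} drugs / {scores['ade_id'].nunique()} ADEs)"
        )
    logger.info(
        "merged signals: %d common pairs (%d drugs, %d ADEs); dropped %d "
        "signal rows and %d score cells",
        len(joined), joined["drug_id"].nunique(), joined["ade_id"].nunique(),
        len(signals) - len(joined), len(scores) - len(joined),
    )
    return joined


def truth_labels(joined: pd.DataFrame, mb: ReferenceStandard) -> pd.Series:
    """1 for joined pairs present in the reference standard, else 0."""
    truth = set(
        (d.strip().casefold(), a.strip().casefold())
        for d, a in map(tuple, mb.to_long()[["drug_id", "ade_id"]].itertuples(index=False))
    )
    return pd.Series(
        [int((d, a) in truth) for d, a in zip(joined["drug_id"], joined["ade_id"])],
        index=joined.index,
        name="label",
    )


@dataclass
class RankingComparison:
    methods: list[str]
    global_auroc: dict[str, float | None]
    per_ade_auroc: dict[str, dict[str, float | None]]
    precision_at_k: dict[str, dict[int, float]]
    n_common_pairs: int
    n_tp: int
    n_fp: int

    def to_dict(self) -> dict:
        return {
            "methods": self.methods,
            "global_auroc": self.global_auroc,
            "per_ade_auroc": self.per_ade_auroc,
            "precision_at_k": {
                m: {str(k): v for k, v in d.items()}
                for m, d in self.precision_at_k.items()
            },
            "n_common_pairs": self.n_common_pairs,
            "n_tp": self.n_tp,
            "n_fp": self.n_fp,
        }


def rank_and_score(
    joined: pd.DataFrame,
    method: str,
    labels: pd.Series,
    ks: tuple[int, ...] = DEFAULT_KS,
) -> dict:
    """AUROC + precision@k for one ranking method on the joined table.

    ``ebgm``, ``t`` and ``sim3d`` rank descending; ``p`` ranks ascending.
    """
    if method not in RANK_METHODS:
        raise InputError(f"unknown ranking method {method!r}; expected {sorted(RANK_METHODS)}")
    col = _METHOD_COLUMNS[method]
    ascending = RANK_METHODS[method]
    work = joined[["drug_id", "ade_id", col]].rename(columns={col: "rank_score"})
    work["label"] = labels.to_numpy()
    # AUROC on the ranking orientation: flip sign for ascending methods
    score = -work["rank_score"] if ascending else work["rank_score"]
    global_auroc = auroc(score, work["label"])
    per_ade = {
        ade: auroc(
            -sub["rank_score"] if ascending else sub["rank_score"], sub["label"]
        )
        for ade, sub in work.groupby("ade_id", sort=True)
    }
    ranked = ranked_pairs(work, score_col="rank_score", ascending=ascending)
    truth = set(
        (d, a) for d, a, lab in zip(work["drug_id"], work["ade_id"], work["label"]) if lab
    )
    p_at_k = {k: precision_at_k(ranked, truth, k) for k in ks if 0 < k <= len(ranked)}
    return {"global_auroc": global_auroc, "per_ade_auroc": per_ade, "precision_at_k": p_at_k}


def compare_rankings(
    joined: pd.DataFrame,
    mb: ReferenceStandard,
    methods: tuple[str, ...] = ("ebgm", "t", "p", "sim3d"),
    ks: tuple[int, ...] = DEFAULT_KS,
) -> RankingComparison:
    """Rank the common pairs by each method and collect the comparison."""
    labels = truth_labels(joined, mb)
    results = {m: rank_and_score(joined, m, labels, ks) for m in methods}
    return RankingComparison(
        methods=list(methods),
        global_auroc={m: r["global_auroc"] for m, r in results.items()},
        per_ade_auroc={m: r["per_ade_auroc"] for m, r in results.items()},
        precision_at_k={m: r["precision_at_k"] for m, r in results.items()},
        n_common_pairs=len(joined),
        n_tp=int(labels.sum()),
        n_fp=int((1 - labels).sum()),
    )
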