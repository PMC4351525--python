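"""Per-ADE QSAR comparator: stepwise linear discriminant analysis.

For a single ADE the drugs are split into causing / non-causing classes
and a linear discriminant function is built on molecular descriptors.
Variable selection is forward stepwise on Wilks' lambda: at each step the
candidate descriptor with the largest partial F (greatest lambda
reduction) enters if its partial-F p-value is below ``alpha_enter``, up to
a hard cap of five descriptors.  Model quality is reported as Wilks' U,
the overall F ratio and its p-value; ranking performance as the AUROC of
the posterior probability of the causing class.

Descriptors are an open constitutional / topological / physico-chemical
set computed with RDKit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .ade_predictor import InputError
from .evaluation import auroc

logger = logging.getLogger(__name__)

__all__ = [
    "DESCRIPTOR_FUNCS",
    "LdaModel",
    "compute_descriptors",
    "wilks_lambda",
    "stepwise_lda",
    "lda_posterior_auroc",
]

# open descriptor set: constitutional, topological and physico-chemical
DESCRIPTOR_FUNCS = {
    "MolWt": Descriptors.MolWt,
    "HeavyAtomCount": Descriptors.HeavyAtomCount,
    "NumHeteroatoms": Descriptors.NumHeteroatoms,
    "RingCount": Descriptors.RingCount,
    "NumAromaticRings": rdMolDescriptors.CalcNumAromaticRings,
    "NumRotatableBonds": Descriptors.NumRotatableBonds,
    "NumHDonors": Descriptors.NumHDonors,
    "NumHAcceptors": Descriptors.NumHAcceptors,
    "NHOHCount": Descriptors.NHOHCount,
    "NOCount": Descriptors.NOCount,
    "FractionCSP3": Descriptors.FractionCSP3,
    "MolLogP": Crippen.MolLogP,
    "MolMR": Crippen.MolMR,
    "TPSA": Descriptors.TPSA,
    "LabuteASA": Descriptors.LabuteASA,
    "BalabanJ": Descriptors.BalabanJ,
    "BertzCT": Descriptors.BertzCT,
    "HallKierAlpha": Descriptors.HallKierAlpha,
    "Kappa1": Descriptors.Kappa1,
    "Kappa2": Descriptors.Kappa2,
    "Kappa3": Descriptors.Kappa3,
    "Chi0v": Descriptors.Chi0v,
    "Chi1v": Descriptors.Chi1v,
    "Chi2v": Descriptors.Chi2v,
}


@dataclass
class LdaModel:
    ade_id: str
    selected_descriptors: list[str]  # at most 5
    coefficients: np.ndarray  # discriminant weights, one per descriptor
    intercept: float
    wilks_u: float
    f_stat: float
    p_value: float
    estimator: LinearDiscriminantAnalysis | None
    medians: pd.Series  # training medians used for imputation

    def to_dict(self) -> dict:
        return {
            "ade_id": self.ade_id,
            "selected_descriptors": self.selected_descriptors,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "wilks_u": float(self.wilks_u),
            "f_stat": float(self.f_stat),
            "p_value": float(self.p_value),
        }


def compute_descriptors(smiles_table: pd.DataFrame) -> pd.DataFrame:
    """Descriptor matrix (drugs × descriptors) for a (drug_id, smiles) table.

    Constant and all-missing columns are dropped; remaining missing values
    are imputed with the column median.
    """
    rows, index = [], []
    for drug_id, smi in zip(smiles_table["drug_id"], smiles_table["smiles"]):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise InputError(f"unparsable SMILES for {drug_id}: {smi!r}")
        vals = {}
        for name, fn in DESCRIPTOR_FUNCS.items():
            try:
                v = float(fn(mol))
                vals[name] = v if np.isfinite(v) else np.nan
            except Exception:
                vals[name] = np.nan
        rows.append(vals)
        index.append(str(drug_id))
    X = pd.DataFrame(rows, index=index)
    X = X.dropna(axis=1, how="all")
    X = X.loc[:, X.nunique(dropna=True) > 1]
    return X.fillna(X.median())


def wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for grouping y over columns of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        W += (Xg - Xg.mean(axis=0)).T @ (Xg - Xg.mean(axis=0))
    detT = np.linalg.det(T)
    if detT <= 0:
        return 1.0
    return float(max(np.linalg.det(W) / detT, np.finfo(float).tiny))


def _partial_f(lam_old: float, lam_new: float, n: int, g: int, p_in: int) -> float:
    """F statistic for adding one variable to a p_in-variable discriminant."""
    df2 = n - g - p_in
    if df2 <= 0 or lam_new <= 0:
        return 0.0
    return (lam_old / lam_new - 1.0) * df2 / (g - 1)


def stepwise_lda(
    X: pd.DataFrame,
    y,
    ade_id: str = "",
    max_vars: int = 5,
    alpha_enter: float = 0.05,
) -> LdaModel:
    """Forward stepwise LDA capped at ``max_vars`` descriptors.

    Entry criterion: largest partial F among candidates, admitted when its
    p-value is below ``alpha_enter``.  No removal step.  Descriptors that
    make the within-class scatter singular are skipped with a warning.
    Returns a model even when no descriptor enters (prior-only classifier,
    Wilks' U = 1).
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise InputError("stepwise LDA needs two classes")
    n, g = len(y), len(np.unique(y))
    selected: list[str] = []
    lam = 1.0
    candidates = list(X.columns)
    while len(selected) < max_vars and candidates:
        best: tuple[float, float, str, float] | None = None  # (F, p, name, lam)
        for name in candidates:
            cols = selected + [name]
            lam_new = wilks_lambda(X[cols].to_numpy(), y)
            F = _partial_f(lam, lam_new, n, g, len(selected))
            if F <= 0:
                continue
            p = float(stats.f.sf(F, g - 1, n - g - len(selected)))
            if best is None or F > best[0]:
                best = (F, p, name, lam_new)
        if best is None or best[1] >= alpha_enter:
            break
        F, p, name, lam = best
        selected.append(name)
        candidates.remove(name)
        logger.debug("ADE %s: entered %s (partial F=%.2f, p=%.3g)", ade_id, name, F, p)

    if selected:
        try:
            est = LinearDiscriminantAnalysis(solver="svd").fit(X[selected], y)
        except np.linalg.LinAlgError:
            est = None
        coefs = est.coef_[0] if est is not None else np.zeros(len(selected))
        intercept = float(est.intercept_[0]) if est is not None else 0.0
        p_vars = len(selected)
        df2 = n - g - p_vars + 1
        F_all = (1.0 - lam) / lam * df2 / p_vars if lam > 0 and df2 > 0 else float("inf")
        p_all = float(stats.f.sf(F_all, p_vars, df2)) if np.isfinite(F_all) else 0.0
    else:
        est, coefs, intercept = None, np.zeros(0), 0.0
        F_all, p_all = 0.0, 1.0
    return LdaModel(
        ade_id=ade_id,
        selected_descriptors=selected,
        coefficients=np.asarray(coefs, dtype=float),
        intercept=intercept,
        wilks_u=lam,
        f_stat=float(F_all),
        p_value=p_all,
        estimator=est,
        medians=X.median(),
    )


def lda_posterior_auroc(model: LdaModel, X: pd.DataFrame, y) -> float | None:
    """AUROC of the posterior probability of the positive class.

    Returns ``None`` for single-class ``y`` (undefined curve).  A model
    with no selected descriptors scores every sample with the class prior,
    giving chance-level AUROC.
    """
    y = np.asarray(y).astype(int)
    if model.estimator is None or not model.selected_descriptors:
        scores = np.zeros(len(y))
    else:
        Xs = X[model.selected_descriptors].fillna(model.medians)
        pos_col = int(np.where(model.estimator.classes_ == 1)[0][0])
        scores = model.estimator.predict_proba(Xs)[:, pos_col]
    return auroc(scores, y)
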