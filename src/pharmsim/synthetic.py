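"""Self-contained synthetic test worlds: drug libraries, reference
standards and pharmacovigilance signal tables.

The generator plants the "similar drugs share ADEs" structure the
predictor is built to exploit: drugs are grown by decorating a fixed set
of chemical scaffolds (one scaffold per cluster, so both 2D and 3D
similarity correlate with cluster identity), each ADE is attached to one
cluster, and cluster members are positive for the ADE with probability
1 - label_noise while outsiders are positive with probability
label_noise.  Signal tables mimic disproportionality statistics: EBGM and
t are drawn from a null distribution mixed, for true pairs, with an
upward-shifted component whose weight is the ``informativeness``; the
two-sided p-value is a strictly decreasing function of |t|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from scipy.special import erfc

from .ade_predictor import InputError, ReferenceStandard

__all__ = [
    "SCAFFOLD_TEMPLATES",
    "SUBSTITUENTS",
    "SyntheticWorld",
    "make_library",
    "make_standard",
    "make_signals",
    "make_world",
]

# two-slot SMILES templates; {a} is attached as a prefix fragment, {b}
# inside a branch.  One scaffold per cluster.  The cores are deliberately
# large and chemically distinctive (10-16 heavy atoms) so that cluster
# identity, not the decorations, dominates both fingerprint bits and the
# pharmacophore arrangement.
SCAFFOLD_TEMPLATES = [
    "{a}c1ccc(-c2ccc({b})cc2)cc1",      # biphenyl
    "{a}c1ccc2nc({b})ccc2c1",           # quinoline
    "{a}C1CCC2(CC1)CCC({b})CC2",        # spiro[5.5]undecane
    "{a}c1ccc(S(=O)(=O)N{b})cc1",       # benzenesulfonamide
    "{a}C1CCN(C(=O)c2ccc({b})cc2)CC1",  # phenylamide-piperidine
    "{a}c1ccc(Oc2ccc({b})cc2)cc1",      # diphenyl ether
    "{a}c1ccc2[nH]c({b})cc2c1",         # indole
    "{a}c1nc2ccc({b})cc2s1",            # benzothiazole
]

SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "CO", "CN",
    "CCO", "CCN", "Cl", "F", "C(=O)O", "C(=O)N", "C#N", "C(F)(F)F", "OC(=O)C",
]

_T_SHIFT = 2.5  # mean shift of the informative signal component
_N_CLUSTER_SUBS = 4  # size of each cluster's characteristic substituent subset


@dataclass
class SyntheticWorld:
    smiles_table: pd.DataFrame  # drug_id, smiles
    reference_standard: ReferenceStandard
    signal_table: pd.DataFrame  # drug_id, ade_id, ebgm, t, p
    ground_truth_clusters: dict[str, int]
    parameters: dict


def make_library(
    n_drugs: int, seed: int = 0, n_clusters: int = 6
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Decorate scaffolds into ``n_drugs`` unique, valid SMILES.

    Drugs are assigned round-robin to ``n_clusters`` scaffolds; each drug
    gets two random substituents, resampled on canonical-SMILES collision.
    Mimicking a congeneric drug series, the second substituent is drawn
    from a small cluster-characteristic subset while the first is free, so
    members of a cluster share their core and part of their decoration.
    Returns the (drug_id, smiles) table and the drug → cluster map.
    """
    if n_clusters > len(SCAFFOLD_TEMPLATES):
        raise InputError(
            f"at most {len(SCAFFOLD_TEMPLATES)} clusters available, got {n_clusters}"
        )
    capacity = n_clusters * len(SUBSTITUENTS) * _N_CLUSTER_SUBS
    if n_drugs > capacity:
        raise InputError(f"n_drugs={n_drugs} exceeds library capacity {capacity}")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    rows, clusters = [], {}
    # some substituent/slot combinations are chemically invalid and simply
    # resampled; keep RDKit from spamming stderr about them
    RDLogger.DisableLog("rdApp.error")
    try:
        return _fill_library(n_drugs, n_clusters, rng, seen, rows, clusters)
    finally:
        RDLogger.EnableLog("rdApp.error")


def _fill_library(n_drugs, n_clusters, rng, seen, rows, clusters):
    for i in range(n_drugs):
        cluster = i % n_clusters
        template = SCAFFOLD_TEMPLATES[cluster]
        cluster_subs = [
            SUBSTITUENTS[(cluster * 7 + j) % len(SUBSTITUENTS)]
            for j in range(_N_CLUSTER_SUBS)
        ]
        for _ in range(1000):
            a = rng.choice(SUBSTITUENTS)
            b = rng.choice(cluster_subs)
            smi = template.format(a=a, b=b)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen.add(canonical)
            break
        else:
            raise InputError("could not generate enough unique molecules")
        drug_id = f"drug_{i:03d}"
        rows.append({"drug_id": drug_id, "smiles": canonical})
        clusters[drug_id] = cluster
    return pd.DataFrame(rows), clusters


def make_standard(
    clusters: dict[str, int],
    n_ades: int,
    label_noise: float = 0.05,
    seed: int = 0,
    min_drugs_per_ade: int = 5,
    max_retries: int = 200,
) -> ReferenceStandard:
    """Reference standard with planted cluster → ADE structure.

    Each ADE belongs to one cluster (cycling through the clusters); a
    drug is positive with probability 1 - label_noise if it is in the
    ADE's cluster, label_noise otherwise.  Columns failing the
    ≥ ``min_drugs_per_ade``-positives filter are redrawn; if a column
    cannot be realised the configuration is infeasible and an error is
    raised.
    """
    if not clusters:
        raise InputError("empty cluster map")
    if not 0 <= label_noise <= 1:
        raise InputError("label_noise must be in [0, 1]")
    drugs = list(clusters)
    cluster_ids = sorted(set(clusters.values()))
    membership = np.array([clusters[d] for d in drugs])
    rng = np.random.default_rng(seed)
    cols, ades = [], []
    for k in range(n_ades):
        cluster = cluster_ids[k % len(cluster_ids)]
        in_cluster = membership == cluster
        p_pos = np.where(in_cluster, 1.0 - label_noise, label_noise)
        for _ in range(max_retries):
            col = (rng.random(len(drugs)) < p_pos).astype(np.int8)
            if col.sum() >= min_drugs_per_ade:
                break
        else:
            raise InputError(
                f"cannot realise an ADE with >= {min_drugs_per_ade} positives "
                f"for cluster {cluster} (cluster size {int(in_cluster.sum())}, "
                f"label_noise {label_noise})"
            )
        cols.append(col)
        ades.append(f"ade_{k:03d}")
    return ReferenceStandard(drugs, ades, np.column_stack(cols))


def make_signals(
    standard: ReferenceStandard, informativeness: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Offsides-style signal table over every cell of the standard.

    For a true pair, EBGM and t are drawn from the shifted component with
    probability ``informativeness`` and from the null otherwise; false
    pairs always draw from the null.  p = erfc(|t|/sqrt(2)) is the
    two-sided normal tail, strictly decreasing in |t| and in (0, 1].
    """
    if not 0 <= informativeness <= 1:
        raise InputError("informativeness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = standard.M.astype(bool).ravel()
    n = labels.size
    informative = labels & (rng.random(n) < informativeness)

    t = rng.normal(0.0, 1.0, n) + np.where(informative, _T_SHIFT, 0.0)
    ebgm_log = rng.normal(0.0, 0.5, n) + np.where(informative, 1.0, 0.0)
    ebgm = np.exp(ebgm_log)
    p = np.clip(erfc(np.abs(t) / np.sqrt(2.0)), np.finfo(float).tiny, 1.0)

    di, ai = np.meshgrid(
        np.arange(len(standard.drugs)), np.arange(len(standard.ades)), indexing="ij"
    )
    return pd.DataFrame(
        {
            "drug_id": np.asarray(standard.drugs, dtype=object)[di.ravel()],
            "ade_id": np.asarray(standard.ades, dtype=object)[ai.ravel()],
            "ebgm": ebgm,
            "t": t,
            "p": p,
        }
    )


def make_world(
    n_drugs: int = 60,
    n_ades: int = 40,
    n_clusters: int = 6,
    label_noise: float = 0.05,
    signal_informativeness: float = 0.0,
    seed: int = 0,
) -> SyntheticWorld:
    """Generate a complete synthetic study world (library, Mb, signals)."""
    smiles_table, clusters = make_library(n_drugs, seed=seed, n_clusters=n_clusters)
    standard = make_standard(clusters, n_ades, label_noise, seed=seed + 1)
    signals = make_signals(standard, signal_informativeness, seed=seed + 2)
    return SyntheticWorld(
        smiles_table=smiles_table,
        reference_standard=standard,
        signal_table=signals,
        ground_truth_clusters=clusters,
        parameters={
            "n_drugs": n_drugs,
            "n_ades": n_ades,
            "n_clusters": n_clusters,
            "label_noise": label_noise,
            "signal_informativeness": signal_informativeness,
            "seed": seed,
        },
    )
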