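"""2D comparator: MACCS structural-key fingerprints and Tanimoto similarity.

Each molecule is encoded as a 166-bit vector of MACCS structural keys and
pairs are compared with the Tanimoto coefficient |A∧B| / |A∨B|.  Serves as
the 2D baseline against the 3D pharmacophoric score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .ade_predictor import InputError, SimilarityMatrix

__all__ = ["Fingerprint", "maccs", "tanimoto", "build_2d_matrix"]

N_MACCS_BITS = 166


@dataclass
class Fingerprint:
    drug_id: str
    bits: np.ndarray  # uint8 {0,1}, length 166

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def maccs(smiles: str, drug_id: str = "") -> Fingerprint:
    """MACCS-keys fingerprint of a molecule given as SMILES.

    RDKit emits a 167-bit vector whose bit 0 is a never-set placeholder;
    it is dropped so the vector has the canonical 166 keys.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    bv = MACCSkeys.GenMACCSKeys(mol)
    bits = np.zeros(bv.GetNumBits(), dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(drug_id or smiles, bits[1:])


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∧B| / |A∨B|; 0 for two all-zero vectors."""
    if a.bits.shape != b.bits.shape:
        raise InputError(
            f"fingerprint length mismatch: {a.bits.size} vs {b.bits.size}"
        )
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    return inter / union


def build_2d_matrix(
    smiles_table: pd.DataFrame, zero_diagonal: bool = True
) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix over a (drug_id, smiles) table.

    Diagonal zeroed by default (leave-one-out convention); rows/columns in
    input order.
    """
    ids = smiles_table["drug_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise InputError("duplicate drug_id in SMILES table")
    fps = [maccs(s, d) for d, s in zip(ids, smiles_table["smiles"])]
    n = len(fps)
    S = np.zeros((n, n))
    for i in range(n):
        S[i, i] = 0.0 if zero_diagonal else tanimoto(fps[i], fps[i])
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(ids, S)
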