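"""3D pharmacophoric similarity between small molecules.

Pipeline: a single low-energy 3D conformer is embedded per drug
(distance-geometry conformers + force-field minimisation, keeping the
global minimum over conformers and, when chirality is unspecified, over up
to three enumerated enantiomers).  The conformer is abstracted into typed
pharmacophore sites — H-bond donors and acceptors, aromatic rings,
hydrophobic carbon clusters, positive and negative ionizable groups — each
a sphere of radius 2 Å at the feature centroid.  Two molecules are compared
by rigid-body alignment that maximises the overlap volume between sites of
the same type, and the similarity score is

    sim3d(A, B) = O(A, B) / max(O(A, A), O(B, B))

where O is the aligned same-type overlap volume and O(X, X) the
self-overlap, so the score ranges from 0 (no shared pharmacophory) to 1
(identical pharmacophore arrangement).

Site densities are spherical Gaussians rho(r) = p * exp(-alpha * |r - c|^2)
with p = 2.7 and alpha set so the Gaussian's effective volume
p * (pi / alpha)^(3/2) equals a hard sphere of radius 2 Å; the pairwise
overlap then has the closed form

    V(d) = p^2 * (pi / (2 alpha))^(3/2) * exp(-alpha d^2 / 2).

A hard-sphere lens-volume functional is available as an alternative
(``overlap_model="hard_sphere"``).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .ade_predictor import InputError, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SITE_TYPES",
    "SITE_RADIUS",
    "ConformerMolecule",
    "PharmacophoreSite",
    "SiteSet",
    "AlignmentResult",
    "embed_minimum_energy",
    "perceive_sites",
    "overlap_volume",
    "self_overlap",
    "align_pair",
    "sim3d",
    "build_similarity_matrix",
]

# --- model constants -------------------------------------------------------

SITE_RADIUS = 2.0  # Å, fixed interaction radius of every pharmacophore site
GAUSS_P = 2.7  # Gaussian peak density (ROCS convention)
# alpha such that p*(pi/alpha)^{3/2} == (4/3)*pi*R^3
GAUSS_ALPHA = math.pi * (3.0 * GAUSS_P / (4.0 * math.pi * SITE_RADIUS**3)) ** (2.0 / 3.0)
# closed-form prefactor of the pairwise Gaussian overlap integral
_PAIR_PREFACTOR = GAUSS_P**2 * (math.pi / (2.0 * GAUSS_ALPHA)) ** 1.5

MAX_HEAVY_ATOMS = 150  # proteins / large peptides are rejected above this
MAX_ENANTIOMERS = 3

SITE_TYPES = (
    "donor",
    "acceptor",
    "aromatic",
    "hydrophobic",
    "positive_ionizable",
    "negative_ionizable",
)


class EmbeddingError(RuntimeError):
    """Raised when no 3D conformer could be generated for a molecule."""


# --- domain types ----------------------------------------------------------


@dataclass
class ConformerMolecule:
    """A drug with a single retained minimum-energy 3D conformer."""

    drug_id: str
    smiles: str  # canonical SMILES of the retained stereo variant
    coords: list[tuple[str, float, float, float]]  # (element, x, y, z) in Å
    energy: float  # force-field energy, arbitrary consistent units
    stereo_variant: int  # 0-based index of the winning enantiomer
    mol: Chem.Mol = field(repr=False)  # heavy-atom RDKit mol with conformer


@dataclass(frozen=True)
class PharmacophoreSite:
    site_type: str
    center: tuple[float, float, float]  # Å
    radius: float = SITE_RADIUS

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise InputError(f"unknown site type {self.site_type!r}")


@dataclass
class SiteSet:
    """Typed pharmacophore sites of one conformer, in its coordinate frame."""

    drug_id: str
    sites: list[PharmacophoreSite]

    def __len__(self) -> int:
        return len(self.sites)

    def by_type(self) -> dict[str, np.ndarray]:
        """Centers grouped by site type as (n, 3) arrays."""
        out: dict[str, list] = {}
        for s in self.sites:
            out.setdefault(s.site_type, []).append(s.center)
        return {t: np.asarray(c, dtype=float) for t, c in out.items()}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SiteSet":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return SiteSet(
            self.drug_id,
            [
                PharmacophoreSite(s.site_type, tuple(R @ np.asarray(s.center) + t), s.radius)
                for s in self.sites
            ],
        )


@dataclass
class AlignmentResult:
    rotation: np.ndarray  # 3x3 proper rotation applied to the moving set
    translation: np.ndarray  # 3-vector, Å
    overlap: float  # Å^3, same-type overlap volume at the optimum
    n_starts: int  # random restarts tried


# --- conformer generation --------------------------------------------------


def _parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    if mol.GetNumHeavyAtoms() > MAX_HEAVY_ATOMS:
        raise InputError(
            f"molecule with {mol.GetNumHeavyAtoms()} heavy atoms exceeds the "
            f"{MAX_HEAVY_ATOMS}-atom limit (proteins and large peptides are "
            "not supported)"
        )
    return mol


def _minimize_confs(molh: Chem.Mol) -> list[tuple[int, float]]:
    """Force-field minimise all conformers; returns (conf_id, energy) pairs.

    MMFF94 when parametrised, UFF otherwise.
    """
    if AllChem.MMFFHasAllMoleculeParams(molh):
        res = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
    else:
        res = AllChem.UFFOptimizeMoleculeConfs(molh, maxIters=500)
    out = []
    for conf, (converged, energy) in zip(molh.GetConformers(), res):
        if converged in (0, 1) and math.isfinite(energy):
            out.append((conf.GetId(), float(energy)))
    return out


def embed_minimum_energy(
    smiles: str,
    drug_id: str = "",
    max_enantiomers: int = MAX_ENANTIOMERS,
    n_confs: int = 50,
    seed: int = 0,
) -> ConformerMolecule:
    """Embed and minimise conformers, returning the global-minimum structure.

    When stereocentres are unassigned, up to ``max_enantiomers`` stereo
    variants are enumerated and each embedded independently; the single
    lowest-energy conformer across all variants is retained.  Deterministic
    for a fixed ``seed``.
    """
    base = _parse_smiles(smiles)
    opts = StereoEnumerationOptions(maxIsomers=max_enantiomers, onlyUnassigned=True)
    variants = list(itertools.islice(EnumerateStereoisomers(base, options=opts),
                                     max_enantiomers))
    if not variants:
        variants = [base]

    best: tuple[float, int, Chem.Mol, int] | None = None  # (energy, variant, molh, conf)
    for v_idx, variant in enumerate(variants):
        molh = Chem.AddHs(variant)
        params = AllChem.ETKDGv3()
        params.randomSeed = (seed * 97 + v_idx) % (2**31 - 1)
        conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
        if len(conf_ids) == 0:  # retry once with random coordinates
            params.useRandomCoords = True
            params.randomSeed += 1
            conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
        if len(conf_ids) == 0:
            continue
        for conf_id, energy in _minimize_confs(molh):
            if best is None or energy < best[0]:
                best = (energy, v_idx, molh, conf_id)
    if best is None:
        raise EmbeddingError(
            f"3D embedding failed for drug {drug_id or smiles!r}"
        )

    energy, v_idx, molh, conf_id = best
    keep = Chem.Mol(molh, confId=conf_id)
    heavy = Chem.RemoveHs(keep)
    conf = heavy.GetConformer()
    coords = [
        (atom.GetSymbol(), *map(float, conf.GetAtomPosition(atom.GetIdx())))
        for atom in heavy.GetAtoms()
    ]
    return ConformerMolecule(
        drug_id=drug_id or Chem.MolToSmiles(base),
        smiles=Chem.MolToSmiles(heavy),
        coords=coords,
        energy=energy,
        stereo_variant=v_idx,
        mol=heavy,
    )


def conformer_from_mol(mol: Chem.Mol, drug_id: str) -> ConformerMolecule:
    """Wrap an RDKit mol that already carries 3D coordinates (e.g. from SDF)."""
    if mol.GetNumConformers() == 0:
        raise InputError(f"molecule {drug_id} has no 3D coordinates")
    heavy = Chem.RemoveHs(mol)
    conf = heavy.GetConformer()
    coords = [
        (atom.GetSymbol(), *map(float, conf.GetAtomPosition(atom.GetIdx())))
        for atom in heavy.GetAtoms()
    ]
    return ConformerMolecule(
        drug_id=drug_id,
        smiles=Chem.MolToSmiles(heavy),
        coords=coords,
        energy=float("nan"),
        stereo_variant=0,
        mol=heavy,
    )


# --- pharmacophore perception ----------------------------------------------

# Feature chemistry: compact SMARTS vocabulary.  "atom" patterns place one
# site per matched atom; "group" patterns place one site at the centroid of
# the matched atoms (duplicate atom sets are collapsed).  The ionizable
# groups marked pH-dependent encode the pH-7 rules: neutral carboxylic
# acids count as negative ionizable, neutral aliphatic amines / amidines /
# guanidines as positive ionizable; they are skipped when protonation
# typing is disabled.
FEATURE_SMARTS: dict[str, list[tuple[str, str, bool]]] = {
    # (smarts, mode, ph_dependent)
    "donor": [
        ("[$([N;H1,H2,H3;+0]),$([N;H1,H2,H3;+1]),$([O;H1;+0]),$([S;H1;+0])]", "atom", False),
    ],
    "acceptor": [
        ("[$([O;X2;+0]),$([O;X1;+0]),$([O;X1;-1]),$([o;+0]),"
         "$([N;v3;X3;H0;+0;!$(N-C=[O,N,S])]),$([N;v3;X2;+0]),$([n;H0;+0])]", "atom", False),
    ],
    "aromatic": [
        ("a1aaaa1", "group", False),
        ("a1aaaaa1", "group", False),
        ("a1aaaaaa1", "group", False),
    ],
    "hydrophobic": [
        # aliphatic carbons with only carbon/hydrogen neighbours; connected
        # runs of matched atoms are merged into one site at their centroid
        ("[C;!$(C~[!#6;!#1])]", "cluster", False),
    ],
    "positive_ionizable": [
        ("[NX4+,NX3+;!$([N+]-[O-])]", "atom", False),
        # aliphatic amine, protonated at pH 7
        ("[NX3;+0;!$(N=*);!$(N-a);!$(N~[!#6;!#1]);!$(N-C=[O,N,S])]", "atom", True),
        ("[NX3][CX3]=[NX2]", "group", True),  # amidine
        ("[NX3][CX3](=[NX2])[NX3]", "group", True),  # guanidine
    ],
    "negative_ionizable": [
        ("[$([O;X1;-1]),$([S;X1;-1])]", "atom", False),
        ("[CX3](=O)[OX2H1]", "group", True),  # carboxylic acid, deprotonated at pH 7
    ],
}


def _heavy_coords(mol: Chem.Mol) -> np.ndarray:
    conf = mol.GetConformer()
    return np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())], dtype=float
    )


def _connected_components(mol: Chem.Mol, atoms: set[int]) -> list[list[int]]:
    comps, seen = [], set()
    for a in sorted(atoms):
        if a in seen:
            continue
        stack, comp = [a], []
        seen.add(a)
        while stack:
            i = stack.pop()
            comp.append(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in atoms and j not in seen:
                    seen.add(j)
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def perceive_sites(mol: ConformerMolecule, protonate: bool = True) -> SiteSet:
    """Abstract a conformer into typed pharmacophore sites of radius 2 Å.

    Each site sits at the centroid of its matched atoms.  ``protonate``
    toggles the pH-7 ionizable typing rules.  An empty site list is a valid
    result (e.g. a pure alkane has only hydrophobic sites, a noble-gas-like
    fragment none at all).
    """
    rd = mol.mol
    xyz = _heavy_coords(rd)
    sites: list[PharmacophoreSite] = []
    for site_type, patterns in FEATURE_SMARTS.items():
        atom_sets: list[tuple[int, ...]] = []
        cluster_atoms: set[int] = set()
        for smarts, mode, ph_dep in patterns:
            if ph_dep and not protonate:
                continue
            patt = Chem.MolFromSmarts(smarts)
            for match in rd.GetSubstructMatches(patt, uniquify=True):
                if mode == "cluster":
                    cluster_atoms.update(match)
                else:
                    atom_sets.append(tuple(sorted(match)))
        for comp in _connected_components(rd, cluster_atoms):
            atom_sets.append(tuple(comp))
        for atoms in dict.fromkeys(atom_sets):  # collapse duplicate atom sets
            center = xyz[list(atoms)].mean(axis=0)
            sites.append(PharmacophoreSite(site_type, tuple(map(float, center))))
    if not sites:
        logger.warning("drug %s has no perceivable pharmacophore sites", mol.drug_id)
    return SiteSet(mol.drug_id, sites)


# --- overlap volume --------------------------------------------------------


def gaussian_pair_overlap(d: np.ndarray | float) -> np.ndarray | float:
    """Closed-form overlap volume (Å^3) of two site Gaussians at distance d."""
    d = np.asarray(d, dtype=float)
    return _PAIR_PREFACTOR * np.exp(-0.5 * GAUSS_ALPHA * d**2)


def hard_sphere_pair_overlap(d: np.ndarray | float) -> np.ndarray | float:
    """Lens volume (Å^3) of two hard spheres of radius 2 Å at distance d."""
    d = np.asarray(d, dtype=float)
    R = SITE_RADIUS
    vol = np.where(
        d >= 2 * R,
        0.0,
        np.pi * (2 * R - d) ** 2 * (d**2 + 4 * R * d) / np.maximum(12 * d, 1e-300),
    )
    return np.where(d <= 1e-12, 4.0 / 3.0 * np.pi * R**3, vol)


_OVERLAP_MODELS = {"gaussian": gaussian_pair_overlap, "hard_sphere": hard_sphere_pair_overlap}


def overlap_volume(a: SiteSet, b: SiteSet, overlap_model: str = "gaussian") -> float:
    """Same-type pharmacophoric overlap O(A, B) in a common frame (Å^3).

    Sums the pairwise sphere-overlap volume over every pair of sites of
    identical type; site pairs of different types contribute nothing.
    Symmetric in its arguments.
    """
    pair = _OVERLAP_MODELS[overlap_model]
    by_a, by_b = a.by_type(), b.by_type()
    total = 0.0
    for t, ca in by_a.items():
        cb = by_b.get(t)
        if cb is None:
            continue
        total += float(np.sum(pair(cdist(ca, cb))))
    return total


def self_overlap(a: SiteSet, overlap_model: str = "gaussian") -> float:
    """O(A, A): the overlap of a site set with itself (identity frame)."""
    return overlap_volume(a, a, overlap_model)


# --- alignment -------------------------------------------------------------


def _typed_arrays(s: SiteSet, types: list[str]) -> dict[str, np.ndarray]:
    by = s.by_type()
    return {t: by[t] for t in types}


def _rigid_apply(params: np.ndarray, pts: np.ndarray) -> np.ndarray:
    R = Rotation.from_rotvec(params[:3]).as_matrix()
    return pts @ R.T + params[3:]


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array(
        [a[1] * b[2] - a[2] * b[1], a[2] * b[0] - a[0] * b[2], a[0] * b[1] - a[1] * b[0]]
    )


def _rotation_jacobian(rotvec: np.ndarray, R: np.ndarray) -> list[np.ndarray]:
    """dR/d(rotvec_i), i = 0..2 (Gallego & Yezzi closed form)."""
    theta2 = float(rotvec @ rotvec)
    if theta2 < 1e-16:
        return [_skew(e) for e in np.eye(3)]
    ImR = np.eye(3) - R
    out = []
    for i in range(3):
        v = rotvec[i] * rotvec + _cross3(rotvec, ImR[:, i])
        out.append(_skew(v) @ R / theta2)
    return out


class _GaussianObjective:
    """Negative same-type Gaussian overlap of a rigidly moved site set,
    with analytic gradient over the 6 rigid-body parameters."""

    def __init__(self, by_a: dict[str, np.ndarray], by_b: dict[str, np.ndarray]):
        self.A = np.vstack(list(by_a.values()))
        self.B = np.vstack(list(by_b.values()))
        types_a = np.repeat(np.arange(len(by_a)), [len(v) for v in by_a.values()])
        types_b = np.repeat(np.arange(len(by_b)), [len(v) for v in by_b.values()])
        self.mask = types_a[:, None] == types_b[None, :]

    def overlap(self, params: np.ndarray) -> float:
        X = _rigid_apply(params, self.B)
        d2 = cdist(self.A, X, "sqeuclidean")
        return float(np.sum(_PAIR_PREFACTOR * np.exp(-0.5 * GAUSS_ALPHA * d2) * self.mask))

    def value_and_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        rotvec = params[:3]
        R = Rotation.from_rotvec(rotvec).as_matrix()
        X = self.B @ R.T + params[3:]
        diff = X[None, :, :] - self.A[:, None, :]  # (nA, nB, 3)
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        E = _PAIR_PREFACTOR * np.exp(-0.5 * GAUSS_ALPHA * d2) * self.mask
        value = float(E.sum())
        gX = -GAUSS_ALPHA * np.einsum("ij,ijk->jk", E, diff)  # dO/dX_j
        grad_t = gX.sum(axis=0)
        N = gX.T @ self.B  # pairs moved points with their gradients
        grad_rot = np.array(
            [np.sum(D * N) for D in _rotation_jacobian(rotvec, R)]
        )
        return -value, -np.concatenate([grad_rot, grad_t])


def _triplet_seeds(
    by_a: dict[str, np.ndarray], by_b: dict[str, np.ndarray], cap: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Kabsch seeds from same-type site correspondences.

    All 3-point correspondences with elementwise matching types are
    enumerated (capped at ``cap``, deterministically subsampled); with
    fewer than 3 matchable sites, 1- and 2-point translation seeds are used.
    """
    typed_a = [(t, i, c) for t, cs in sorted(by_a.items()) for i, c in enumerate(cs)]
    typed_b = [(t, i, c) for t, cs in sorted(by_b.items()) for i, c in enumerate(cs)]
    corrs = [
        (ca, cb) for (ta, _, ca) in typed_a for (tb, _, cb) in typed_b if ta == tb
    ]
    seeds: list[np.ndarray] = []
    triplets = list(itertools.combinations(range(len(corrs)), 3))
    if len(triplets) > cap:
        idx = rng.choice(len(triplets), size=cap, replace=False)
        triplets = [triplets[i] for i in sorted(idx)]
    for tri in triplets:
        P = np.array([corrs[i][1] for i in tri])  # moving (b)
        Q = np.array([corrs[i][0] for i in tri])  # fixed (a)
        if np.linalg.matrix_rank(P - P.mean(axis=0)) < 1:
            continue
        with warnings.catch_warnings():
            # collinear triplets leave one rotation axis free; any solution
            # is an acceptable seed
            warnings.simplefilter("ignore", UserWarning)
            R, _ = Rotation.align_vectors(Q - Q.mean(axis=0), P - P.mean(axis=0))
        rv = R.as_rotvec()
        t = Q.mean(axis=0) - R.apply(P.mean(axis=0))
        seeds.append(np.concatenate([rv, t]))
    if not seeds:
        for ca, cb in corrs[:cap]:  # translation-only site-on-site seeds
            seeds.append(np.concatenate([np.zeros(3), np.asarray(ca) - np.asarray(cb)]))
    return seeds


def align_pair(
    a: SiteSet,
    b: SiteSet,
    n_starts: int = 10,
    seed: int = 0,
    overlap_model: str = "gaussian",
    max_triplet_seeds: int = 12,
) -> AlignmentResult:
    """Rigid transform of ``b`` maximising its same-type overlap with ``a``.

    Multi-start local optimisation: the identity pose, a centroid-matching
    pose, Kabsch poses seeded from same-type site correspondences, and
    ``n_starts`` random orientations are each refined by quasi-Newton
    descent over the 6 rigid-body parameters; the best overlap wins.
    Random starts are drawn sequentially from a seeded generator, so the
    best overlap is non-decreasing in ``n_starts``.
    """
    shared = sorted(set(s.site_type for s in a.sites) & set(s.site_type for s in b.sites))
    if not shared:
        return AlignmentResult(np.eye(3), np.zeros(3), 0.0, n_starts)
    by_a = _typed_arrays(a, shared)
    by_b = _typed_arrays(b, shared)

    if overlap_model == "gaussian":
        obj = _GaussianObjective(by_a, by_b)
        objective, jac = obj.value_and_grad, True
        raw_overlap = obj.overlap
    else:
        pair = _OVERLAP_MODELS[overlap_model]
        all_a_arr = np.vstack(list(by_a.values()))
        all_b_arr = np.vstack(list(by_b.values()))
        slices, off = {}, 0
        for t in shared:
            slices[t] = slice(off, off + len(by_b[t]))
            off += len(by_b[t])

        def objective(params: np.ndarray) -> float:
            moved = _rigid_apply(params, all_b_arr)
            return -sum(
                float(np.sum(pair(cdist(by_a[t], moved[slices[t]]))))
                for t in shared
            )

        jac = False

        def raw_overlap(params: np.ndarray) -> float:
            return -objective(params)

    all_a = np.vstack(list(by_a.values()))
    all_b = np.vstack(list(by_b.values()))
    rng = np.random.default_rng(seed)
    starts = [np.zeros(6)]
    starts.append(np.concatenate([np.zeros(3), all_a.mean(axis=0) - all_b.mean(axis=0)]))
    starts.extend(_triplet_seeds(by_a, by_b, max_triplet_seeds, rng))
    for _ in range(n_starts):
        q = rng.normal(size=4)
        R = Rotation.from_quat(q / np.linalg.norm(q))
        t = all_a.mean(axis=0) - R.apply(all_b.mean(axis=0))
        starts.append(np.concatenate([R.as_rotvec(), t]))

    best_val, best_params = raw_overlap(np.zeros(6)), np.zeros(6)
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", jac=jac,
                       options={"maxiter": 100, "ftol": 1e-9})
        for cand in (x0, res.x):
            val = raw_overlap(cand)
            if val > best_val:
                best_val, best_params = float(val), cand.copy()

    R = Rotation.from_rotvec(best_params[:3]).as_matrix()
    return AlignmentResult(R, best_params[3:].copy(), best_val, n_starts)


# --- similarity score ------------------------------------------------------


def sim3d(
    a: SiteSet,
    b: SiteSet,
    n_starts: int = 10,
    seed: int = 0,
    overlap_model: str = "gaussian",
) -> float:
    """3D pharmacophoric similarity O(A,B)/max(O(A,A), O(B,B)) in [0, 1].

    The cross-overlap is maximised by rigid alignment; both alignment
    directions are tried and the larger overlap kept, since the score is
    symmetric in exact arithmetic but the numerical optimiser is not.
    Returns 0 when either molecule has no sites.
    """
    oa = self_overlap(a, overlap_model)
    ob = self_overlap(b, overlap_model)
    if oa <= 0.0 or ob <= 0.0:
        return 0.0
    o_ab = align_pair(a, b, n_starts, seed, overlap_model).overlap
    o_ba = align_pair(b, a, n_starts, seed, overlap_model).overlap
    score = max(o_ab, o_ba) / max(oa, ob)
    return float(min(max(score, 0.0), 1.0))


def build_similarity_matrix(
    mols: list[ConformerMolecule],
    n_starts: int = 10,
    seed: int = 0,
    overlap_model: str = "gaussian",
    zero_diagonal: bool = True,
    protonate: bool = True,
) -> SimilarityMatrix:
    """Pairwise sim3d over a drug library → symmetric similarity matrix Ma.

    The diagonal is zeroed by default (leave-one-out convention).  Rows and
    columns follow input order; duplicate drug ids are rejected.
    """
    ids = [m.drug_id for m in mols]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate drug_id in molecule list")
    site_sets = [perceive_sites(m, protonate=protonate) for m in mols]
    n = len(mols)
    S = np.zeros((n, n))
    for i in range(n):
        S[i, i] = 0.0 if zero_diagonal else (1.0 if len(site_sets[i]) else 0.0)
        for j in range(i + 1, n):
            # distinct deterministic seed per pair
            pair_seed = (seed * 1_000_003 + i * 8191 + j) % (2**31 - 1)
            S[i, j] = S[j, i] = sim3d(
                site_sets[i], site_sets[j], n_starts, pair_seed, overlap_model
            )
        logger.debug("similarity row %d/%d done", i + 1, n)
    return SimilarityMatrix(ids, S)
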