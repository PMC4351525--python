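"""Shared fixtures: small molecule conformers and a compact synthetic world.

Everything is generated at test time; heavyweight artefacts (conformer
embedding, the 3D similarity matrix of the shared world) are session-scoped
so they are computed once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import pharmsim as ps


@pytest.fixture(scope="session")
def benzene():
    return ps.embed_minimum_energy("c1ccccc1", "benzene", seed=7)


@pytest.fixture(scope="session")
def aspirin():
    return ps.embed_minimum_energy("CC(=O)Oc1ccccc1C(=O)O", "aspirin", seed=7)


@pytest.fixture(scope="session")
def ethane():
    return ps.embed_minimum_energy("CC", "ethane", seed=7)


def toy_sites(spec: list[tuple[str, tuple[float, float, float]]], drug_id: str = "toy") -> ps.SiteSet:
    return ps.SiteSet(drug_id, [ps.PharmacophoreSite(t, c) for t, c in spec])


@pytest.fixture(scope="session")
def small_world():
    """30-drug, 6-cluster, 20-ADE synthetic world used across modules."""
    return ps.make_world(
        n_drugs=30, n_ades=20, n_clusters=6, label_noise=0.05, seed=11
    )


@pytest.fixture(scope="session")
def small_world_conformers(small_world):
    return [
        ps.embed_minimum_energy(smi, drug_id, n_confs=20, seed=100 + i)
        for i, (drug_id, smi) in enumerate(
            zip(small_world.smiles_table["drug_id"], small_world.smiles_table["smiles"])
        )
    ]


@pytest.fixture(scope="session")
def small_world_ma3d(small_world_conformers):
    """3D similarity matrix of the shared world (computed once per session)."""
    return ps.build_similarity_matrix(small_world_conformers, n_starts=4, seed=5)


@pytest.fixture(scope="session")
def small_world_ma2d(small_world):
    return ps.build_2d_matrix(small_world.smiles_table)


def random_instance(rng: np.random.Generator, n_drugs: int = 6, n_ades: int = 3):
    """A random (Ma, Mb) pair for brute-force cross-checks."""
    S = rng.random((n_drugs, n_drugs))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 0.0)
    drugs = [f"d{i}" for i in range(n_drugs)]
    M = np.zeros((n_drugs, n_ades), dtype=np.int8)
    while M.sum(axis=0).min() == 0:  # every ADE needs >=1 positive
        M = (rng.random((n_drugs, n_ades)) < 0.4).astype(np.int8)
    ma = ps.SimilarityMatrix(drugs, S)
    mb = ps.ReferenceStandard(drugs, [f"a{k}" for k in range(n_ades)], M)
    return ma, mb
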