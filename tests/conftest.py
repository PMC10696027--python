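import numpy as np
import pytest

from csncrit.mcs import MolecularGraph, SimilarityStore
from csncrit.synth import generate_planted_store, three_archetypes_preset


@pytest.fixture(scope="session")
def preset_molecules():
    """Three-archetypes synthetic set, small enough for fast MCS tests."""
    return three_archetypes_preset(seed=11, n_members=12)


@pytest.fixture(scope="session")
def planted_store():
    """3 families x 20 nodes, within (0.75, 0.95) vs between (0.30, 0.45)."""
    return generate_planted_store(
        n_families=3,
        family_size=20,
        within_sim=(0.75, 0.95),
        between_sim=(0.30, 0.45),
        seed=5,
    )


@pytest.fixture
def tiny_store():
    """Three molecules A, B, C with pairwise similarities 0.9, 0.5, 0.31."""
    store = SimilarityStore(ids=["A", "B", "C"], floor=0.3)
    store.entries = {(0, 1): 0.9, (0, 2): 0.5, (1, 2): 0.31}
    return store


@pytest.fixture(scope="session")
def small_graphs():
    """Molecular graphs of <= 8 heavy atoms, written in varied notations."""
    smiles = [
        "CC", "CCC", "CCO", "C", "N", "CCN", "c1ccccc1", "Cc1ccccc1",
        "C1CCCCC1", "CC(C)O", "C=CC", "C#CC", "CC=O", "COC", "C1CC1",
        "c1ccncc1", "OCC(N)C", "CC(C)(C)C", "C1CCC1", "CNC(C)=O",
    ]
    return {s: MolecularGraph.from_smiles(s) for s in smiles}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
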