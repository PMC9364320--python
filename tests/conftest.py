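import numpy as np
import pytest
from hypothesis import settings

from macaw import MacawEmbedder, MoleculeRecord, make_synthetic_set

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def surrogate_set():
    """Mixed-family synthetic set with noise-free surrogate property values."""
    return make_synthetic_set(300, seed=11)


@pytest.fixture(scope="session")
def surrogate_records(surrogate_set):
    return [
        MoleculeRecord(s, y=float(v))
        for s, v in zip(surrogate_set.smiles, surrogate_set.y)
    ]


@pytest.fixture(scope="session")
def alkane_records():
    """Linear + branched alkanes only (no heteroatoms, no unsaturation)."""
    s = make_synthetic_set(
        60, {"linear_alkane": 0.25, "branched_alkane": 0.75}, seed=5
    )
    return [MoleculeRecord(sm, y=float(v)) for sm, v in zip(s.smiles, s.y)]


@pytest.fixture(scope="session")
def trained_embedder(surrogate_records):
    emb = MacawEmbedder(n_landmarks=50, n_components=15, seed=3)
    emb.train(surrogate_records)
    return emb


@pytest.fixture(scope="session")
def generator_seeds():
    """20-molecule seed set for the generator."""
    s = make_synthetic_set(
        20, {"branched_alkane": 0.5, "alcohol": 0.3, "alkene": 0.2}, seed=7
    )
    return s.smiles
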