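"""Fingerprints, similarity metrics and the similarity-to-distance conversion."""

import itertools

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from hypothesis import given, settings, strategies as st

from macaw.chem_distance import (
    FINGERPRINT_TYPES,
    SIMILARITY_METRICS,
    SYMMETRIC_METRICS,
    FingerprintSpec,
    InvalidMoleculeError,
    MoleculeRecord,
    compute_fingerprint,
    pairwise_distances,
    similarity,
    similarity_to_distance,
)

MOLS = ["CC", "CCO", "c1ccccc1"]


# -- fingerprints -----------------------------------------------------------

def test_fingerprint_deterministic_and_lengths():
    fp1 = compute_fingerprint("CCO", "morgan2")
    fp2 = compute_fingerprint("CCO", "morgan2")
    assert np.array_equal(fp1, fp2)
    assert compute_fingerprint("CCO", "maccs").size == 167  # MACCS standard key count
    concat = compute_fingerprint("CCO", "pattern + atompairs")
    assert concat.size == (
        compute_fingerprint("CCO", "pattern").size
        + compute_fingerprint("CCO", "atompairs").size
    )
    assert np.array_equal(
        concat,
        np.concatenate(
            [compute_fingerprint("CCO", "pattern"), compute_fingerprint("CCO", "atompairs")]
        ),
    )


@pytest.mark.parametrize("name", sorted(FINGERPRINT_TYPES))
def test_every_fingerprint_type_produces_bits(name):
    fp = compute_fingerprint("CC(C)CO", name)
    assert fp.dtype == bool and fp.sum() > 0


def test_fingerprint_errors():
    with pytest.raises(InvalidMoleculeError, match="xyz"):
        compute_fingerprint("xyz(", "morgan2")
    with pytest.raises(ValueError, match="unknown fingerprint"):
        FingerprintSpec.parse("morgan99")


def test_spec_parsing_order():
    assert FingerprintSpec.parse("pattern + atompairs").parts == ("pattern", "atompairs")


# -- similarity metrics -----------------------------------------------------

def test_tanimoto_and_dice_hand_counts():
    x = np.array([1, 1, 0, 0], bool)
    y = np.array([1, 0, 1, 0], bool)
    assert similarity(x, y, "tanimoto") == pytest.approx(1 / 3)
    assert similarity(x, y, "dice") == pytest.approx(0.5)


def test_tanimoto_matches_hand_formula_on_exhaustive_4bit_vectors():
    """c/(a+b-c) over all 256x256 4-bit pairs (degenerate pairs excluded)."""
    vecs = [np.array(bits, bool) for bits in itertools.product([0, 1], repeat=4)]
    for x in vecs:
        for y in vecs:
            a, b, c = x.sum(), y.sum(), (x & y).sum()
            if a == 0 or b == 0:
                continue
            assert similarity(x, y, "tanimoto") == pytest.approx(c / (a + b - c))


@pytest.mark.parametrize("metric", sorted(set(SIMILARITY_METRICS) - {"blay-roger"}))
def test_self_similarity_is_one(metric):
    fp = compute_fingerprint("CCO", "morgan2")
    assert similarity(fp, fp, metric) == pytest.approx(1.0)


@pytest.mark.parametrize("metric", sorted(SYMMETRIC_METRICS))
def test_symmetric_metrics_are_exactly_symmetric(metric):
    for s1, s2 in itertools.combinations(MOLS, 2):
        f1, f2 = compute_fingerprint(s1, "morgan2"), compute_fingerprint(s2, "morgan2")
        assert similarity(f1, f2, metric) == similarity(f2, f1, metric)


_RDKIT_ORACLE = {
    "tanimoto": DataStructs.TanimotoSimilarity,
    "dice": DataStructs.DiceSimilarity,
    "cosine": DataStructs.CosineSimilarity,
    "sokal": DataStructs.SokalSimilarity,
    "kulczynski": DataStructs.KulczynskiSimilarity,
    "braun-blanquet": DataStructs.BraunBlanquetSimilarity,
    "rogot-goldberg": DataStructs.RogotGoldbergSimilarity,
    "asymmetric": DataStructs.AsymmetricSimilarity,
}


@pytest.mark.parametrize("metric", sorted(_RDKIT_ORACLE))
def test_similarity_formulas_match_rdkit(metric):
    """Our bit-count formulas agree with the toolkit's reference implementations."""
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    for s1, s2 in itertools.combinations(MOLS + ["CC(C)O", "CCCC"], 2):
        bv1 = gen.GetFingerprint(Chem.MolFromSmiles(s1))
        bv2 = gen.GetFingerprint(Chem.MolFromSmiles(s2))
        f1 = compute_fingerprint(s1, "morgan2")
        f2 = compute_fingerprint(s2, "morgan2")
        assert similarity(f1, f2, metric) == pytest.approx(
            _RDKIT_ORACLE[metric](bv1, bv2), abs=1e-12
        )


def test_mcconnaughey_is_rescaled_rdkit():
    f1, f2 = compute_fingerprint("CC", "morgan2"), compute_fingerprint("CCO", "morgan2")
    bv = lambda s: FINGERPRINT_TYPES["morgan2"](Chem.MolFromSmiles(s))
    raw = DataStructs.McConnaugheySimilarity(bv("CC"), bv("CCO"))
    assert similarity(f1, f2, "mcconnaughey") == pytest.approx((raw + 1) / 2)


def test_manhattan_similarity_is_one_minus_hamming_fraction():
    x = np.array([1, 1, 0, 0], bool)
    y = np.array([1, 0, 1, 0], bool)
    assert similarity(x, y, "manhattan") == pytest.approx(1 - 2 / 4)


def test_blay_roger_not_implemented():
    fp = compute_fingerprint("CC", "morgan2")
    with pytest.raises(NotImplementedError):
        similarity(fp, fp, "blay-roger")


def test_similarity_edge_cases():
    with pytest.raises(ValueError, match="mismatch"):
        similarity(np.ones(4, bool), np.ones(5, bool))
    with pytest.warns(UserWarning, match="all-zero"):
        assert similarity(np.zeros(4, bool), np.zeros(4, bool)) == 1.0
    assert similarity(np.zeros(4, bool), np.ones(4, bool)) == 0.0
    with pytest.raises(ValueError, match="unknown similarity"):
        similarity(np.ones(4, bool), np.ones(4, bool), "nope")


@settings(deadline=None, max_examples=100)
@given(st.integers(0, 2**31 - 1))
def test_similarity_range_and_symmetry_property(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, 64).astype(bool)
    y = rng.integers(0, 2, 64).astype(bool)
    if not x.any() or not y.any():
        return
    for metric in sorted(set(SIMILARITY_METRICS) - {"blay-roger"}):
        s = similarity(x, y, metric)
        assert 0.0 <= s <= 1.0
        if metric in SYMMETRIC_METRICS:
            assert s == similarity(y, x, metric)


# -- similarity -> distance -------------------------------------------------

def test_similarity_to_distance_endpoints_and_monotonicity():
    assert similarity_to_distance(1.0) == 0.0
    assert similarity_to_distance(0.0) == 1.0
    assert similarity_to_distance(0.25) == 0.75
    grid = np.arange(0, 1.01, 0.1)
    d = np.array([similarity_to_distance(s) for s in grid])
    assert np.all(np.diff(d) < 0)
    assert np.all((d >= 0) & (d <= 1))
    with pytest.raises(ValueError):
        similarity_to_distance(1.5)


# -- pairwise distances -----------------------------------------------------

def test_pairwise_single_molecule_zero():
    rec = [MoleculeRecord.from_smiles("CCO")]
    M = pairwise_distances(rec, None, "morgan2", "tanimoto")
    assert M.shape == (1, 1) and M[0, 0] == pytest.approx(0.0)


@pytest.mark.parametrize("metric", ["tanimoto", "dice", "rogot-goldberg"])
def test_pairwise_matches_bruteforce_double_loop(metric, surrogate_records):
    recs = surrogate_records[:12]
    M = pairwise_distances(recs, None, "morgan2", metric)
    assert np.allclose(M, M.T)
    assert np.allclose(np.diag(M), 0.0)
    fps = [compute_fingerprint(r, "morgan2") for r in recs]
    for i in range(len(recs)):
        for j in range(len(recs)):
            expect = similarity_to_distance(similarity(fps[i], fps[j], metric))
            assert M[i, j] == pytest.approx(expect, abs=1e-12)


def test_pairwise_handpicked_molecules_match_elementwise():
    recs = [MoleculeRecord.from_smiles(s) for s in ("CC", "CCO", "c1ccccc1")]
    M = pairwise_distances(recs, None, "morgan2", "tanimoto")
    for i, ri in enumerate(recs):
        for j, rj in enumerate(recs):
            s = similarity(
                compute_fingerprint(ri, "morgan2"),
                compute_fingerprint(rj, "morgan2"),
                "tanimoto",
            )
            assert M[i, j] == pytest.approx(1 - s)


def test_pairwise_error_includes_index():
    recs = [MoleculeRecord("CC"), MoleculeRecord("oops(")]
    with pytest.raises(InvalidMoleculeError, match="record 1"):
        pairwise_distances(recs, None, "morgan2", "tanimoto")
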