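"""Landmark selection, classic MDS, triangulation, and the embedder contract."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from macaw.chem_distance import MoleculeRecord, pairwise_distances
from macaw.embedder import (
    MacawEmbedder,
    classic_mds,
    select_landmarks,
    triangulate,
    _mds_eig,
    _triangulation_operator,
)

SQRT2 = np.sqrt(2.0)
UNIT_SQUARE = np.array(
    [[0, 1, SQRT2, 1], [1, 0, 1, SQRT2], [SQRT2, 1, 0, 1], [1, SQRT2, 1, 0]]
)


# -- landmark selection -----------------------------------------------------

def test_random_selection_exhaustive_when_L_equals_N():
    recs = [MoleculeRecord("C") for _ in range(50)]
    ls = select_landmarks(recs, 50, "random", seed=0)
    assert sorted(ls.indices) == list(range(50))


def test_highest_and_lowest_modes():
    recs = [MoleculeRecord("C", y=v) for v in [1, 2, 3, 4, 100]]
    assert select_landmarks(recs, 1, "highest").indices == (4,)
    assert select_landmarks(recs, 1, "lowest").indices == (0,)


def test_binned_selection_equalizes_bin_probability():
    """90/10 split across two occupied bins: each draw picks bin 2 w.p. ~1/2."""
    recs = [MoleculeRecord("C", y=1.0)] * 90 + [MoleculeRecord("C", y=10.0)] * 10
    hits = sum(
        i >= 90
        for s in range(2000)
        for i in select_landmarks(recs, 2, "binned", 10, seed=s).indices
    )
    assert hits / 4000 == pytest.approx(0.5, abs=0.05)


def test_selection_errors():
    recs = [MoleculeRecord("C", y=1.0)] * 5
    with pytest.raises(ValueError, match="exceeds"):
        select_landmarks(recs, 6, "random")
    with pytest.raises(ValueError, match="property values"):
        select_landmarks([MoleculeRecord("C")] * 5, 2, "binned")


# -- classic MDS ------------------------------------------------------------

def test_mds_collinear_points_recover_line_geometry():
    D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
    coords, evals = classic_mds(D, 1)
    x = np.sort(coords.ravel())
    assert np.allclose(x, [-1, 0, 1], atol=1e-9)
    assert np.abs(squareform(pdist(coords)) - D).max() < 1e-9
    assert np.all(np.diff(evals) <= 1e-12)  # descending


def test_mds_unit_square_reproduces_all_distances():
    coords, _ = classic_mds(UNIT_SQUARE, 2)
    assert np.abs(squareform(pdist(coords)) - UNIT_SQUARE).max() < 1e-9


def test_mds_full_rank_reconstructs_euclidean_input():
    rng = np.random.default_rng(0)
    pts = rng.standard_normal((12, 4))
    D = squareform(pdist(pts))
    coords, _ = classic_mds(D, 12)
    assert np.abs(squareform(pdist(coords)) - D).max() < 1e-8


def test_mds_input_validation():
    with pytest.raises(ValueError, match="symmetric"):
        classic_mds(np.array([[0, 1], [2, 0]], float), 1)
    with pytest.raises(ValueError, match="nonnegative"):
        classic_mds(np.array([[0, -1], [-1, 0]], float), 1)


def test_mds_deterministic_sign_convention():
    c1, _ = classic_mds(UNIT_SQUARE, 2)
    c2, _ = classic_mds(UNIT_SQUARE.copy(), 2)
    assert np.array_equal(c1, c2)


# -- triangulation ----------------------------------------------------------

def test_triangulate_recovers_landmarks_and_centroid():
    evals, evecs = _mds_eig(UNIT_SQUARE)
    P = _triangulation_operator(evecs, evals, 2)
    mean_sq = (UNIT_SQUARE**2).mean(axis=0)
    coords, _ = classic_mds(UNIT_SQUARE, 2)
    assert np.abs(triangulate(UNIT_SQUARE, P, mean_sq) - coords).max() < 1e-9
    center = triangulate(np.full(4, SQRT2 / 2), P, mean_sq)
    assert np.abs(center).max() < 1e-9
    # determinism
    q = np.array([0.3, 0.7, 1.1, 0.9])
    assert np.array_equal(triangulate(q, P, mean_sq), triangulate(q, P, mean_sq))


# -- embedder train/transform ----------------------------------------------

def test_train_is_deterministic_given_seed(surrogate_records):
    e1 = MacawEmbedder(n_landmarks=30, n_components=10, seed=7).train(surrogate_records)
    e2 = MacawEmbedder(n_landmarks=30, n_components=10, seed=7).train(surrogate_records)
    assert e1.landmarks.indices == e2.landmarks.indices
    assert np.array_equal(e1.landmark_coords, e2.landmark_coords)


def test_projector_self_map_on_landmarks(trained_embedder):
    E = trained_embedder.transform(trained_embedder.landmark_smiles)
    assert np.abs(E.coords - trained_embedder.landmark_coords).max() < 1e-8


def test_pca_coordinates_are_centered(surrogate_records):
    emb = MacawEmbedder(
        n_landmarks=30, n_components=5, algorithm="pca", seed=1
    ).train(surrogate_records)
    assert np.abs(emb.landmark_coords.mean(axis=0)).max() < 1e-10


def test_transform_counts_exactly_N_times_L(trained_embedder, surrogate_set):
    emb = trained_embedder
    before = emb.n_distance_computations
    emb.transform(surrogate_set.smiles[:37])
    assert emb.n_distance_computations - before == 37 * emb.n_landmarks


def test_fit_transform_equals_train_then_transform(surrogate_records):
    e1 = MacawEmbedder(n_landmarks=30, n_components=10, seed=2)
    E1 = e1.fit_transform(surrogate_records)
    e2 = MacawEmbedder(n_landmarks=30, n_components=10, seed=2).train(surrogate_records)
    E2 = e2.transform(surrogate_records)
    assert np.array_equal(E1.coords, E2.coords)


def test_transform_rejects_invalid_smiles(trained_embedder):
    with pytest.raises(ValueError, match=r"\[1\]"):
        trained_embedder.transform(["CC", "bad(", "CCO"])


def test_train_requires_enough_molecules(surrogate_records):
    with pytest.raises(ValueError, match="n_landmarks"):
        MacawEmbedder(n_landmarks=50, n_components=5).train(surrogate_records[:10])


# -- setters ----------------------------------------------------------------

def test_set_n_components_truncates_mds_columns(surrogate_records, surrogate_set):
    emb = MacawEmbedder(n_landmarks=40, n_components=15, seed=9).train(surrogate_records)
    full = emb.transform(surrogate_set.smiles[:20]).coords
    before = emb.n_distance_computations
    emb.set_n_components(5)
    assert emb.n_distance_computations == before  # caching contract
    trunc = emb.transform(surrogate_set.smiles[:20]).coords
    assert np.array_equal(trunc, full[:, :5])


def test_set_metric_equals_fresh_training_with_same_landmarks(surrogate_records):
    emb = MacawEmbedder(n_landmarks=30, n_components=10, seed=4).train(surrogate_records)
    emb.set_metric("dice")
    fresh = MacawEmbedder(
        n_landmarks=30, n_components=10, metric="dice", seed=4
    ).train(surrogate_records)
    assert emb.landmarks.indices == fresh.landmarks.indices
    smiles = [r.smiles for r in surrogate_records[:15]]
    assert np.allclose(emb.transform(smiles).coords, fresh.transform(smiles).coords)


def test_set_type_fp_equals_fresh_training(surrogate_records):
    emb = MacawEmbedder(n_landmarks=30, n_components=10, seed=4).train(surrogate_records)
    emb.set_type_fp("maccs")
    fresh = MacawEmbedder(
        type_fp="maccs", n_landmarks=30, n_components=10, seed=4
    ).train(surrogate_records)
    smiles = [r.smiles for r in surrogate_records[:15]]
    assert np.allclose(emb.transform(smiles).coords, fresh.transform(smiles).coords)


def test_set_n_components_validates_dimension(trained_embedder):
    with pytest.raises(ValueError, match="exceed"):
        trained_embedder.set_n_components(trained_embedder.n_landmarks + 1)


def test_set_algorithm_reuses_distances(surrogate_records):
    emb = MacawEmbedder(n_landmarks=30, n_components=5, seed=4).train(surrogate_records)
    before = emb.n_distance_computations
    emb.set_algorithm("pca")
    assert emb.n_distance_computations == before
    X = emb.transform([r.smiles for r in surrogate_records[:5]]).coords
    assert np.isfinite(X).all() and X.shape == (5, 5)


# -- geometric invariants ---------------------------------------------------

def test_isometry_at_full_rank_for_euclidean_input():
    rng = np.random.default_rng(3)
    pts = rng.standard_normal((20, 5))
    D = squareform(pdist(pts))
    coords, _ = classic_mds(D, 20)
    rms = np.sqrt(((squareform(pdist(coords)) - D) ** 2).mean())
    assert rms < 1e-6


def test_mds_reconstruction_error_nonincreasing_in_D(trained_embedder):
    D = trained_embedder.landmark_dist
    errs = []
    for d in (2, 5, 10, 20, 40):
        coords, _ = classic_mds(D, d)
        errs.append(np.sqrt(((squareform(pdist(coords)) - D) ** 2).mean()))
    assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))


def test_similar_molecules_embed_nearby(alkane_records):
    """Fingerprint distance and embedding distance correlate strongly."""
    emb = MacawEmbedder(n_landmarks=40, n_components=10, seed=6).train(alkane_records)
    E = emb.transform([r.smiles for r in alkane_records]).coords
    fp_d = pairwise_distances(alkane_records, None, "morgan2", "tanimoto")
    emb_d = squareform(pdist(E))
    iu = np.triu_indices(len(alkane_records), k=1)
    rho = spearmanr(fp_d[iu], emb_d[iu]).statistic
    assert rho > 0.5


def test_cv_performance_does_not_degrade_with_more_dimensions(surrogate_records):
    """Predictive power at D=25 is at least that at D=5 minus a small margin."""
    from sklearn.model_selection import cross_val_score
    from sklearn.svm import SVR

    y = np.array([r.y for r in surrogate_records])
    emb = MacawEmbedder(n_landmarks=50, n_components=25, seed=8).train(surrogate_records)
    X25 = emb.transform([r.smiles for r in surrogate_records]).coords
    X5 = X25[:, :5]  # eigen-truncation property of classic MDS
    svr = lambda: SVR(kernel="rbf", C=100, epsilon=0.1)
    r2_25 = cross_val_score(svr(), X25, y, cv=5, scoring="r2").mean()
    r2_5 = cross_val_score(svr(), X5, y, cv=5, scoring="r2").mean()
    assert r2_25 >= r2_5 - 0.05
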