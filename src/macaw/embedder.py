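"""Landmark-MDS molecular embedding.

A small set of L landmark molecules is selected from the training list, the
L x L fingerprint-distance matrix between landmarks is projected with classic
(Torgerson) multidimensional scaling, and any further molecule is placed in
the D-dimensional space by distance-based triangulation against the landmarks
(de Silva & Tenenbaum landmark MDS).  Embedding N molecules therefore costs
exactly N*L molecule-molecule distance computations.

Alternative projection algorithms (isomap, PCA, ICA, factor analysis) operate
on the landmarks' distance-to-landmark row vectors and are applied to query
distance rows, preserving the O(N*L) transform cost.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path
from sklearn.decomposition import PCA, FastICA, FactorAnalysis

from .chem_distance import (
    FingerprintSpec,
    MoleculeRecord,
    _fingerprint_matrix,
    pairwise_distances,
)

__all__ = ["LandmarkSet", "Embedding", "MacawEmbedder", "select_landmarks",
           "classic_mds", "triangulate"]


# ---------------------------------------------------------------------------
# Landmark selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkSet:
    indices: tuple[int, ...]
    mode: str
    n_bins: int
    seed: int


def select_landmarks(
    records: Sequence[MoleculeRecord],
    n_landmarks: int,
    mode: str = "random",
    n_bins: int = 10,
    seed: int = 0,
) -> LandmarkSet:
    """Choose landmark molecule indices.

    Modes: ``random`` — uniform without replacement; ``binned`` — property
    values are split into ``n_bins`` equal-width bins and each draw first
    picks a non-exhausted bin uniformly, then a member uniformly, so sparse
    bins are represented as often as dense ones; ``highest``/``lowest`` — the
    top/bottom ``n_landmarks`` by property value (ties by input order).
    """
    N = len(records)
    if n_landmarks > N:
        raise ValueError(f"n_landmarks={n_landmarks} exceeds dataset size {N}")
    rng = np.random.default_rng(seed)
    if mode == "random":
        idx = tuple(int(i) for i in rng.choice(N, size=n_landmarks, replace=False))
        return LandmarkSet(idx, mode, n_bins, seed)
    y = np.array([r.y for r in records], dtype=object)
    if any(v is None for v in y):
        raise ValueError(f"landmark mode {mode!r} requires property values for all records")
    y = y.astype(float)
    if mode in ("highest", "lowest"):
        order = np.argsort(-y if mode == "highest" else y, kind="stable")
        return LandmarkSet(tuple(int(i) for i in order[:n_landmarks]), mode, n_bins, seed)
    if mode != "binned":
        raise ValueError(f"unknown landmark mode {mode!r}")
    edges = np.linspace(y.min(), y.max(), n_bins + 1)
    bin_of = np.clip(np.digitize(y, edges[1:-1]), 0, n_bins - 1)
    remaining = {b: list(np.flatnonzero(bin_of == b)) for b in range(n_bins)}
    chosen: list[int] = []
    while len(chosen) < n_landmarks:
        nonempty = [b for b, mem in remaining.items() if mem]
        b = nonempty[rng.integers(len(nonempty))]
        j = rng.integers(len(remaining[b]))
        chosen.append(int(remaining[b].pop(j)))
    return LandmarkSet(tuple(chosen), mode, n_bins, seed)


# ---------------------------------------------------------------------------
# Classic MDS and triangulation
# ---------------------------------------------------------------------------

def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the largest-magnitude entry is positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def classic_mds(distmat: np.ndarray, n_components: int):
    """Torgerson MDS of a symmetric distance matrix.

    Double-centers the squared distances, B = -1/2 J D^2 J, and returns the
    top-``n_components`` coordinates (eigenvectors scaled by sqrt of the
    clipped eigenvalues) along with the full eigenvalue spectrum in
    descending order.  Directions with non-positive eigenvalues get zero
    coordinates: fingerprint distances need not be Euclidean-realizable.
    """
    evals, evecs = _mds_eig(distmat)
    if n_components > len(evals):
        raise ValueError(f"n_components={n_components} exceeds n_landmarks={len(evals)}")
    scale = np.sqrt(_effective_evals(evals)[:n_components])
    coords = evecs[:, :n_components] * scale[None, :]
    return coords, evals


def _effective_evals(evals: np.ndarray) -> np.ndarray:
    """Clip eigenvalues: non-positive and near-zero directions are degenerate.

    A relative cutoff (1e-9 of the leading eigenvalue) keeps triangulation
    numerically stable — dividing by sqrt of a vanishing eigenvalue would
    amplify rounding noise — and zeroes the corresponding coordinates.
    """
    tol = 1e-9 * max(float(evals.max(initial=0.0)), 0.0)
    return np.where(evals > tol, evals, 0.0)


def _mds_eig(distmat: np.ndarray):
    """Eigendecomposition of the double-centered squared-distance matrix."""
    D = np.asarray(distmat, dtype=float)
    L = D.shape[0]
    if D.shape != (L, L):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < -1e-12):
        raise ValueError("distance matrix must be nonnegative")
    J = np.eye(L) - np.full((L, L), 1.0 / L)
    B = -0.5 * J @ (D * D) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    return evals[order], _fix_signs(evecs[:, order])


def _triangulation_operator(evecs: np.ndarray, evals: np.ndarray, n_components: int) -> np.ndarray:
    """Pseudoinverse operator mapping centered squared distances to coordinates.

    Row k is eigvec_k / sqrt(eigval_k) for positive eigenvalues and zero
    otherwise, so triangulated coordinates live in the same axes as the
    landmark MDS coordinates.
    """
    eff = _effective_evals(evals)
    P = np.zeros((n_components, evecs.shape[0]))
    for k in range(n_components):
        if eff[k] > 0:
            P[k] = evecs[:, k] / np.sqrt(eff[k])
    return P


def triangulate(delta: np.ndarray, P: np.ndarray, mean_sq_row: np.ndarray) -> np.ndarray:
    """Place points given their distances to the landmarks.

    ``x = -1/2 P (delta^2 - mean_sq_row)`` where ``mean_sq_row`` is the column
    mean of the squared landmark distance matrix.  Accepts a single length-L
    row or an N x L matrix.
    """
    delta = np.asarray(delta, dtype=float)
    single = delta.ndim == 1
    d2 = np.atleast_2d(delta) ** 2
    X = -0.5 * (d2 - mean_sq_row[None, :]) @ P.T
    return X[0] if single else X


# ---------------------------------------------------------------------------
# Embedder
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    coords: np.ndarray
    smiles: list[str]


_ALGORITHMS = ("mds", "isomap", "pca", "ica", "fa")


class MacawEmbedder:
    """Trainable landmark-MDS molecular embedder.

    Parameters
    ----------
    type_fp:
        Fingerprint type or ``+``-joined combination (default ``morgan2``).
    metric:
        Bit-vector similarity metric name (default ``tanimoto``).
    n_components:
        Embedding dimensionality D (default 15, must satisfy D <= L).
    n_landmarks:
        Number of landmark molecules L (default 50).
    algorithm:
        Projection algorithm: ``mds`` (default), ``isomap``, ``pca``, ``ica``
        or ``fa``.
    landmark_mode / n_bins:
        Landmark selection strategy (see :func:`select_landmarks`).
    isomap_k:
        Neighbourhood size of the geodesic graph for ``isomap``.
    seed:
        Seed for landmark selection and stochastic projections.

    The instrumentation attribute ``n_distance_computations`` counts
    molecule-to-landmark distance evaluations; ``transform`` on N molecules
    adds exactly N*L to it.
    """

    def __init__(
        self,
        type_fp: str = "morgan2",
        metric: str = "tanimoto",
        n_components: int = 15,
        n_landmarks: int = 50,
        algorithm: str = "mds",
        landmark_mode: str = "random",
        n_bins: int = 10,
        isomap_k: int = 5,
        seed: int = 0,
    ):
        if algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}; known: {_ALGORITHMS}")
        if n_components > n_landmarks:
            raise ValueError("n_components must not exceed n_landmarks")
        self.spec = FingerprintSpec.parse(type_fp)
        self.metric = metric
        self.n_components = n_components
        self.n_landmarks = n_landmarks
        self.algorithm = algorithm
        self.landmark_mode = landmark_mode
        self.n_bins = n_bins
        self.isomap_k = isomap_k
        self.seed = seed
        self.n_distance_computations = 0
        self._trained = False
        self.landmarks: Optional[LandmarkSet] = None
        self.landmark_smiles: Optional[list[str]] = None
        self.landmark_fps: Optional[np.ndarray] = None
        self.landmark_dist: Optional[np.ndarray] = None

    # -- training ----------------------------------------------------------

    def train(self, records: Sequence[MoleculeRecord]) -> "MacawEmbedder":
        """Select landmarks, cache their fingerprints/distances, fit projector."""
        records = [
            r if isinstance(r, MoleculeRecord) else MoleculeRecord.from_smiles(r)
            for r in records
        ]
        if len(records) < self.n_landmarks:
            raise ValueError(
                f"need at least n_landmarks={self.n_landmarks} molecules, got {len(records)}"
            )
        self.landmarks = select_landmarks(
            records, self.n_landmarks, self.landmark_mode, self.n_bins, self.seed
        )
        lm = [records[i] for i in self.landmarks.indices]
        self.landmark_smiles = [r.smiles for r in lm]
        self.landmark_fps = _fingerprint_matrix(lm, self.spec)
        self.landmark_dist = pairwise_distances(
            lm, None, self.spec, self.metric, fps_A=self.landmark_fps
        )
        self.n_distance_computations += self.n_landmarks * self.n_landmarks
        self._fit_projector()
        self._trained = True
        return self

    def _fit_projector(self) -> None:
        D = self.landmark_dist
        L = self.n_landmarks
        if self.algorithm in ("mds", "isomap"):
            Dp = self._geodesic(D) if self.algorithm == "isomap" else D
            # full-rank eigendecomposition is cached so set_n_components is free
            evals, evecs = _mds_eig(Dp)
            self._mds_evals = evals
            self._mds_evecs_full = evecs
            self._proj_base = Dp
            self._mean_sq_row = (Dp ** 2).mean(axis=0)
            self._P = _triangulation_operator(evecs, evals, self.n_components)
            scale = np.sqrt(_effective_evals(evals)[: self.n_components])
            self.landmark_coords = evecs[:, : self.n_components] * scale[None, :]
            self.eigenvalues = evals
        else:
            est = {
                "pca": lambda: PCA(n_components=self.n_components, random_state=self.seed),
                "ica": lambda: FastICA(
                    n_components=self.n_components, random_state=self.seed, max_iter=2000
                ),
                "fa": lambda: FactorAnalysis(
                    n_components=self.n_components, random_state=self.seed
                ),
            }[self.algorithm]()
            self._estimator = est.fit(D)
            self.landmark_coords = est.transform(D)
            self.eigenvalues = None

    def _geodesic(self, D: np.ndarray) -> np.ndarray:
        """Geodesic landmark distances over a k-nearest-neighbour graph."""
        L = D.shape[0]
        k = min(self.isomap_k, L - 1)
        G = np.full_like(D, np.inf)
        for i in range(L):
            nn = np.argsort(D[i], kind="stable")[: k + 1]
            G[i, nn] = D[i, nn]
        G = np.minimum(G, G.T)
        np.fill_diagonal(G, 0.0)
        geo = shortest_path(G, method="D", directed=False)
        if np.isinf(geo).any():  # disconnected graph: bridge with raw distances
            geo = np.where(np.isinf(geo), D, geo)
        return geo

    # -- embedding ---------------------------------------------------------

    def _require_trained(self):
        if not self._trained:
            raise RuntimeError("embedder is not trained; call train() first")

    def _query_distances(self, smiles_list: Sequence[str]) -> np.ndarray:
        bad = []
        records = []
        for i, s in enumerate(smiles_list):
            try:
                records.append(MoleculeRecord.from_smiles(s) if isinstance(s, str) else s)
            except Exception:
                bad.append(i)
        if bad:
            raise ValueError(f"invalid SMILES at indices {bad}")
        delta = pairwise_distances(
            records, None, self.spec, self.metric, fps_B=self.landmark_fps
        )
        self.n_distance_computations += len(records) * self.n_landmarks
        return delta

    def _project_rows(self, delta: np.ndarray) -> np.ndarray:
        if self.algorithm in ("mds", "isomap"):
            if self.algorithm == "isomap":
                # geodesic correction: route each query-landmark distance
                # through the nearest landmark on the geodesic graph
                delta = np.min(delta[:, :, None] + self._proj_base[None, :, :], axis=1)
            return triangulate(delta, self._P, self._mean_sq_row)
        return self._estimator.transform(delta)

    def transform(self, smiles_list: Sequence[str]) -> Embedding:
        """Embed N molecules with exactly N*L new distance computations."""
        self._require_trained()
        smiles = [
            s.smiles if isinstance(s, MoleculeRecord) else s for s in smiles_list
        ]
        delta = self._query_distances(smiles)
        coords = self._project_rows(delta)
        return Embedding(np.asarray(coords, dtype=float), smiles)

    def fit_transform(self, records: Sequence[MoleculeRecord]) -> Embedding:
        """Train and embed in one call (landmark distances computed once)."""
        self.train(records)
        return self.transform(records)

    # -- setters -----------------------------------------------------------

    def set_type_fp(self, type_fp: str) -> "MacawEmbedder":
        """Change the fingerprint combination; recomputes landmark distances."""
        self._require_trained()
        self.spec = FingerprintSpec.parse(type_fp)
        self._recompute_landmark_cache()
        return self

    def set_metric(self, metric: str) -> "MacawEmbedder":
        """Change the similarity metric; recomputes landmark distances."""
        self._require_trained()
        self.metric = metric
        self._recompute_landmark_cache(refingerprint=False)
        return self

    def set_n_components(self, n_components: int) -> "MacawEmbedder":
        """Change the embedding dimensionality; no distances recomputed."""
        self._require_trained()
        if n_components > self.n_landmarks:
            raise ValueError("n_components must not exceed n_landmarks")
        self.n_components = n_components
        if self.algorithm in ("mds", "isomap"):
            # cached eigendecomposition: just re-truncate
            self._P = _triangulation_operator(
                self._mds_evecs_full, self._mds_evals, n_components
            )
            scale = np.sqrt(_effective_evals(self._mds_evals)[:n_components])
            self.landmark_coords = self._mds_evecs_full[:, :n_components] * scale[None, :]
        else:
            self._fit_projector()
        return self

    def set_algorithm(self, algorithm: str) -> "MacawEmbedder":
        """Change the projection algorithm; reuses cached landmark distances."""
        self._require_trained()
        if algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}; known: {_ALGORITHMS}")
        self.algorithm = algorithm
        self._fit_projector()
        return self

    def _recompute_landmark_cache(self, refingerprint: bool = True) -> None:
        lm = [MoleculeRecord(s) for s in self.landmark_smiles]
        if refingerprint:
            self.landmark_fps = _fingerprint_matrix(lm, self.spec)
        self.landmark_dist = pairwise_distances(
            lm, None, self.spec, self.metric, fps_A=self.landmark_fps
        )
        self.n_distance_computations += self.n_landmarks * self.n_landmarks
        self._fit_projector()
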