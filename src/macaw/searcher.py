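"""Hit search over an embedded molecule library.

``hit_finder`` retrieves library molecules predicted closest to a property
specification while evaluating the predictive model on only a few candidates:
the k1 training molecules with property values nearest the target act as
query seeds, the spatial index returns the k2 nearest library molecules to
each seed, and only that union (at most k1*k2 molecules) is predicted and
ranked.  ``hit_finder_grad`` instead minimizes (model(x) - target)^2 over the
continuous embedding space from k1 random restarts and retrieves neighbours
of each minimum.

Distances: Minkowski order p >= 1 (p=1 Manhattan recommended), or for
0 < p < 1 the rank-weighted V-distance

    d_V(v1, v2) = sum_i p^(i-1) * sort_ascending(|v1 - v2|)_i

which equals Manhattan at p=1 and down-weights the largest single-dimension
deviations.  The V-distance violates the triangle inequality in general, so
k-NN queries under it use exact brute-force scans; metric cases use a
BallTree.  Either way the neighbour sets are exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.neighbors import BallTree

logger = logging.getLogger(__name__)

__all__ = ["v_distance", "EmbeddedLibrary", "SearchSpec", "hit_finder", "hit_finder_grad"]


def v_distance(v1: np.ndarray, v2: np.ndarray, p: float) -> float:
    """Rank-weighted Manhattan distance for 0 < p <= 1."""
    if not 0.0 < p <= 1.0:
        raise ValueError("v_distance requires 0 < p <= 1; use Minkowski for p > 1")
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal dimension")
    a = np.sort(np.abs(v1 - v2))
    return float(a @ (p ** np.arange(a.size)))


def _v_distance_rows(Q: np.ndarray, X: np.ndarray, p: float) -> np.ndarray:
    """|Q| x |X| V-distance matrix (vectorized brute force)."""
    diffs = np.abs(Q[:, None, :] - X[None, :, :])
    diffs.sort(axis=2)
    w = p ** np.arange(Q.shape[1], dtype=float)
    return diffs @ w


@dataclass(frozen=True)
class SearchSpec:
    """Target property value and search breadth for :func:`hit_finder`."""

    target: float
    k1: int = 10
    k2: int = 20
    p: float = 1.0

    def __post_init__(self):
        if self.p <= 0:
            raise ValueError("p must be positive")
        if self.k1 < 1 or self.k2 < 1:
            raise ValueError("k1 and k2 must be positive")


class EmbeddedLibrary:
    """Embedded molecule library with an exact nearest-neighbour index.

    For Minkowski orders p >= 1 a BallTree provides the index; for the
    (non-metric) V-distance at 0 < p < 1 queries fall back to an exact
    brute-force scan, trading speed for correctness.
    """

    def __init__(self, coords: np.ndarray, smiles: Sequence[str], p: float = 1.0):
        self.coords = np.asarray(coords, dtype=float)
        self.smiles = list(smiles)
        if self.coords.shape[0] != len(self.smiles):
            raise ValueError("coords and smiles must align")
        if p <= 0:
            raise ValueError("p must be positive")
        self.p = p
        self._tree = (
            BallTree(self.coords, metric="minkowski", p=p) if p >= 1 else None
        )

    def __len__(self) -> int:
        return len(self.smiles)

    def query(self, X: np.ndarray, k: int) -> np.ndarray:
        """Indices of the k nearest library points per query row (exact)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = min(k, len(self))
        if self._tree is not None:
            _, idx = self._tree.query(X, k=k)
            return idx
        d = _v_distance_rows(X, self.coords, self.p)
        return np.argsort(d, axis=1, kind="stable")[:, :k]


def hit_finder(
    library: EmbeddedLibrary,
    model,
    spec: SearchSpec,
    train_embedding: np.ndarray,
    train_y: np.ndarray,
) -> list[tuple[str, float]]:
    """Model-frugal nearest-seed search; ranked (smiles, prediction) list.

    ``model`` follows the property-model contract: ``model.predict(rows)``
    (or a bare callable) maps embedding rows to property values.  The model
    is evaluated on at most k1*k2 library molecules.
    """
    train_y = np.asarray(train_y, dtype=float)
    if train_y.size == 0:
        raise ValueError("training set must be non-empty")
    k1 = spec.k1
    if k1 > train_y.size:
        warnings.warn(f"k1={k1} exceeds training size {train_y.size}; clipping")
        k1 = train_y.size
    if spec.k1 * spec.k2 > len(library):
        warnings.warn("k1*k2 exceeds library size; search approaches exhaustive")
    seed_idx = np.argsort(np.abs(train_y - spec.target), kind="stable")[:k1]
    seeds = np.asarray(train_embedding, dtype=float)[seed_idx]
    neighbor_idx = library.query(seeds, spec.k2)
    visited: list[int] = []
    seen: set[int] = set()
    for row in neighbor_idx:
        for j in row:
            if int(j) not in seen:
                seen.add(int(j))
                visited.append(int(j))
    preds = _predict(model, library.coords[visited])
    order = np.argsort(np.abs(preds - spec.target), kind="stable")
    return [(library.smiles[visited[i]], float(preds[i])) for i in order]


def hit_finder_grad(
    library: EmbeddedLibrary,
    model,
    target: float,
    k1_restarts: int = 10,
    k2: int = 20,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Multistart gradient search over the embedding; ranked hits.

    From each of ``k1_restarts`` random library points, minimizes
    ``g(x) = (model(x) - target)^2`` with L-BFGS-B (numerical gradients),
    then retrieves the ``k2`` library molecules nearest each minimum.
    Non-converged starts are discarded; if all fail the start points
    themselves seed the neighbour lookup.
    """
    rng = np.random.default_rng(seed)
    starts = library.coords[rng.choice(len(library), size=min(k1_restarts, len(library)), replace=False)]

    def g(x):
        return float((_predict(model, x[None, :])[0] - target) ** 2)

    minima = []
    for x0 in starts:
        res = minimize(g, x0, method="L-BFGS-B")
        if res.success:
            minima.append(res.x)
        else:
            logger.info("discarding non-converged restart: %s", res.message)
    if not minima:
        warnings.warn("no gradient restart converged; using start points as queries")
        minima = list(starts)
    neighbor_idx = library.query(np.asarray(minima), min(k2, len(library)))
    visited: list[int] = []
    seen: set[int] = set()
    for row in neighbor_idx:
        for j in row:
            if int(j) not in seen:
                seen.add(int(j))
                visited.append(int(j))
    preds = _predict(model, library.coords[visited])
    order = np.argsort(np.abs(preds - target), kind="stable")
    return [(library.smiles[visited[i]], float(preds[i])) for i in order]


def _predict(model, rows: np.ndarray) -> np.ndarray:
    fn: Callable = model.predict if hasattr(model, "predict") else model
    return np.asarray(fn(np.atleast_2d(rows)), dtype=float).ravel()
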