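"""Molecular fingerprints, bit-vector similarity metrics, and distances.

Molecules are described by fixed-length binary fingerprints (optionally a
concatenation of several fingerprint types), pairwise similarity is computed
under a named metric with range [0, 1], and similarity is converted to a
distance ``d = 1 - s``.  All similarity formulas are expressed in terms of the
usual bit counts: ``a`` = on-bits of x, ``b`` = on-bits of y, ``c`` = common
on-bits, ``n`` = fingerprint length (``d = n - a - b + c`` off-off matches).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator, rdMHFPFingerprint

__all__ = [
    "MoleculeRecord",
    "FingerprintSpec",
    "FINGERPRINT_TYPES",
    "SIMILARITY_METRICS",
    "InvalidMoleculeError",
    "compute_fingerprint",
    "similarity",
    "similarity_to_distance",
    "pairwise_distances",
]


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string does not parse to a molecule."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule with an optional numeric property value.

    ``smiles`` is canonicalized on construction via :meth:`from_smiles`.
    """

    smiles: str
    y: Optional[float] = None
    id: Optional[str] = None

    @classmethod
    def from_smiles(cls, smiles: str, y: float | None = None, id: str | None = None):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise InvalidMoleculeError(f"invalid SMILES: {smiles!r}")
        return cls(Chem.MolToSmiles(mol), y, id)


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

_HASHED_NBITS = 2048  # toolkit default for hashed types, fixed for reproducibility


def _morgan(radius: int, features: bool = False):
    kw = {"radius": radius, "fpSize": _HASHED_NBITS}
    if features:
        kw["atomInvariantsGenerator"] = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
    gen = rdFingerprintGenerator.GetMorganGenerator(**kw)
    return lambda mol: gen.GetFingerprint(mol)


def _rdk(max_path: int):
    return lambda mol: Chem.RDKFingerprint(mol, maxPath=max_path, fpSize=_HASHED_NBITS)


def _atompairs():
    gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=_HASHED_NBITS)
    return gen.GetFingerprint


def _torsion():
    gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=_HASHED_NBITS)
    return gen.GetFingerprint


def _secfp():
    enc = rdMHFPFingerprint.MHFPEncoder()
    return lambda mol: enc.EncodeSECFPMol(mol, radius=3, length=_HASHED_NBITS)


#: name -> callable(mol) -> rdkit ExplicitBitVect
FINGERPRINT_TYPES: dict[str, Callable] = {
    "morgan2": _morgan(2),
    "morgan3": _morgan(3),
    "featmorgan2": _morgan(2, features=True),
    "featmorgan3": _morgan(3, features=True),
    "rdk5": _rdk(5),
    "rdk7": _rdk(7),
    "maccs": MACCSkeys.GenMACCSKeys,
    "avalon": lambda mol: pyAvalonTools.GetAvalonFP(mol, 512),
    "atompairs": _atompairs(),
    "torsion": _torsion(),
    "pattern": lambda mol: Chem.PatternFingerprint(mol, fpSize=_HASHED_NBITS),
    "secfp": _secfp(),
    "layered": lambda mol: Chem.LayeredFingerprint(mol, fpSize=_HASHED_NBITS),
    # topological path fingerprint with the toolkit's Daylight-like defaults
    "daylight": lambda mol: Chem.RDKFingerprint(mol, fpSize=_HASHED_NBITS),
}


@dataclass(frozen=True)
class FingerprintSpec:
    """An ordered combination of fingerprint types, e.g. ``pattern + atompairs``."""

    parts: tuple[str, ...]

    def __post_init__(self):
        if not self.parts:
            raise ValueError("FingerprintSpec needs at least one part")
        for p in self.parts:
            if p not in FINGERPRINT_TYPES:
                raise ValueError(
                    f"unknown fingerprint type {p!r}; known: {sorted(FINGERPRINT_TYPES)}"
                )

    @classmethod
    def parse(cls, text: "str | FingerprintSpec") -> "FingerprintSpec":
        if isinstance(text, FingerprintSpec):
            return text
        return cls(tuple(p.strip().lower() for p in text.split("+") if p.strip()))

    def __str__(self) -> str:
        return " + ".join(self.parts)


def compute_fingerprint(record: "MoleculeRecord | str", spec: "FingerprintSpec | str") -> np.ndarray:
    """Concatenated binary fingerprint of a molecule as a boolean numpy array."""
    spec = FingerprintSpec.parse(spec)
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"invalid SMILES: {smiles!r}")
    chunks = []
    for part in spec.parts:
        bv = FINGERPRINT_TYPES[part](mol)
        arr = np.zeros((bv.GetNumBits(),), dtype=np.uint8)
        DataStructs.ConvertToNumpyArray(bv, arr)
        chunks.append(arr.astype(bool))
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# Similarity metrics
# ---------------------------------------------------------------------------
# Each metric is a function of broadcastable arrays (a, b, c, n) evaluated only
# where a+b > 0; the degenerate all-zero/all-zero pair is handled separately
# (s = 1, both fingerprints identical and featureless).


def _safe(num, den):
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def _tanimoto(a, b, c, n):
    return _safe(c, a + b - c)


def _dice(a, b, c, n):
    return _safe(2 * c, a + b)


def _cosine(a, b, c, n):
    return _safe(c, np.sqrt(a * b))


def _sokal(a, b, c, n):
    # Sokal–Sneath: doubles the weight of mismatches
    return _safe(c, 2 * a + 2 * b - 3 * c)


def _kulczynski(a, b, c, n):
    return _safe(c * (a + b), 2 * a * b)


def _mcconnaughey(a, b, c, n):
    # native range [-1, 1]; rescaled affinely to [0, 1] (s(x, x) stays 1)
    m = _safe(c * (a + b) - a * b, a * b)
    return (m + 1.0) / 2.0


def _braun_blanquet(a, b, c, n):
    return _safe(c, np.maximum(a, b))


def _rogot_goldberg(a, b, c, n):
    d = n - a - b + c
    return _safe(c, a + b) + _safe(d, 2 * n - a - b)


def _asymmetric(a, b, c, n):
    return np.clip(_safe(c, np.minimum(a, b)), 0.0, 1.0)


def _manhattan(a, b, c, n):
    # similarity form: 1 - normalized Hamming distance
    return 1.0 - (a + b - 2 * c) / n


def _blay_roger(a, b, c, n):
    raise NotImplementedError(
        "no published formula is available for the 'blay-roger' similarity; "
        "register a replacement in SIMILARITY_METRICS to use it"
    )


SIMILARITY_METRICS: dict[str, Callable] = {
    "tanimoto": _tanimoto,
    "dice": _dice,
    "cosine": _cosine,
    "sokal": _sokal,
    "kulczynski": _kulczynski,
    "mcconnaughey": _mcconnaughey,
    "braun-blanquet": _braun_blanquet,
    "blay-roger": _blay_roger,
    "rogot-goldberg": _rogot_goldberg,
    "asymmetric": _asymmetric,
    "manhattan": _manhattan,
}

#: metrics for which s(x, y) = s(y, x) holds exactly
SYMMETRIC_METRICS = frozenset(SIMILARITY_METRICS) - {"asymmetric", "blay-roger"}


def _metric_fn(metric: str) -> Callable:
    m = metric.strip().lower()
    if m not in SIMILARITY_METRICS:
        raise ValueError(f"unknown similarity metric {m!r}; known: {sorted(SIMILARITY_METRICS)}")
    return SIMILARITY_METRICS[m]


def similarity(fp1: np.ndarray, fp2: np.ndarray, metric: str = "tanimoto") -> float:
    """Similarity in [0, 1] between two equal-length binary fingerprints."""
    fp1 = np.asarray(fp1, dtype=bool)
    fp2 = np.asarray(fp2, dtype=bool)
    if fp1.shape != fp2.shape:
        raise ValueError(f"fingerprint length mismatch: {fp1.shape} vs {fp2.shape}")
    a = int(fp1.sum())
    b = int(fp2.sum())
    if a == 0 and b == 0:
        warnings.warn("both fingerprints are all-zero; similarity defined as 1")
        return 1.0
    if a == 0 or b == 0:
        return 0.0
    c = int((fp1 & fp2).sum())
    return float(_metric_fn(metric)(a, b, c, fp1.size))


def similarity_to_distance(s):
    """Convert similarity to distance.

    The adopted form is ``d = 1 - s`` (Soergel-type for Tanimoto): bounded on
    [0, 1], zero at identity, monotone decreasing.  Replace this function to
    experiment with alternatives such as ``sqrt(1 - s)``.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0) or np.any(s_arr > 1):
        raise ValueError("similarity must lie in [0, 1]")
    d = 1.0 - s_arr
    return float(d) if np.isscalar(s) or s_arr.ndim == 0 else d


def _fingerprint_matrix(records, spec) -> np.ndarray:
    rows = []
    for i, rec in enumerate(records):
        try:
            rows.append(compute_fingerprint(rec, spec))
        except InvalidMoleculeError as e:
            raise InvalidMoleculeError(f"record {i}: {e}") from e
    return np.asarray(rows, dtype=bool)


def pairwise_distances(
    A: Sequence,
    B: Sequence | None = None,
    spec: "FingerprintSpec | str" = "morgan2",
    metric: str = "tanimoto",
    *,
    fps_A: np.ndarray | None = None,
    fps_B: np.ndarray | None = None,
) -> np.ndarray:
    """|A| x |B| matrix of fingerprint distances.

    ``B=None`` means B = A (square matrix, zero diagonal).  Precomputed
    fingerprint matrices may be passed to skip recomputation.
    """
    FA = _fingerprint_matrix(A, spec) if fps_A is None else np.asarray(fps_A, dtype=bool)
    if B is None and fps_B is None:
        FB = FA
    else:
        FB = _fingerprint_matrix(B, spec) if fps_B is None else np.asarray(fps_B, dtype=bool)
    if FA.shape[1] != FB.shape[1]:
        raise ValueError("fingerprint length mismatch between A and B")
    n = FA.shape[1]
    a = FA.sum(axis=1).astype(float)[:, None]
    b = FB.sum(axis=1).astype(float)[None, :]
    c = (FA.astype(np.float64) @ FB.astype(np.float64).T)
    fn = _metric_fn(metric)
    s = fn(a, b, c, float(n))
    # degenerate all-zero fingerprints: s=1 vs another all-zero, s=0 otherwise
    zero_a = a == 0
    zero_b = b == 0
    if zero_a.any() or zero_b.any():
        s = np.where(zero_a | zero_b, 0.0, s)
        s = np.where(zero_a & zero_b, 1.0, s)
    s = np.clip(s, 0.0, 1.0)
    return similarity_to_distance(s)
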