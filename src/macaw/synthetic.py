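"""Synthetic molecule sets and a structure-computable surrogate fuel property.

The generator builds small organic molecules grammatically (random bounded
carbon skeletons decorated per family) so the whole pipeline can be exercised
offline and deterministically.  The surrogate property emulates the
qualitative structure trends of an octane-number-like fuel rating: long
unbranched saturated chains score low; short, branched, unsaturated and
oxygenated molecules score high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_distance import InvalidMoleculeError

__all__ = [
    "SurrogatePropertyParams",
    "SyntheticSet",
    "make_synthetic_set",
    "surrogate_property",
    "structure_counts",
]

FAMILIES = ("linear_alkane", "branched_alkane", "alcohol", "alkene", "aromatic")

#: default family composition of a synthetic set; linear alkanes get a small
#: share because only C2-C20 exist (19 unique molecules)
DEFAULT_MIX = {
    "linear_alkane": 0.02,
    "branched_alkane": 0.38,
    "alcohol": 0.25,
    "alkene": 0.25,
    "aromatic": 0.10,
}

MAX_HEAVY_ATOMS = 20


@dataclass(frozen=True)
class SurrogatePropertyParams:
    """Coefficients of the surrogate property.

    y = intercept + branch_coef*branches + unsat_coef*unsaturations
        + oxygen_coef*oxygens - heavy_coef*heavy_atoms + Normal(0, noise_sd)

    Defaults give an octane-rating-like scale (~20-100 over the default
    synthetic sets) with the canonical trend directions.
    """

    intercept: float = 60.0
    branch_coef: float = 8.0
    unsat_coef: float = 10.0
    oxygen_coef: float = 15.0
    heavy_coef: float = 3.0
    noise_sd: float = 0.0


@dataclass
class SyntheticSet:
    smiles: list[str]
    y: np.ndarray
    families: dict[str, int]
    seed: int


def structure_counts(smiles: str) -> dict[str, int]:
    """Heavy atoms, branch points, unsaturations and oxygens of a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"invalid SMILES: {smiles!r}")
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    heavy = kek.GetNumHeavyAtoms()
    branches = sum(
        1
        for atom in kek.GetAtoms()
        if atom.GetSymbol() == "C"
        and sum(1 for n in atom.GetNeighbors() if n.GetSymbol() == "C") >= 3
    )
    unsat = sum(
        1 for b in kek.GetBonds() if b.GetBondType() != Chem.BondType.SINGLE
    )
    oxygens = sum(1 for atom in kek.GetAtoms() if atom.GetSymbol() == "O")
    return {"heavy": heavy, "branches": branches, "unsaturations": unsat, "oxygens": oxygens}


def surrogate_property(
    smiles: str,
    params: SurrogatePropertyParams = SurrogatePropertyParams(),
    rng: np.random.Generator | None = None,
) -> float:
    """Deterministic (at noise_sd=0) structure-computable property value."""
    c = structure_counts(smiles)
    y = (
        params.intercept
        + params.branch_coef * c["branches"]
        + params.unsat_coef * c["unsaturations"]
        + params.oxygen_coef * c["oxygens"]
        - params.heavy_coef * c["heavy"]
    )
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y += params.noise_sd * rng.standard_normal()
    return float(y)


# ---------------------------------------------------------------------------
# Grammatical molecule construction
# ---------------------------------------------------------------------------

def _random_carbon_tree(rng: np.random.Generator, n_carbons: int, branched: bool) -> Chem.RWMol:
    """Random acyclic carbon skeleton with max degree 4.

    ``branched=False`` yields an unbranched chain; ``branched=True`` attaches
    each new carbon to a random open position, retrying until at least one
    branch point exists (guaranteed feasible for n >= 4).
    """
    while True:
        mol = Chem.RWMol()
        mol.AddAtom(Chem.Atom("C"))
        for _ in range(n_carbons - 1):
            if branched:
                open_pos = [
                    a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() < 4
                ]
                parent = int(open_pos[rng.integers(len(open_pos))])
            else:
                parent = mol.GetNumAtoms() - 1
            new = mol.AddAtom(Chem.Atom("C"))
            mol.AddBond(parent, new, Chem.BondType.SINGLE)
        if not branched:
            return mol
        has_branch = any(a.GetDegree() >= 3 for a in mol.GetAtoms())
        if has_branch:
            return mol


def _finish(mol: Chem.RWMol) -> str:
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _make_member(family: str, rng: np.random.Generator) -> str:
    if family == "linear_alkane":
        n = int(rng.integers(2, MAX_HEAVY_ATOMS + 1))
        return _finish(_random_carbon_tree(rng, n, branched=False))
    if family == "branched_alkane":
        n = int(rng.integers(4, MAX_HEAVY_ATOMS + 1))
        return _finish(_random_carbon_tree(rng, n, branched=True))
    if family == "alcohol":
        n = int(rng.integers(2, MAX_HEAVY_ATOMS))
        mol = _random_carbon_tree(rng, n, branched=bool(rng.integers(2)) and n >= 4)
        open_pos = [a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() < 4]
        o = mol.AddAtom(Chem.Atom("O"))
        mol.AddBond(int(open_pos[rng.integers(len(open_pos))]), o, Chem.BondType.SINGLE)
        return _finish(mol)
    if family == "alkene":
        n = int(rng.integers(3, MAX_HEAVY_ATOMS + 1))
        mol = _random_carbon_tree(rng, n, branched=bool(rng.integers(2)) and n >= 4)
        # promote one eligible bond to a double bond
        cands = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtom().GetDegree() <= 3 and b.GetEndAtom().GetDegree() <= 3
        ]
        if cands:
            b = mol.GetBondWithIdx(int(cands[rng.integers(len(cands))]))
            b.SetBondType(Chem.BondType.DOUBLE)
        return _finish(mol)
    if family == "aromatic":
        n_sub = int(rng.integers(0, 4))
        chains = ["".join("C" for _ in range(rng.integers(1, 5))) for _ in range(n_sub)]
        mol = Chem.RWMol(Chem.MolFromSmiles("c1ccccc1"))
        ring_atoms = [a.GetIdx() for a in mol.GetAtoms()]
        for ch in chains:
            pos = int(ring_atoms[rng.integers(len(ring_atoms))])
            if mol.GetAtomWithIdx(pos).GetDegree() >= 3:
                continue
            prev = pos
            for _ in range(len(ch)):
                if mol.GetNumAtoms() >= MAX_HEAVY_ATOMS:
                    break
                new = mol.AddAtom(Chem.Atom("C"))
                mol.AddBond(prev, new, Chem.BondType.SINGLE)
                prev = new
        return _finish(mol)
    raise ValueError(f"unknown family {family!r}")


def make_synthetic_set(
    n: int,
    family_mix: dict[str, float] | None = None,
    seed: int = 0,
    params: SurrogatePropertyParams = SurrogatePropertyParams(),
) -> SyntheticSet:
    """Generate ``n`` unique molecules with surrogate property values.

    ``family_mix`` maps family names to fractions (normalized internally).
    Deterministic given ``seed``; duplicates (by canonical SMILES) are
    rejected and redrawn, so requesting more unique molecules than a family
    can produce raises after a bounded number of attempts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(DEFAULT_MIX if family_mix is None else family_mix)
    for fam in mix:
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}; known: {FAMILIES}")
    total = sum(mix.values())
    if total <= 0:
        raise ValueError("family mix fractions must sum to a positive value")
    rng = np.random.default_rng(seed)
    quota: dict[str, int] = {}
    fams = sorted(mix)
    for fam in fams:
        quota[fam] = int(round(n * mix[fam] / total))
    # fix rounding drift on the largest family
    drift = n - sum(quota.values())
    quota[max(fams, key=lambda f: quota[f])] += drift

    seen: set[str] = set()
    smiles: list[str] = []
    families: dict[str, int] = {f: 0 for f in fams}
    for fam in fams:
        attempts = 0
        while families[fam] < quota[fam]:
            attempts += 1
            if attempts > 200 * max(quota[fam], 1):
                raise ValueError(
                    f"cannot draw {quota[fam]} unique molecules of family {fam!r}"
                )
            smi = _make_member(fam, rng)
            if smi in seen:
                continue
            seen.add(smi)
            smiles.append(smi)
            families[fam] += 1
    y = np.array([surrogate_property(s, params, rng) for s in smiles])
    return SyntheticSet(smiles, y, families, seed)
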