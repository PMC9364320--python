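"""Robust molecular token strings.

A molecule is written as a linear sequence of tokens — atom tokens such as
``[C]``, ``[=O]``, branch delimiters ``[Branch]`` / ``[EndBranch]``, and ring
closures ``[Ring3]`` — with the key property that *any* sequence of tokens
decodes to a chemically valid molecule.  This is the property popularised by
the SELFIES representation: the decoder applies hard-coded valence rules and
simply clips or ignores instructions that cannot be realised, so random token
concatenations still yield parseable structures.  The probabilistic library
generator builds directly on this guarantee.

Grammar
-------
* ``[C]``, ``[=C]``, ``[#C]``, ``[N]``, ``[O]``, ... — append an atom, bonded
  to the current attachment point with the requested order (single when no
  prefix).  The order is clipped to the free valence on both ends.
* ``[Branch]`` — remember the current atom; ``[EndBranch]`` — return to it.
* ``[RingK]`` / ``[=RingK]`` — bond the current atom to the atom created K
  steps earlier, if both have free valence and are not already bonded.

Only neutral, non-isotopic atoms of the organic subset (plus B, Si, P) are
representable; molecules outside that set raise :class:`TokenizeError` on
encoding.  Stereochemistry is dropped on encoding.
"""

from __future__ import annotations

import re

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: Maximum explicit valence enforced by the decoder, per element.
VALENCE: dict[str, int] = {
    "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "B": 3, "Si": 4,
}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_PREFIX_BOND = {"": 1, "=": 2, "#": 3}
_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}

BRANCH = "[Branch]"
END_BRANCH = "[EndBranch]"

_ATOM_RE = re.compile(r"^\[([=#]?)(C|N|O|S|P|F|Cl|Br|I|B|Si)\]$")
_RING_RE = re.compile(r"^\[([=#]?)Ring([1-9][0-9]?)\]$")


class TokenizeError(ValueError):
    """Raised when a molecule cannot be written in the token grammar."""


def is_token(tok: str) -> bool:
    """True if *tok* is a token the decoder implements valence rules for."""
    return (
        tok in (BRANCH, END_BRANCH)
        or _ATOM_RE.match(tok) is not None
        or _RING_RE.match(tok) is not None
    )


def atom_token(symbol: str, order: int = 1) -> str:
    return f"[{_BOND_PREFIX[order]}{symbol}]"


def ring_token(offset: int, order: int = 1) -> str:
    return f"[{_BOND_PREFIX[order]}Ring{offset}]"


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES via rdkit; raises ``ValueError`` on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def encode(smiles: str) -> list[str]:
    """Encode a SMILES string as a token sequence.

    The molecule is kekulized and traversed depth-first from atom 0; branch
    points emit ``[Branch]``/``[EndBranch]`` pairs and graph back-edges emit
    ring-closure tokens whose offset is the distance in atom-creation order.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise TokenizeError(f"invalid SMILES: {smiles!r}")
    mol = Chem.RWMol(mol)
    Chem.RemoveStereochemistry(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in VALENCE:
            raise TokenizeError(f"unsupported element {sym!r} in {smiles!r}")
        if atom.GetFormalCharge() or atom.GetIsotope() or atom.GetNumRadicalElectrons():
            raise TokenizeError(f"charged/isotopic/radical atom in {smiles!r}")
        if atom.GetExplicitValence() > VALENCE[sym]:
            raise TokenizeError(f"hypervalent {sym} in {smiles!r}")

    order_of = {}
    for bond in mol.GetBonds():
        bt = bond.GetBondType()
        if bt == Chem.BondType.SINGLE:
            o = 1
        elif bt == Chem.BondType.DOUBLE:
            o = 2
        elif bt == Chem.BondType.TRIPLE:
            o = 3
        else:
            raise TokenizeError(f"unsupported bond type {bt} in {smiles!r}")
        order_of[bond.GetIdx()] = o

    visited: dict[int, int] = {}  # rdkit idx -> creation order
    used_bonds: set[int] = set()

    def walk(v: int, parent: int, bond_order: int) -> list[str]:
        visited[v] = len(visited)
        toks = [atom_token(mol.GetAtomWithIdx(v).GetSymbol(), bond_order)]
        nbrs = sorted(n.GetIdx() for n in mol.GetAtomWithIdx(v).GetNeighbors())
        for u in nbrs:
            if u == parent or u not in visited:
                continue
            b = mol.GetBondBetweenAtoms(v, u)
            if b.GetIdx() in used_bonds:
                continue
            used_bonds.add(b.GetIdx())
            toks.append(ring_token(visited[v] - visited[u], order_of[b.GetIdx()]))
        segs = []
        for u in nbrs:
            if u == parent or u in visited:
                continue
            b = mol.GetBondBetweenAtoms(v, u)
            used_bonds.add(b.GetIdx())
            segs.append(walk(u, v, order_of[b.GetIdx()]))
        for seg in segs[:-1]:
            toks += [BRANCH, *seg, END_BRANCH]
        if segs:
            toks += segs[-1]
        return toks

    if mol.GetNumAtoms() == 0:
        raise TokenizeError(f"empty molecule: {smiles!r}")
    return walk(0, -1, 1)


def decode(tokens: list[str]) -> str | None:
    """Decode a token sequence into a canonical SMILES string.

    Decoding never raises for sequences of known tokens: bond orders are
    clipped to the available valence, branch/ring instructions that cannot be
    realised are skipped, and an atom token whose attachment point is
    saturated falls back to the most recently created atom with free valence.
    Returns ``None`` only when the sequence contains no realisable atom.
    """
    mol = Chem.RWMol()
    free: list[int] = []
    cur = -1
    stack: list[int] = []
    for tok in tokens:
        m = _ATOM_RE.match(tok)
        if m:
            order = _PREFIX_BOND[m.group(1)]
            sym = m.group(2)
            if mol.GetNumAtoms() == 0:
                cur = mol.AddAtom(Chem.Atom(sym))
                free.append(VALENCE[sym])
                continue
            attach = cur if free[cur] > 0 else -1
            if attach < 0:
                for i in range(mol.GetNumAtoms() - 1, -1, -1):
                    if free[i] > 0:
                        attach = i
                        break
            if attach < 0:
                continue  # molecule saturated: ignore
            b = min(order, free[attach], VALENCE[sym])
            new = mol.AddAtom(Chem.Atom(sym))
            free.append(VALENCE[sym] - b)
            mol.AddBond(attach, new, _BOND_TYPE[b])
            free[attach] -= b
            cur = new
        elif tok == BRANCH:
            if cur >= 0:
                stack.append(cur)
        elif tok == END_BRANCH:
            if stack:
                cur = stack.pop()
        else:
            m = _RING_RE.match(tok)
            if m is None:
                continue  # unknown token: ignore (robustness)
            if cur < 0:
                continue
            target = cur - int(m.group(2))
            if target < 0 or target == cur:
                continue
            if mol.GetBondBetweenAtoms(target, cur) is not None:
                continue
            if free[cur] < 1 or free[target] < 1:
                continue
            b = min(_PREFIX_BOND[m.group(1)], free[cur], free[target])
            mol.AddBond(target, cur, _BOND_TYPE[b])
            free[cur] -= b
            free[target] -= b
    if mol.GetNumAtoms() == 0:
        return None
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:  # pragma: no cover - valence clipping should prevent this
        return None
    return Chem.MolToSmiles(out)
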