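"""Probabilistic molecule library generation on robust token strings.

``library_maker`` generates arbitrary-size molecule libraries "centered"
around an input molecule set: the inputs are encoded into robust token
strings (see :mod:`macaw.tokenstrings`), token frequencies are counted —
per string position, per token-to-token transition, or both ("dual") — and
new strings are sampled from the row-normalized frequency matrix blended
with a uniform matrix.  The blending weight ``noise_factor`` in [0, 1]
controls focus versus diversity: 0 reproduces the input distribution, 1
samples tokens uniformly.  Because every token string decodes to a valid
molecule, sampled strings decode to parseable SMILES at ~100% rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import tokenstrings as ts

logger = logging.getLogger(__name__)

__all__ = [
    "SelfiesAlphabet",
    "ProbabilityMatrix",
    "LengthDistribution",
    "build_alphabet",
    "count_frequencies",
    "apply_noise",
    "sample_molecule",
    "library_maker",
]

ALGORITHMS = ("position", "transition", "dual")

#: alphabet used when no input molecules are provided: a small organic-subset
#: token list with branching and common ring sizes
PREDEFINED_ALPHABET = (
    "[C]", "[=C]", "[#C]", "[N]", "[=N]", "[O]", "[=O]", "[F]",
    ts.BRANCH, ts.END_BRANCH, "[Ring3]", "[Ring4]", "[Ring5]", "[Ring6]",
)


@dataclass(frozen=True)
class SelfiesAlphabet:
    """Ordered token alphabet with provenance."""

    tokens: tuple[str, ...]
    source: str  # "derived-from-input" | "predefined-default"

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}


@dataclass(frozen=True)
class LengthDistribution:
    """Discrete string-length distribution p(n) ∝ exp(beta*n), n in [1, max_len]."""

    max_len: int
    beta: float = 1.0

    def weights(self) -> np.ndarray:
        n = np.arange(1, self.max_len + 1, dtype=float)
        w = np.exp(self.beta * (n - n.max()))  # shift for numerical stability
        return w / w.sum()

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(np.arange(1, self.max_len + 1), p=self.weights()))


@dataclass
class ProbabilityMatrix:
    """Row-stochastic token sampling distribution.

    ``data`` shape by algorithm: position — (|A|, max_len) column-stochastic
    over tokens per position; transition — (|A|+1, |A|) rows (previous token,
    with a virtual begin-of-string row last); dual — (|A|+1, |A|, max_len).
    """

    algorithm: str
    alphabet: SelfiesAlphabet
    data: np.ndarray
    noise_factor: float
    max_len: int

    def sampling_row(self, prev: int | None, pos: int) -> np.ndarray:
        """Distribution over next tokens given the previous token and position."""
        if self.algorithm == "position":
            return self.data[:, min(pos, self.max_len - 1)]
        row = len(self.alphabet) if prev is None else prev
        if self.algorithm == "transition":
            return self.data[row]
        return self.data[row, :, min(pos, self.max_len - 1)]


def build_alphabet(smiles_list=None) -> SelfiesAlphabet:
    """Token alphabet: unique robust tokens of the inputs, or the predefined list.

    Tokens appear in first-occurrence order across the encoded inputs.  All
    tokens produced by the encoder carry decoder valence rules, so no robust
    filtering drops anything; unknown tokens injected by a user are filtered
    with a logged list.
    """
    if not smiles_list:
        return SelfiesAlphabet(tuple(PREDEFINED_ALPHABET), "predefined-default")
    tokens: list[str] = []
    seen: set[str] = set()
    bad: list[str] = []
    for smi in smiles_list:
        try:
            toks = ts.encode(smi)
        except ts.TokenizeError:
            bad.append(smi)
            continue
        for t in toks:
            if t not in seen:
                if not ts.is_token(t):  # pragma: no cover - encoder emits known tokens
                    logger.warning("dropping non-robust token %r", t)
                    continue
                seen.add(t)
                tokens.append(t)
    if bad:
        raise ts.TokenizeError(f"cannot encode input molecules: {bad}")
    return SelfiesAlphabet(tuple(tokens), "derived-from-input")


def _encode_all(smiles_list) -> list[list[str]]:
    return [ts.encode(s) for s in smiles_list]


def count_frequencies(
    token_strings: list[list[str]],
    algorithm: str,
    alphabet: SelfiesAlphabet,
    max_len: int | None = None,
) -> tuple[np.ndarray, int]:
    """Raw integer token frequency array; returns ``(counts, max_len)``.

    ``max_len=None`` defaults to the longest input string; an explicit
    ``max_len`` smaller than the longest input raises (truncation would skew
    the counts).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; known: {ALGORITHMS}")
    longest = max((len(t) for t in token_strings), default=1)
    if max_len is None:
        max_len = longest
    elif max_len < longest:
        raise ValueError(
            f"max_len={max_len} is smaller than the longest input string ({longest})"
        )
    A = len(alphabet)
    idx = alphabet.index()
    for toks in token_strings:
        for t in toks:
            if t not in idx:
                raise ValueError(f"token {t!r} not in alphabet")
    begin = A  # virtual begin-of-string row for transition/dual
    if algorithm == "position":
        counts = np.zeros((A, max_len))
        for toks in token_strings:
            for p, t in enumerate(toks):
                counts[idx[t], p] += 1
    elif algorithm == "transition":
        counts = np.zeros((A + 1, A))
        for toks in token_strings:
            prev = begin
            for t in toks:
                counts[prev, idx[t]] += 1
                prev = idx[t]
    else:  # dual
        counts = np.zeros((A + 1, A, max_len))
        for toks in token_strings:
            prev = begin
            for p, t in enumerate(toks):
                counts[prev, idx[t], p] += 1
                prev = idx[t]
    return counts, max_len


def apply_noise(
    raw: np.ndarray,
    noise_factor: float,
    algorithm: str,
    alphabet: SelfiesAlphabet,
    max_len: int,
) -> ProbabilityMatrix:
    """Normalize counts row-wise and blend with the uniform distribution.

    ``row' = (1 - eta) * normalize(row) + eta * uniform``; all-zero rows map
    to uniform at any ``eta``.  Sampling axes: position — axis 0 (tokens per
    position); transition/dual — axis 1 (next token given previous).
    """
    if not 0.0 <= noise_factor <= 1.0:
        raise ValueError("noise_factor must lie in [0, 1]")
    raw = np.asarray(raw, dtype=float)
    A = len(alphabet)
    uniform = 1.0 / A

    def blend(mat, axis):
        sums = mat.sum(axis=axis, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(sums > 0, mat / np.where(sums > 0, sums, 1.0), uniform)
        return (1.0 - noise_factor) * norm + noise_factor * uniform

    if algorithm == "position":
        data = blend(raw, axis=0)
    else:
        data = blend(raw, axis=1)
    return ProbabilityMatrix(algorithm, alphabet, data, noise_factor, max_len)


def fit_probability_matrix(
    smiles_list,
    algorithm: str = "position",
    noise_factor: float = 0.3,
    max_len: int | None = None,
) -> ProbabilityMatrix:
    """Convenience: alphabet + counts + noise from a molecule list."""
    alphabet = build_alphabet(smiles_list)
    strings = _encode_all(smiles_list) if smiles_list else []
    if not strings and max_len is None:
        max_len = 20  # no-input mode: no observed lengths to default to
    raw, max_len = count_frequencies(strings, algorithm, alphabet, max_len)
    return apply_noise(raw, noise_factor, algorithm, alphabet, max_len)


def sample_tokens(
    P: ProbabilityMatrix, lengths: LengthDistribution, rng: np.random.Generator
) -> list[str]:
    """Draw one token string of sampled length from the probability matrix."""
    n = lengths.sample(rng)
    toks: list[str] = []
    prev: int | None = None
    for pos in range(n):
        row = P.sampling_row(prev, pos)
        i = int(rng.choice(len(row), p=row))
        toks.append(P.alphabet.tokens[i])
        prev = i
    return toks


def sample_molecule(
    P: ProbabilityMatrix,
    lengths: LengthDistribution | None = None,
    rng: np.random.Generator | int | None = None,
) -> str | None:
    """Sample one molecule; returns canonical SMILES (None for atom-free strings)."""
    if lengths is None:
        lengths = LengthDistribution(P.max_len)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return ts.decode(sample_tokens(P, lengths, rng))


def library_maker(
    smiles_list=None,
    n_requested: int = 1000,
    algorithm: str = "position",
    noise_factor: float = 0.3,
    max_len: int | None = None,
    length_beta: float = 1.0,
    seed: int = 0,
) -> list[str]:
    """Generate up to ``n_requested`` unique canonical SMILES around the inputs.

    Duplicates and synonyms are removed by canonical-SMILES deduplication;
    when uniqueness stalls (tiny alphabet) the function returns fewer
    molecules after ``20 * n_requested`` draws with a logged warning.
    Deterministic given ``seed``.
    """
    if n_requested < 1:
        raise ValueError("n_requested must be >= 1")
    P = fit_probability_matrix(smiles_list, algorithm, noise_factor, max_len)
    lengths = LengthDistribution(P.max_len, beta=length_beta)
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    draws = 0
    max_draws = 20 * n_requested
    while len(out) < n_requested and draws < max_draws:
        draws += 1
        smi = ts.decode(sample_tokens(P, lengths, rng))
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
    if len(out) < n_requested:
        warnings.warn(
            f"library_maker produced {len(out)}/{n_requested} unique molecules "
            f"after {draws} draws"
        )
    return out
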