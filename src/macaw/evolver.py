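"""Directed evolution of molecule libraries toward a property specification.

Each round seeds the probabilistic generator with the current molecule set,
generates up to k1 candidates, embeds and predicts them, pools them with the
k2 carried-over molecules from the previous round (with their stored
predictions), and keeps the k2 closest to the target.  Because the selected
set is always pooled with the carry-over, the best |prediction - target| is
non-increasing across rounds.  After n_rounds the n_hits closest molecules
are returned with their predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .generator import library_maker
from .searcher import _predict

logger = logging.getLogger(__name__)

__all__ = ["EvolverConfig", "EvolverTrace", "library_evolver"]


@dataclass(frozen=True)
class EvolverConfig:
    """Knobs of the evolutionary loop (defaults as printed)."""

    target: float
    k1: int = 3000
    k2: int = 100
    n_rounds: int = 8
    n_hits: int = 10
    algorithm: str = "transition"  # generator algorithm inside the loop
    noise_factor: float = 0.3
    max_len: int | None = None
    length_beta: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.k2 > self.k1:
            raise ValueError("k2 must not exceed k1")
        if self.n_hits > self.k2:
            raise ValueError("n_hits must not exceed k2")


@dataclass
class RoundRecord:
    seed_smiles: list[str]
    n_generated: int
    best_abs_error: float
    selected: list[tuple[str, float]]  # (smiles, prediction)


@dataclass
class EvolverTrace:
    rounds: list[RoundRecord] = field(default_factory=list)

    @property
    def best_abs_errors(self) -> list[float]:
        return [r.best_abs_error for r in self.rounds]


def library_evolver(
    seed_smiles,
    embedder,
    model,
    config: EvolverConfig,
) -> tuple[list[tuple[str, float]], EvolverTrace]:
    """Evolve molecules toward ``config.target``; returns (hits, trace).

    ``embedder`` must be trained; ``model`` follows the property-model
    contract (predict on embedding rows).  Predictions of carried-over
    molecules are reused across rounds (the embedding is static per run);
    duplicates are resolved by canonical SMILES, keeping the earlier
    prediction.  Model evaluations are bounded by k1*n_rounds + k2.
    """
    seeds = list(seed_smiles)
    if not seeds:
        raise ValueError("seed_smiles must be non-empty")
    trace = EvolverTrace()
    predictions: dict[str, float] = {}  # canonical smiles -> stored prediction
    carried: list[str] = []
    rng = np.random.default_rng(config.seed)
    current = seeds
    for rnd in range(config.n_rounds):
        lib = library_maker(
            current,
            n_requested=config.k1,
            algorithm=config.algorithm,
            noise_factor=config.noise_factor,
            max_len=config.max_len,
            length_beta=config.length_beta,
            seed=int(rng.integers(2**31 - 1)),
        )
        if len(lib) < config.k1:
            logger.info("round %d: generator yielded %d/%d molecules", rnd, len(lib), config.k1)
        new = [s for s in lib if s not in predictions]
        if new:
            emb = embedder.transform(new)
            preds = _predict(model, emb.coords)
            good = np.isfinite(preds)
            if not good.all():
                warnings.warn(f"round {rnd}: dropping {int((~good).sum())} failed predictions")
            for s, p, ok in zip(new, preds, good):
                if ok:
                    predictions[s] = float(p)
        pool = list(dict.fromkeys([s for s in lib if s in predictions] + carried))
        pool.sort(key=lambda s: (abs(predictions[s] - config.target), s))
        carried = pool[: config.k2]
        best = abs(predictions[carried[0]] - config.target) if carried else float("inf")
        trace.rounds.append(
            RoundRecord(
                seed_smiles=list(current),
                n_generated=len(lib),
                best_abs_error=best,
                selected=[(s, predictions[s]) for s in carried],
            )
        )
        current = carried if carried else current
    hits = [(s, predictions[s]) for s in carried[: config.n_hits]]
    return hits, trace
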