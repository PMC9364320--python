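"""Automatic fingerprint/metric recommendation (``macaw_optimus``).

Each candidate (fingerprint combination, similarity metric) pair is embedded
with identical landmark indices and seed, and scored by the k-fold
cross-validated R^2 of a fixed radial-basis SVM regressor on the embedding
coordinates.  Fold assignments are shared across candidates (a paired
comparison), so score differences reflect the embeddings, not the splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, cross_val_score
from sklearn.svm import SVR

from .chem_distance import FingerprintSpec, MoleculeRecord
from .embedder import MacawEmbedder

logger = logging.getLogger(__name__)

__all__ = ["OptimusResult", "macaw_optimus", "DEFAULT_SPECS", "DEFAULT_METRICS"]

#: desk-scale default candidate grid (45 pairs); pass the full lists of
#: chem_distance.FINGERPRINT_TYPES / SIMILARITY_METRICS for the 14x11 grid
DEFAULT_SPECS = (
    "morgan2", "morgan3", "rdk5", "maccs", "avalon",
    "atompairs", "torsion", "pattern", "secfp",
)
DEFAULT_METRICS = ("tanimoto", "dice", "cosine", "rogot-goldberg", "mcconnaughey")

# selection-time SVM (fixed; the final model is tuned separately)
_SELECTION_SVM = dict(kernel="rbf", C=100.0, epsilon=0.1)


@dataclass
class OptimusResult:
    """Ranked candidate table plus the trained recommended embedder."""

    table: pd.DataFrame  # columns: type_fp, metric, score_mean, score_sd
    best: tuple[str, str]
    embedder: MacawEmbedder


def macaw_optimus(
    records,
    candidate_specs=DEFAULT_SPECS,
    candidate_metrics=DEFAULT_METRICS,
    n_components: int = 15,
    n_landmarks: int = 50,
    cv_folds: int = 5,
    seed: int = 0,
    landmark_mode: str = "random",
) -> OptimusResult:
    """Recommend a fingerprint/metric pair for a dataset with property values.

    Candidates failing to embed are logged and excluded; if every candidate
    fails an aggregate error reports the per-candidate causes.  Ties on mean
    CV score break by lower score sd, then grid order.
    """
    records = [
        r if isinstance(r, MoleculeRecord) else MoleculeRecord.from_smiles(r)
        for r in records
    ]
    y = np.array([r.y for r in records], dtype=float)
    if np.isnan(y).any():
        raise ValueError("macaw_optimus requires property values for all records")
    if len(records) < 2 * cv_folds:
        raise ValueError(f"need at least {2 * cv_folds} records for {cv_folds}-fold CV")

    # fixed fold assignment and landmark indices shared by every candidate
    cv = list(KFold(n_splits=cv_folds, shuffle=True, random_state=seed).split(y))
    rows = []
    failures = {}
    embedders = {}
    for spec in candidate_specs:
        for metric in candidate_metrics:
            try:
                emb = MacawEmbedder(
                    type_fp=spec,
                    metric=metric,
                    n_components=n_components,
                    n_landmarks=n_landmarks,
                    landmark_mode=landmark_mode,
                    seed=seed,
                )
                emb.train(records)
                X = emb.transform(records).coords
                scores = cross_val_score(
                    SVR(**_SELECTION_SVM), X, y, cv=cv, scoring="r2"
                )
                rows.append(
                    {
                        "type_fp": str(FingerprintSpec.parse(spec)),
                        "metric": metric,
                        "score_mean": float(scores.mean()),
                        "score_sd": float(scores.std()),
                    }
                )
                embedders[(rows[-1]["type_fp"], metric)] = emb
            except Exception as e:  # noqa: BLE001 - aggregate and report
                failures[(str(spec), metric)] = repr(e)
                logger.warning("candidate (%s, %s) failed: %r", spec, metric, e)
    if not rows:
        raise RuntimeError(f"all optimus candidates failed: {failures}")
    table = pd.DataFrame(rows)
    table["_order"] = range(len(table))
    table = table.sort_values(
        ["score_mean", "score_sd", "_order"], ascending=[False, True, True]
    ).drop(columns="_order").reset_index(drop=True)
    best = (table.loc[0, "type_fp"], table.loc[0, "metric"])
    return OptimusResult(table=table, best=best, embedder=embedders[best])
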