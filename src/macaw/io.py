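"""Shared file I/O: .smi and CSV molecule readers, embedding TSV, embedder bundles.

All SMILES are canonicalized on ingest; invalid lines are dropped with a
logged count (readers) — embedding-time APIs, by contrast, raise on invalid
input rather than silently dropping.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_distance import InvalidMoleculeError, MoleculeRecord
from .embedder import Embedding, LandmarkSet, MacawEmbedder

logger = logging.getLogger(__name__)

__all__ = [
    "read_smi", "read_csv_molecules", "write_embedding_tsv", "read_embedding_tsv",
    "save_embedder", "load_embedder",
]

BUNDLE_FORMAT_VERSION = 1


def read_smi(path) -> list[MoleculeRecord]:
    """Read a .smi file: one SMILES per line, optional tab-separated name.

    Lines starting with ``#`` and blank lines are ignored; unparseable
    SMILES are dropped and counted in a log message.
    """
    records: list[MoleculeRecord] = []
    dropped = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles, name = parts[0], (parts[1] if len(parts) > 1 else None)
        try:
            records.append(MoleculeRecord.from_smiles(smiles, id=name))
        except InvalidMoleculeError:
            dropped += 1
    if dropped:
        logger.warning("read_smi(%s): dropped %d invalid lines", path, dropped)
    return records


def read_csv_molecules(path, y_col: str | None = None) -> list[MoleculeRecord]:
    """Read molecules from a CSV with a ``smiles`` column (+ optional property)."""
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols:
        raise ValueError(f"{path}: CSV needs a 'smiles' column; found {list(df.columns)}")
    if y_col is not None and y_col not in df.columns:
        raise ValueError(f"{path}: no column {y_col!r}")
    records = []
    dropped = 0
    for _, row in df.iterrows():
        try:
            records.append(
                MoleculeRecord.from_smiles(
                    str(row[cols["smiles"]]),
                    y=float(row[y_col]) if y_col is not None else None,
                )
            )
        except (InvalidMoleculeError, ValueError):
            dropped += 1
    if dropped:
        logger.warning("read_csv_molecules(%s): dropped %d invalid rows", path, dropped)
    return records


def write_embedding_tsv(embedding: Embedding, path) -> None:
    """Write an embedding as TSV with header smiles, c1..cD."""
    D = embedding.coords.shape[1]
    df = pd.DataFrame(embedding.coords, columns=[f"c{j+1}" for j in range(D)])
    df.insert(0, "smiles", embedding.smiles)
    df.to_csv(path, sep="\t", index=False)


def read_embedding_tsv(path) -> Embedding:
    df = pd.read_csv(path, sep="\t", comment="#")
    return Embedding(df.iloc[:, 1:].to_numpy(dtype=float), df["smiles"].tolist())


def save_embedder(embedder: MacawEmbedder, path) -> None:
    """Serialize a trained embedder to a versioned JSON bundle."""
    embedder._require_trained()
    bundle = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "type_fp": str(embedder.spec),
        "metric": embedder.metric,
        "algorithm": embedder.algorithm,
        "n_components": embedder.n_components,
        "n_landmarks": embedder.n_landmarks,
        "landmark_mode": embedder.landmark_mode,
        "n_bins": embedder.n_bins,
        "isomap_k": embedder.isomap_k,
        "seed": embedder.seed,
        "landmark_smiles": embedder.landmark_smiles,
        "landmark_indices": list(embedder.landmarks.indices),
        "landmark_coords": embedder.landmark_coords.tolist(),
        "eigenvalues": None
        if embedder.eigenvalues is None
        else embedder.eigenvalues.tolist(),
    }
    Path(path).write_text(json.dumps(bundle))


def load_embedder(path) -> MacawEmbedder:
    """Rebuild a trained embedder from a JSON bundle.

    Landmark fingerprints and distances are recomputed from the stored
    landmark SMILES (deterministic), and the reconstruction is verified to
    reproduce the stored landmark coordinates.
    """
    bundle = json.loads(Path(path).read_text())
    if bundle.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported bundle version {bundle.get('format_version')}")
    emb = MacawEmbedder(
        type_fp=bundle["type_fp"],
        metric=bundle["metric"],
        n_components=bundle["n_components"],
        n_landmarks=bundle["n_landmarks"],
        algorithm=bundle["algorithm"],
        landmark_mode=bundle["landmark_mode"],
        n_bins=bundle["n_bins"],
        isomap_k=bundle["isomap_k"],
        seed=bundle["seed"],
    )
    from .chem_distance import _fingerprint_matrix, pairwise_distances

    emb.landmarks = LandmarkSet(
        tuple(bundle["landmark_indices"]), bundle["landmark_mode"],
        bundle["n_bins"], bundle["seed"],
    )
    emb.landmark_smiles = list(bundle["landmark_smiles"])
    lm = [MoleculeRecord(s) for s in emb.landmark_smiles]
    emb.landmark_fps = _fingerprint_matrix(lm, emb.spec)
    emb.landmark_dist = pairwise_distances(lm, None, emb.spec, emb.metric,
                                           fps_A=emb.landmark_fps)
    emb._fit_projector()
    emb._trained = True
    stored = np.asarray(bundle["landmark_coords"], dtype=float)
    if not np.allclose(emb.landmark_coords, stored, atol=1e-6):
        raise ValueError(f"{path}: landmark coordinates do not reproduce; "
                         "bundle may come from a different toolkit version")
    return emb
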