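"""Delimited-text readers/writers and run manifests.

Everything on disk is comma-separated text with a header row. An adjacency
matrix is written twice — as a labelled square 0/1 matrix and as a
two-column edge list — and either form reads back to the same matrix.
User-facing files carry ROI labels, never internal indices.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from ._validation import check_adjacency

__all__ = [
    "write_adjacency",
    "read_adjacency",
    "write_residuals",
    "read_residuals",
    "write_manifest",
]


def _edge_path(path: Path) -> Path:
    return path.with_suffix(".edges.csv")


def write_adjacency(path, W, labels=None) -> tuple[Path, Path]:
    """Write a network as a labelled square matrix and an edge list.

    Returns the (matrix, edge-list) paths; the edge list lives next to the
    matrix with an ``.edges.csv`` suffix.
    """
    W = check_adjacency(W)
    path = Path(path)
    K = W.shape[0]
    if labels is None:
        labels = [f"roi_{k + 1:02d}" for k in range(K)]
    if len(labels) != K:
        raise ValueError(f"{len(labels)} labels for a {K}-node network")
    df = pd.DataFrame(W.astype(int), index=labels, columns=labels)
    df.to_csv(path, index_label="roi")
    j, k = np.triu_indices(K, k=1)
    keep = W[j, k] == 1
    edges = pd.DataFrame(
        {
            "source": [labels[a] for a in j[keep]],
            "target": [labels[b] for b in k[keep]],
        }
    )
    epath = _edge_path(path)
    edges.to_csv(epath, index=False)
    return path, epath


def read_adjacency(path) -> tuple[np.ndarray, list[str]]:
    """Read a network from either on-disk form; returns (matrix, labels).

    A file whose header is exactly ``source,target`` is parsed as an edge
    list (labels in first-appearance order); anything else as a labelled
    square matrix. Binary/symmetric/zero-diagonal is enforced on read.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) == ["source", "target"]:
        labels = list(dict.fromkeys(df["source"].tolist() + df["target"].tolist()))
        index = {lab: i for i, lab in enumerate(labels)}
        K = len(labels)
        W = np.zeros((K, K))
        for s, t in df.itertuples(index=False):
            W[index[s], index[t]] = W[index[t], index[s]] = 1.0
        return check_adjacency(W), labels
    df = df.set_index(df.columns[0])
    labels = list(df.columns)
    if list(df.index) != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return check_adjacency(df.to_numpy(dtype=float)), labels


def write_residuals(path, B, labels=None, ids=None, id_column="participant_id") -> Path:
    """Write an N x K residual matrix as CSV with ROI labels and subject IDs."""
    path = Path(path)
    B = np.asarray(B, dtype=float)
    if labels is None:
        labels = [f"roi_{k + 1:02d}" for k in range(B.shape[1])]
    df = pd.DataFrame(B, columns=labels)
    if ids is not None:
        df.insert(0, id_column, list(ids))
    df.to_csv(path, index=False)
    return path


def read_residuals(path, id_column="participant_id"):
    """Read a residual matrix CSV; returns (values, roi labels, ids-or-None)."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: file has a header but no data rows")
    ids = None
    if id_column in df.columns:
        ids = df[id_column].tolist()
        df = df.drop(columns=[id_column])
    return df.to_numpy(dtype=float), list(df.columns), ids


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, config: dict, seed, inputs=(), outputs=()) -> Path:
    """Record what a run did: command, config echo, seed, file digests."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "outputs": {str(p): _digest(Path(p)) for p in outputs},
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
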