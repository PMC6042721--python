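"""Shared input checks for adjacency matrices and data tables."""

from __future__ import annotations

import numpy as np


class DegenerateDataError(ValueError):
    """Raised when the data carry no usable information (e.g. zero variance)."""


def check_adjacency(W, *, name: str = "W") -> np.ndarray:
    """Validate a binary, symmetric, zero-diagonal adjacency matrix.

    Returns the matrix as a float64 array (float keeps downstream linear
    algebra free of silent integer upcasts).
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {W.shape}")
    if not np.isin(W, (0.0, 1.0)).all():
        raise ValueError(f"{name} entries must be 0 or 1")
    if np.any(np.diag(W) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    if not np.array_equal(W, W.T):
        raise ValueError(f"{name} must be symmetric")
    return W


def check_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if not 0.0 <= gamma < 1.0:
        raise ValueError(
            f"gamma must lie in [0, 1); got {gamma}. At gamma = 1 the precision "
            "matrix becomes a graph Laplacian and is singular."
        )
    return gamma


def check_sigma2(sigma2: float) -> float:
    sigma2 = float(sigma2)
    if not sigma2 > 0.0:
        raise ValueError(f"sigma2 must be strictly positive, got {sigma2}")
    return sigma2


def check_data(B, *, n_features: int | None = None, name: str = "B") -> np.ndarray:
    """Validate an N x K observation matrix: 2-D, finite, optionally K columns."""
    B = np.asarray(B, dtype=float)
    if B.ndim != 2:
        raise ValueError(f"{name} must be 2-D (participants x ROIs), got ndim={B.ndim}")
    if not np.isfinite(B).all():
        raise ValueError(f"{name} contains non-finite entries")
    if n_features is not None and B.shape[1] != n_features:
        raise ValueError(
            f"{name} has {B.shape[1]} columns but the network has {n_features} nodes"
        )
    return B


def upper_triangle_pairs(K: int) -> list[tuple[int, int]]:
    """Row-major enumeration of strict upper-triangle index pairs (j < k)."""
    return [(j, k) for j in range(K) for k in range(j + 1, K)]
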