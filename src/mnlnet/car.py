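"""Leroux-type multivariate CAR network likelihood.

The model places a zero-mean multivariate normal on each participant's vector
of K standardized ROI residuals,

    b_i ~ MVN(0, sigma2 * Q),    Q^{-1} = gamma * (W_hat - W) + (1 - gamma) * I,

where W is a binary, symmetric, zero-diagonal adjacency matrix encoding which
ROI pairs share a network link and W_hat is the diagonal matrix of its row
sums (node degrees), so W_hat - W is the graph Laplacian of the network. The
spatial-dependence parameter gamma in [0, 1) mixes that Laplacian with the
identity; gamma = 0 gives independent ROIs, values near 1 strong spatial
coupling. sigma2 > 0 is the overall spatial scale variance.

This module evaluates the log-likelihood of an N x K data matrix under a
candidate network, profiles sigma2 in closed form, and — the workhorse of the
greedy search — scores single-edge flips incrementally: toggling one edge
(j, k) perturbs the precision by the rank-one matrix

    +- gamma * (e_j - e_k)(e_j - e_k)^T,

so the log-determinant moves by a matrix-determinant-lemma term and the
quadratic form by the corresponding entries of B^T B. All dense evaluations
go through a Cholesky factor of the precision; the precision is never
inverted to compute a likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from ._validation import (
    DegenerateDataError,
    check_adjacency,
    check_data,
    check_gamma,
    check_sigma2,
)

__all__ = [
    "CarParams",
    "build_precision",
    "log_network_likelihood",
    "profile_sigma2",
    "LikelihoodState",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class CarParams:
    """Fixed parameters of the CAR likelihood.

    Parameters
    ----------
    gamma : float
        Spatial-dependence strength in [0, 1). Conventionally fixed at 0.9
        for cortical networks rather than estimated.
    sigma2 : float
        Spatial scale variance, > 0, in squared standardized-residual units.
    """

    gamma: float = 0.9
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        check_gamma(self.gamma)
        check_sigma2(self.sigma2)


def build_precision(W, gamma: float) -> np.ndarray:
    """Unscaled CAR precision  Q^{-1} = gamma (W_hat - W) + (1 - gamma) I.

    Symmetric positive definite for every valid adjacency matrix and every
    gamma in [0, 1): the Laplacian term is PSD and (1 - gamma) I pushes the
    spectrum strictly above zero.
    """
    W = check_adjacency(W)
    gamma = check_gamma(gamma)
    K = W.shape[0]
    degrees = W.sum(axis=1)
    Q_inv = -gamma * W
    Q_inv[np.diag_indices(K)] = gamma * degrees + (1.0 - gamma)
    return Q_inv


def _chol_logdet(Q_inv: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor and log-determinant of the precision."""
    try:
        L = linalg.cholesky(Q_inv, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise np.linalg.LinAlgError(
            "precision matrix is not positive definite; this indicates "
            "gamma >= 1 or a corrupted adjacency matrix"
        ) from exc
    return L, 2.0 * float(np.sum(np.log(np.diag(L))))


def log_network_likelihood(B, W, params: CarParams) -> float:
    """Log-likelihood of the data under the network.

    sum_i [ -(K/2) log(2 pi sigma2) + (1/2) log|Q^{-1}|
            - (1 / (2 sigma2)) b_i^T Q^{-1} b_i ].

    The quadratic term is computed as trace(Q^{-1} B^T B); the determinant
    comes from the Cholesky factor's diagonal.
    """
    Q_inv = build_precision(W, params.gamma)
    B = check_data(B, n_features=Q_inv.shape[0])
    N, K = B.shape
    _, logdet = _chol_logdet(Q_inv)
    quad = float(np.einsum("ij,ji->", Q_inv, B.T @ B))
    return (
        -0.5 * N * K * (_LOG_2PI + np.log(params.sigma2))
        + 0.5 * N * logdet
        - quad / (2.0 * params.sigma2)
    )


def profile_sigma2(B, W, gamma: float) -> float:
    """Closed-form maximiser of the likelihood in sigma2 at fixed W.

    Setting the sigma2-derivative of the log-likelihood to zero gives

        sigma2_hat = trace(Q^{-1} B^T B) / (N K),

    the unique stationary point, which is a maximum.
    """
    Q_inv = build_precision(W, gamma)
    B = check_data(B, n_features=Q_inv.shape[0])
    N, K = B.shape
    quad = float(np.einsum("ij,ji->", Q_inv, B.T @ B))
    if quad <= 0.0:
        raise DegenerateDataError(
            "profiled sigma2 is zero: the data matrix carries no variation"
        )
    return quad / (N * K)


class LikelihoodState:
    """Mutable cache for fast likelihood evaluation under single-edge flips.

    Holds the current adjacency matrix, the precision, its covariance (kept
    in sync by Sherman–Morrison rank-one updates when flips are committed),
    the log-determinant, and the data cross-product S_B = B^T B. A flip of
    edge (j, k) is scored in O(1) and committed in O(K^2).

    The cached log-likelihood always agrees with a from-scratch
    :func:`log_network_likelihood` evaluation; :meth:`refresh` re-derives all
    caches by a fresh Cholesky factorisation (cheap at K <= a few hundred)
    and is called once per search sweep to stop float drift accumulating
    across thousands of rank-one updates.
    """

    def __init__(self, B, W, gamma: float = 0.9, sigma2: float = 1.0) -> None:
        self.W = check_adjacency(W).copy()
        self.gamma = check_gamma(gamma)
        self.sigma2 = check_sigma2(sigma2)
        B = check_data(B, n_features=self.W.shape[0])
        self.n_samples, self.n_nodes = B.shape
        self.S_B = B.T @ B
        self.refresh()

    # -- cache construction -------------------------------------------------

    def refresh(self) -> None:
        """Recompute precision, covariance, log-det and quadratic from scratch."""
        self.precision = build_precision(self.W, self.gamma)
        L, self.logdet = _chol_logdet(self.precision)
        identity = np.eye(self.n_nodes)
        # covariance of the unscaled CAR field, (Q^{-1})^{-1}
        self.covariance = linalg.cho_solve((L, True), identity)
        self.covariance = 0.5 * (self.covariance + self.covariance.T)
        self.quad = float(np.einsum("ij,ji->", self.precision, self.S_B))

    @property
    def loglik(self) -> float:
        N, K = self.n_samples, self.n_nodes
        return (
            -0.5 * N * K * (_LOG_2PI + np.log(self.sigma2))
            + 0.5 * N * self.logdet
            - self.quad / (2.0 * self.sigma2)
        )

    # -- edge flips ---------------------------------------------------------

    def _flip_terms(self, j: int, k: int) -> tuple[float, float, float]:
        if j == k:
            raise IndexError("cannot flip a diagonal entry (self-links are fixed at 0)")
        # sign +1 adds the edge, -1 removes it
        sign = 1.0 - 2.0 * self.W[j, k]
        c = sign * self.gamma
        M = self.covariance
        u_M_u = M[j, j] + M[k, k] - 2.0 * M[j, k]
        S = self.S_B
        u_S_u = S[j, j] + S[k, k] - 2.0 * S[j, k]
        return c, u_M_u, u_S_u

    def flip_delta(self, j: int, k: int) -> float:
        """Log-likelihood change from toggling edge (j, k); no state mutation.

        The precision changes by c * u u^T with u = e_j - e_k and
        c = +-gamma, so

            delta = (N/2) log(1 + c u^T Q u) - c (S_jj + S_kk - 2 S_jk) / (2 sigma2).
        """
        c, u_M_u, u_S_u = self._flip_terms(j, k)
        growth = 1.0 + c * u_M_u
        if growth <= 0.0:  # roundoff guard; mathematically impossible for gamma < 1
            return -np.inf
        return (
            0.5 * self.n_samples * np.log(growth)
            - c * u_S_u / (2.0 * self.sigma2)
        )

    def commit_flip(self, j: int, k: int) -> float:
        """Toggle edge (j, k), updating every cache; returns the delta applied."""
        c, u_M_u, u_S_u = self._flip_terms(j, k)
        delta = (
            0.5 * self.n_samples * np.log1p(c * u_M_u)
            - c * u_S_u / (2.0 * self.sigma2)
        )
        new = 1.0 - self.W[j, k]
        self.W[j, k] = self.W[k, j] = new
        # precision: four entries change
        self.precision[j, j] += c
        self.precision[k, k] += c
        self.precision[j, k] -= c
        self.precision[k, j] -= c
        # covariance: Sherman-Morrison rank-one downdate
        v = self.covariance[:, j] - self.covariance[:, k]
        self.covariance -= (c / (1.0 + c * u_M_u)) * np.outer(v, v)
        self.logdet += float(np.log1p(c * u_M_u))
        self.quad += c * u_S_u
        return float(delta)

    # -- sigma2 -------------------------------------------------------------

    def set_sigma2(self, sigma2: float) -> None:
        self.sigma2 = check_sigma2(sigma2)

    def profile_sigma2(self) -> float:
        """Closed-form sigma2 maximiser at the current adjacency matrix."""
        if self.quad <= 0.0:
            raise DegenerateDataError("degenerate data: profiled sigma2 is zero")
        return self.quad / (self.n_samples * self.n_nodes)
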