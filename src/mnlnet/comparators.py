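"""Benchmark network estimators and recovery scoring.

Two standard ways of turning an ROI-by-subject table into a binary network:

* Pearson pairwise correlation (PPC) thresholding — link two ROIs when the
  absolute sample correlation of their columns is at least tau (inclusive).
* Graphical lasso (gLASSO) — estimate an L1-penalised sparse precision
  matrix and link ROIs whose off-diagonal precision entry is numerically
  non-zero. The convex solver is delegated to scikit-learn.

Both trade sensitivity against specificity through their tuning parameter;
``grid_evaluate`` sweeps a grid and scores each resulting network against a
known truth over the strict upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.covariance import graphical_lasso

from ._validation import DegenerateDataError, check_adjacency, check_data

__all__ = [
    "CorrelationThresholdNetwork",
    "GraphicalLassoNetwork",
    "RecoveryScore",
    "ppc_network",
    "glasso_network",
    "score_network",
    "grid_evaluate",
]


@dataclass(frozen=True)
class RecoveryScore:
    """Confusion counts of an estimated network against the truth.

    Counts are over the strict upper triangle only (the matrices are
    symmetric). Sensitivity is the proportion of true links recovered,
    specificity the proportion of true non-links recovered; a ratio with an
    empty denominator is reported as None, never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None


def _check_columns_vary(B: np.ndarray) -> None:
    sd = B.std(axis=0)
    # roundoff from centering a constant column leaves sd ~ 1e-15, not 0
    bad = np.flatnonzero(sd <= 1e-10 * (1.0 + np.abs(B.mean(axis=0))))
    if bad.size:
        raise DegenerateDataError(
            f"column(s) {bad.tolist()} have zero variance; correlations undefined"
        )


class CorrelationThresholdNetwork(BaseEstimator):
    """Binary network from thresholded absolute Pearson correlations.

    Links ROI pair (j, k) iff |rho_jk| >= tau. Small tau admits links driven
    by spurious noise; large tau keeps only the strongest correlations and
    may disconnect the network.

    Parameters
    ----------
    tau : float
        Threshold in (0, 1); the comparison is inclusive (>=).

    Attributes
    ----------
    correlation_ : ndarray of shape (K, K)
        Sample correlation matrix.
    adjacency_ : ndarray of shape (K, K)
        Binary symmetric network, zero diagonal.
    """

    def __init__(self, tau: float = 0.5) -> None:
        self.tau = tau

    def fit(self, X, y=None):
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        B = check_data(X)
        _check_columns_vary(B)
        R = np.corrcoef(B, rowvar=False)
        A = (np.abs(R) >= self.tau).astype(float)
        np.fill_diagonal(A, 0.0)
        self.correlation_ = R
        self.adjacency_ = A
        self.n_features_in_ = B.shape[1]
        return self


class GraphicalLassoNetwork(BaseEstimator):
    """Binary network from the support of an L1-penalised precision matrix.

    Solves  max_Theta  log|Theta| - trace(S Theta) - lambda ||Theta||_1
    (scikit-learn's coordinate-descent graphical lasso) on the sample
    covariance S of the observations, then links ROI pairs whose estimated
    precision entry exceeds ``zero_tol`` in magnitude — numeric solvers
    return tiny non-zeros rather than exact zeros.

    Parameters
    ----------
    lambda_ : float
        Sparsity penalty >= 0. lambda_ = 0 reverts to the unpenalised MLE
        (generically dense); large lambda_ empties the network.
    zero_tol : float, default=1e-8
        Magnitude below which a precision entry counts as zero.
    assume_centered : bool, default=True
        The observations are modelled as zero-mean; set False to subtract
        column means before forming S.

    Attributes
    ----------
    precision_ : ndarray of shape (K, K)
        Penalised precision estimate.
    covariance_ : ndarray of shape (K, K)
        Matching covariance estimate.
    adjacency_ : ndarray of shape (K, K)
        Binarised support of the precision off-diagonals.
    """

    def __init__(
        self,
        lambda_: float = 0.5,
        zero_tol: float = 1e-8,
        assume_centered: bool = True,
        max_iter: int = 200,
    ) -> None:
        self.lambda_ = lambda_
        self.zero_tol = zero_tol
        self.assume_centered = assume_centered
        self.max_iter = max_iter

    def fit(self, X, y=None):
        if self.lambda_ < 0:
            raise ValueError(f"lambda_ must be >= 0, got {self.lambda_}")
        B = check_data(X)
        if not self.assume_centered:
            B = B - B.mean(axis=0)
        S = (B.T @ B) / B.shape[0]
        # alpha=0 is rejected by the solver; the unpenalised MLE is S^{-1}
        if self.lambda_ == 0.0:
            precision = np.linalg.inv(S)
            covariance = S.copy()
        else:
            try:
                covariance, precision = graphical_lasso(
                    S, alpha=self.lambda_, max_iter=self.max_iter
                )
            except FloatingPointError as exc:
                raise RuntimeError(
                    f"graphical lasso failed to converge at lambda={self.lambda_} "
                    f"within {self.max_iter} iterations: {exc}"
                ) from exc
        A = (np.abs(precision) > self.zero_tol).astype(float)
        np.fill_diagonal(A, 0.0)
        A = np.maximum(A, A.T)
        self.precision_ = precision
        self.covariance_ = covariance
        self.adjacency_ = A
        self.n_features_in_ = B.shape[1]
        return self


def ppc_network(B, tau: float) -> np.ndarray:
    """Adjacency matrix from thresholded absolute Pearson correlations."""
    return CorrelationThresholdNetwork(tau=tau).fit(B).adjacency_


def glasso_network(B, lambda_: float, zero_tol: float = 1e-8, **kwargs) -> np.ndarray:
    """Adjacency matrix from the graphical-lasso precision support."""
    return (
        GraphicalLassoNetwork(lambda_=lambda_, zero_tol=zero_tol, **kwargs)
        .fit(B)
        .adjacency_
    )


def score_network(estimate, truth) -> RecoveryScore:
    """Confusion counts of ``estimate`` against ``truth``, upper triangle only."""
    estimate = check_adjacency(estimate, name="estimate")
    truth = check_adjacency(truth, name="truth")
    if estimate.shape != truth.shape:
        raise ValueError(
            f"size mismatch: estimate is {estimate.shape[0]} nodes, "
            f"truth is {truth.shape[0]}"
        )
    iu = np.triu_indices(truth.shape[0], k=1)
    e, t = estimate[iu].astype(bool), truth[iu].astype(bool)
    return RecoveryScore(
        tp=int(np.sum(e & t)),
        fp=int(np.sum(e & ~t)),
        tn=int(np.sum(~e & ~t)),
        fn=int(np.sum(~e & t)),
    )


def grid_evaluate(B, truth, method: str, grid) -> pd.DataFrame:
    """Score a tuning-parameter grid of one comparator against a known truth.

    Returns a tidy frame with one row per grid value: method, tuning, the
    four confusion counts, sensitivity and specificity. Reproduces the
    sensitivity/specificity trade-off curves in tabular form.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    makers = {"ppc": ppc_network, "glasso": glasso_network}
    if method not in makers:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(makers)}")
    rows = []
    for value in grid:
        A = makers[method](B, value)
        s = score_network(A, truth)
        rows.append(
            {
                "method": method,
                "tuning": value,
                "tp": s.tp,
                "fp": s.fp,
                "tn": s.tn,
                "fn": s.fn,
                "sensitivity": s.sensitivity,
                "specificity": s.specificity,
            }
        )
    return pd.DataFrame(rows)
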