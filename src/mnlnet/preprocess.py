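"""Covariate residualisation, standardisation and spatial diagnostics.

Real ROI tables carry nuisance structure (age, sex, genetic risk status)
that would otherwise masquerade as covariance between regions. Each ROI
column is therefore regressed on the covariates by ordinary least squares
(with an intercept), and the residuals are standardised to mean 0, sd 1 per
ROI — putting all regions on a common scale while preserving the
between-ROI correlation structure net of the covariates. The standardised
residual matrix is the data the network likelihood consumes.

After a network fit, Moran's I on per-participant residuals measures how
much spatial autocorrelation the fitted network failed to absorb: values
near the null expectation -1/(K-1) indicate the spatial structure was
adequately modelled. The natural residual for a zero-mean multivariate
normal is the whitened observation r_i = sigma_hat^{-1} L^T b_i (L the
lower Cholesky factor of the fitted precision), which is i.i.d. standard
normal exactly when the model is true.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import DegenerateDataError, check_adjacency, check_data
from .car import build_precision
from .mnl import FitResult

__all__ = [
    "CovariateResidualizer",
    "residualize",
    "morans_i",
    "residual_diagnostics",
    "DiagnosticsReport",
]


def _design_matrix(cov: pd.DataFrame | None, n_rows: int) -> tuple[np.ndarray, list[str]]:
    """Intercept-plus-covariates design; categorical columns are dummy-coded."""
    if cov is None or (hasattr(cov, "shape") and cov.shape[1] == 0):
        return np.ones((n_rows, 1)), ["intercept"]
    cov = pd.DataFrame(cov)
    numeric = pd.get_dummies(cov, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(numeric)), numeric.to_numpy(dtype=float)])
    names = ["intercept"] + list(numeric.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns whose removal restores full rank
        redundant = []
        for i in range(1, X.shape[1]):
            others = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                redundant.append(names[i])
        raise ValueError(
            f"covariate design is rank deficient; collinear column(s): {redundant}"
        )
    return X, names


def residualize(roi, covariates=None, id_column: str = "participant_id"):
    """OLS-residualise each ROI column on the covariates, then standardise.

    For each ROI k, fit y_.k = X beta + eps by least squares (X = intercept
    plus covariates), and return b_.k = (eps_.k - mean(eps_.k)) / sd(eps_.k)
    with the N-1 sd denominator. With no covariates this reduces to
    centering and scaling each column. Output columns each have mean 0 and
    sd 1.

    ``roi`` and ``covariates`` may be DataFrames; if both carry
    ``id_column`` the rows must align and the column is dropped from the
    model. Returns a DataFrame when given one, else an ndarray.
    """
    roi_df = None
    if isinstance(roi, pd.DataFrame):
        roi_df = roi
        if isinstance(covariates, pd.DataFrame) and id_column in covariates.columns:
            if id_column in roi_df.columns:
                mismatch = roi_df[id_column].to_numpy() != covariates[id_column].to_numpy()
                if mismatch.any():
                    first = int(np.flatnonzero(mismatch)[0])
                    raise ValueError(
                        f"participant IDs misaligned at row {first}: "
                        f"{roi_df[id_column].iloc[first]!r} vs "
                        f"{covariates[id_column].iloc[first]!r}"
                    )
            covariates = covariates.drop(columns=[id_column])
        if id_column in roi_df.columns:
            roi = roi_df.drop(columns=[id_column])
        else:
            roi = roi_df
        labels = list(roi.columns)
        Y = roi.to_numpy(dtype=float)
    else:
        Y = np.asarray(roi, dtype=float)
        labels = None
    if Y.shape[0] == 0:
        raise ValueError("empty input: no participant rows")
    Y = check_data(Y, name="roi")

    X, _ = _design_matrix(covariates, Y.shape[0])
    if Y.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more participants ({Y.shape[0]}) than design columns ({X.shape[1]})"
        )
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    resid -= resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        which = [labels[i] for i in dead] if labels else dead.tolist()
        raise DegenerateDataError(f"zero residual variance in ROI(s): {which}")
    B = resid / sd
    if roi_df is not None:
        out = pd.DataFrame(B, columns=labels, index=roi_df.index)
        if id_column in roi_df.columns:
            out.insert(0, id_column, roi_df[id_column])
        return out
    return B


class CovariateResidualizer(TransformerMixin, BaseEstimator):
    """Transformer wrapper over :func:`residualize`.

    Parameters
    ----------
    covariates : DataFrame or None
        Covariate table row-aligned with the ROI table passed to
        ``transform``. None means centre-and-scale only.

    Notes
    -----
    The transform is study-internal (residuals are defined against the same
    rows they are computed from), so ``fit`` only records dimensions and
    ``transform`` performs the regression on the rows it is given.
    """

    def __init__(self, covariates=None, id_column: str = "participant_id") -> None:
        self.covariates = covariates
        self.id_column = id_column

    def fit(self, X, y=None):
        self.n_features_in_ = (
            X.shape[1] - (1 if isinstance(X, pd.DataFrame) and self.id_column in X else 0)
        )
        return self

    def transform(self, X):
        return residualize(X, self.covariates, id_column=self.id_column)


def morans_i(x, W) -> float:
    """Moran's I spatial autocorrelation of node values x on network W.

    I = (K / sum_jk w_jk) * sum_jk w_jk (x_j - xbar)(x_k - xbar)
                          / sum_j (x_j - xbar)^2,

    with both double sums over all ordered pairs. Near zero (more precisely
    the null expectation -1/(K-1)) means no spatial correlation along the
    network; positive values mean linked nodes co-vary.
    """
    W = check_adjacency(W)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != W.shape[0]:
        raise ValueError("x must be a length-K vector matching W")
    w_sum = W.sum()
    if w_sum == 0:
        raise ValueError("Moran's I is undefined for a network with no links")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise DegenerateDataError("Moran's I is undefined for a constant vector")
    return float(len(x) / w_sum * (xc @ W @ xc) / denom)


@dataclass
class DiagnosticsReport:
    """Per-participant spatial diagnostics of a fitted network."""

    morans: np.ndarray          # one Moran's I per participant
    median_morans: float
    whitened: np.ndarray        # N x K residual matrix actually diagnosed
    roi_mean: np.ndarray        # per-ROI residual means
    roi_sd: np.ndarray          # per-ROI residual sds (≈1 when the model holds)
    null_expectation: float     # -1/(K-1)


def residual_diagnostics(B, fit: FitResult, whiten: bool = True) -> DiagnosticsReport:
    """Moran's I of per-participant residuals against the fitted network.

    With ``whiten`` (default) the residuals are r_i = sigma_hat^{-1} L^T b_i
    where L L^T is the Cholesky factorisation of the fitted unscaled
    precision — i.i.d. N(0, 1) entries when the model is true, so their
    Moran's I should scatter around -1/(K-1). ``whiten=False`` diagnoses the
    raw observations instead.
    """
    W = check_adjacency(fit.adjacency, name="fitted adjacency")
    B = check_data(B, n_features=W.shape[0])
    if W.sum() == 0:
        raise ValueError(
            "the fitted network has no links; Moran's I diagnostics are undefined"
        )
    if whiten:
        Q_inv = build_precision(W, fit.gamma)
        L = linalg.cholesky(Q_inv, lower=True)
        R = (B @ L) / np.sqrt(fit.sigma2)
    else:
        R = np.asarray(B, dtype=float)
    morans = np.array([morans_i(row, W) for row in R])
    K = W.shape[0]
    return DiagnosticsReport(
        morans=morans,
        median_morans=float(np.median(morans)),
        whitened=R,
        roi_mean=R.mean(axis=0),
        roi_sd=R.std(axis=0, ddof=1),
        null_expectation=-1.0 / (K - 1),
    )
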