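"""Signed-path-coefficient Granger causality via VAR(1) with covariates.

The effective-connectivity model: every network's present value is
regressed on all networks' values one step back plus a contemporaneous
covariate term,

    Y_jt = sum_k A_jk Y_k(t-1) + C_j Z_t + b_j + e_jt,

and the signed regression coefficients A_jk (k != j) are taken as directed
path strengths k -> j. The covariate enters the model rather than being
regressed out beforehand. Only lag order 1 is supported: higher orders
multiply the coefficient matrices and have no agreed group-level reading.

Estimation is equation-by-equation ordinary least squares, which for an
unrestricted VAR coincides with the multivariate least-squares solution
and keeps every coefficient and its standard error in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


class GrangerVAR(BaseEstimator):
    """Lag-1 vector autoregression with contemporaneous covariates.

    Parameters
    ----------
    order : int, default 1
        Lag order; only 1 is supported (validated, not generalized).
    standardize : bool, default True
        Z-score each network time course before fitting so path
        coefficients are on a common scale across subjects, as the
        group-level edge statistics assume.
    include_intercept : bool, default True

    Attributes (after ``fit``)
    --------------------------
    coef_ : (N, N) array
        ``coef_[j, k]`` is the signed path coefficient of node k's past on
        node j's present; the diagonal holds the autoregressive terms.
    covar_coef_ : (N, c) contemporaneous covariate coefficients.
    intercept_ : (N,) intercepts.
    residuals_ : (T - order, N) per-equation residuals.
    coef_se_, covar_se_, intercept_se_ : standard errors, same shapes.
    sigma2_ : (N,) per-equation residual variances (unbiased).
    node_labels_ : column labels when a DataFrame was passed.
    """

    def __init__(self, order: int = 1, standardize: bool = True,
                 include_intercept: bool = True):
        self.order = order
        self.standardize = standardize
        self.include_intercept = include_intercept

    def fit(self, Y, Z=None):
        if self.order != 1:
            raise ValueError("only order=1 is supported")
        if isinstance(Y, pd.DataFrame):
            labels = list(Y.columns)
            Ya = Y.to_numpy(dtype=float)
        else:
            Ya = np.asarray(Y, dtype=float)
            labels = [f"node{i}" for i in range(Ya.shape[1])]
        if Ya.ndim != 2:
            raise ValueError("Y must be 2-D (T x N)")
        T, N = Ya.shape
        if not np.all(np.isfinite(Ya)):
            raise ValueError("Y contains non-finite values")
        sds = Ya.std(axis=0)
        if np.any(sds == 0):
            bad = [labels[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"constant columns cannot be fit: {bad}")

        if Z is None:
            Za = np.empty((T, 0))
        else:
            Za = np.asarray(Z, dtype=float)
            if Za.ndim == 1:
                Za = Za.reshape(-1, 1)
            if Za.shape[0] != T:
                raise ValueError("Z must have the same number of rows as Y")
            if not np.all(np.isfinite(Za)):
                raise ValueError("Z contains non-finite values")
        c = Za.shape[1]

        n_params = N + c + (1 if self.include_intercept else 0)
        if T - 1 <= n_params:
            raise ValueError(
                f"T={T} too small: need at least {n_params + 2} time points "
                f"for {n_params} parameters per equation"
            )

        if self.standardize:
            Ya = (Ya - Ya.mean(axis=0)) / sds

        # design: lagged values, contemporaneous covariates, intercept
        X_parts = [Ya[:-1]]
        if c:
            X_parts.append(Za[1:])
        if self.include_intercept:
            X_parts.append(np.ones((T - 1, 1)))
        X = np.hstack(X_parts)
        target = Ya[1:]

        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            names = list(labels) + [f"Z{i}" for i in range(c)]
            if self.include_intercept:
                names.append("intercept")
            from scipy.linalg import qr

            _, r, piv = qr(X, mode="economic", pivoting=True)
            tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
            bad = sorted(piv[np.abs(np.diag(r)) <= tol].tolist())
            raise ValueError(
                f"design matrix is rank deficient; collinear columns: "
                f"{[names[i] for i in bad]}"
            )

        B, *_ = np.linalg.lstsq(X, target, rcond=None)  # (N+c+1) x N
        fitted = X @ B
        resid = target - fitted
        dof = (T - 1) - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # (N+c+1) x N

        self.coef_ = B[:N].T  # [j, k] = effect of k on j
        self.coef_se_ = se[:N].T
        if c:
            self.covar_coef_ = B[N:N + c].T
            self.covar_se_ = se[N:N + c].T
        else:
            self.covar_coef_ = np.empty((N, 0))
            self.covar_se_ = np.empty((N, 0))
        if self.include_intercept:
            self.intercept_ = B[-1]
            self.intercept_se_ = se[-1]
        else:
            self.intercept_ = np.zeros(N)
            self.intercept_se_ = np.zeros(N)
        self.residuals_ = resid
        self.fitted_ = fitted
        self.sigma2_ = sigma2
        self.df_resid_ = dof
        self.nobs_ = T - 1
        self.node_labels_ = labels
        self.n_covariates_ = c
        return self

    def path_matrix(self, diagonal=np.nan) -> np.ndarray:
        """Cross-network signed path coefficients, oriented
        [row = target, column = source]; the diagonal (self influence) is
        replaced by a sentinel so it never enters edge statistics."""
        A = self.coef_.copy()
        np.fill_diagonal(A, diagonal)
        return A

    def path_frame(self) -> pd.DataFrame:
        """Path matrix as a labelled DataFrame in the column-causes-row
        convention used by the report tables."""
        return pd.DataFrame(self.path_matrix(), index=self.node_labels_,
                            columns=self.node_labels_)


def fit_mvar(Y, Z=None, order: int = 1, standardize: bool = True) -> GrangerVAR:
    """Fit the multivariate signed-path-coefficient model; see GrangerVAR."""
    return GrangerVAR(order=order, standardize=standardize).fit(Y, Z)


@dataclass
class BivariateFit:
    """Paired two-series Granger model X <-> Y.

    ``a_xy`` is the signed path coefficient of lagged X on Y and ``a_yx``
    of lagged Y on X; ``b_y``/``b_x`` the autoregressive terms;
    ``c_y``/``c_x`` covariate loadings; residuals per equation.
    """

    a_xy: float
    a_yx: float
    b_x: float
    b_y: float
    c_x: np.ndarray
    c_y: np.ndarray
    intercept_x: float
    intercept_y: float
    resid_x: np.ndarray
    resid_y: np.ndarray
    se_a_xy: float
    se_a_yx: float
    order: int = 1


def fit_bivariate(x, y, Z=None, order: int = 1,
                  standardize: bool = True) -> BivariateFit:
    """Fit the paired bivariate Granger model by explicit normal equations.

    Each series is regressed on both series' lagged values, the
    contemporaneous covariate(s) and an intercept. Solved directly from
    the Gram matrix, independently of the multivariate code path.
    """
    if order != 1:
        raise ValueError("only order=1 is supported")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    T = x.size
    if standardize:
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
    if Z is None:
        Za = np.empty((T, 0))
    else:
        Za = np.asarray(Z, dtype=float)
        if Za.ndim == 1:
            Za = Za.reshape(-1, 1)
    c = Za.shape[1]
    X = np.hstack([x[:-1, None], y[:-1, None], Za[1:], np.ones((T - 1, 1))])
    G = X.T @ X
    dof = (T - 1) - X.shape[1]
    Ginv = np.linalg.inv(G)

    def _solve(target):
        beta = Ginv @ (X.T @ target)
        resid = target - X @ beta
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(sigma2 * np.diag(Ginv))
        return beta, resid, se

    beta_y, resid_y, se_y = _solve(y[1:])  # eq for Y: A x(t-1) + B y(t-1)
    beta_x, resid_x, se_x = _solve(x[1:])
    return BivariateFit(
        a_xy=float(beta_y[0]), a_yx=float(beta_x[1]),
        b_x=float(beta_x[0]), b_y=float(beta_y[1]),
        c_x=beta_x[2:2 + c], c_y=beta_y[2:2 + c],
        intercept_x=float(beta_x[-1]), intercept_y=float(beta_y[-1]),
        resid_x=resid_x, resid_y=resid_y,
        se_a_xy=float(se_y[0]), se_a_yx=float(se_x[1]),
        order=order,
    )


def path_matrix(fit: GrangerVAR, diagonal=np.nan) -> np.ndarray:
    """Module-level convenience for :meth:`GrangerVAR.path_matrix`."""
    if fit.order != 1:
        raise ValueError("only order=1 path matrices are defined")
    return fit.path_matrix(diagonal=diagonal)


def cohort_path_stack(subjects, Z_from=None, standardize: bool = True):
    """Fit the VAR per subject and stack the path matrices.

    ``subjects`` is an iterable of objects with ``timeseries`` (T x N) and
    optionally ``covariate_series``; ``Z_from`` overrides how the covariate
    is obtained (callable subject -> array, or None to use
    ``covariate_series`` when present). Returns (S, N, N) array with NaN
    diagonals.
    """
    mats = []
    for sub in subjects:
        if Z_from is not None:
            Z = Z_from(sub)
        else:
            Z = getattr(sub, "covariate_series", None)
        fit = fit_mvar(sub.timeseries, Z, standardize=standardize)
        mats.append(fit.path_matrix())
    return np.stack(mats)
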