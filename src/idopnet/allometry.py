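"""Allometric power-law fits g(E) = alpha * E**beta.

Each gene's (or module's) expression is a part of the sample's
expression index E, and the part scales with the whole as a power law.
The fit criterion is least squares on the original scale, because the
downstream network likelihood assumes additive Gaussian error on
observed expression; ordinary least squares on log-log scale only
provides the initializer (``scale="log"`` switches the final estimate
to the log-OLS fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._power import powerlaw_fit_rows

__all__ = [
    "PowerFit",
    "PowerLawRegressor",
    "fit_power",
    "fit_power_matrix",
    "power_derivative",
    "residual_diagnostics",
]

MIN_SAMPLES = 3


@dataclass(frozen=True)
class PowerFit:
    """Fitted power curve alpha * E**beta with residual diagnostics."""

    alpha: float
    beta: float
    rss: float
    n_used: int

    @property
    def sigma2(self) -> float:
        return self.rss / self.n_used

    def predict(self, e):
        e = np.asarray(e, dtype=float)
        return self.alpha * e**self.beta

    def derivative(self, e):
        e = np.asarray(e, dtype=float)
        if np.any(e <= 0):
            raise ValueError("derivative requires positive E")
        return self.alpha * self.beta * e ** (self.beta - 1.0)


class PowerLawRegressor(RegressorMixin, BaseEstimator):
    """Power-law regression of expression on the expression index.

    scikit-learn estimator: ``X`` is the (n, 1) column of EI values and
    ``y`` the non-negative expression values.

    Parameters
    ----------
    scale : {"original", "log"}
        "original" (default) refines the log-OLS initializer by damped
        Gauss-Newton on the untransformed residuals; "log" keeps the
        log-OLS estimate as final.
    tol, max_iter : solver controls (relative objective change).
    """

    def __init__(self, scale: str = "original", tol: float = 1e-8, max_iter: int = 500):
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single EI column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] < MIN_SAMPLES:
            raise ValueError(f"need at least {MIN_SAMPLES} samples")
        if np.any(X <= 0):
            raise ValueError("EI values must be positive")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite inputs")
        if np.any(y < 0):
            raise ValueError("negative expression values")
        if not np.any(y > 0):
            raise ValueError("all expression values are zero; no curve to fit")
        w = None if sample_weight is None else np.asarray(sample_weight, float)[None, :]
        max_iter = 0 if self.scale == "log" else self.max_iter
        a, b, rss = powerlaw_fit_rows(
            y[None, :], X[None, :], w, max_iter=max_iter, tol=self.tol
        )
        self.alpha_ = float(a[0])
        self.beta_ = float(b[0])
        self.rss_ = float(rss[0])
        self.n_used_ = int(y.shape[0])
        self.sigma2_ = self.rss_ / self.n_used_
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        X = np.asarray(X, dtype=float)
        e = X[:, 0] if X.ndim == 2 else X
        return self.alpha_ * e**self.beta_

    def derivative(self, e):
        """Analytic slope d g / d E = alpha * beta * E**(beta-1)."""
        check_is_fitted(self, "alpha_")
        return self._fit().derivative(e)

    def _fit(self) -> PowerFit:
        return PowerFit(self.alpha_, self.beta_, self.rss_, self.n_used_)


# ----------------------------------------------------------------------
def fit_power(y, ei, scale: str = "original") -> PowerFit:
    """Fit alpha * E**beta to one expression vector by nonlinear least
    squares (log-OLS initialized)."""
    reg = PowerLawRegressor(scale=scale).fit(np.asarray(ei, float), np.asarray(y, float))
    return reg._fit()


def fit_power_matrix(Y, ei, weights=None):
    """Batched per-row power fits; returns (alpha, beta, rss) arrays.

    Rows with fewer than three positive entries are unfittable: their
    entries are returned as NaN so callers can exclude them.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    a, b, rss = powerlaw_fit_rows(Y, ei, weights)
    bad = (Y > 0).sum(axis=1) < MIN_SAMPLES
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    rss = np.where(bad, np.nan, rss)
    return a, b, rss


def power_derivative(fit: PowerFit, e) -> float:
    return fit.derivative(e)


def residual_diagnostics(fit: PowerFit, y, ei) -> pd.DataFrame:
    """Predicted/residual table ordered by EI.

    The lag-1 autocorrelation of EI-ordered residuals is stored in
    ``result.attrs["lag1_autocorr"]``; independence of residuals from
    the predictions supports the adequacy of the power form.
    """
    y = np.asarray(y, dtype=float)
    e = np.asarray(ei, dtype=float)
    if y.shape != e.shape:
        raise ValueError("length mismatch")
    order = np.argsort(e, kind="stable")
    pred = fit.predict(e[order])
    resid = y[order] - pred
    out = pd.DataFrame(
        {"ei": e[order], "observed": y[order], "predicted": pred, "residual": resid}
    )
    r = resid - resid.mean()
    denom = float(r @ r)
    out.attrs["lag1_autocorr"] = float(r[1:] @ r[:-1] / denom) if denom > 0 else np.nan
    out.attrs["rss"] = float(resid @ resid)
    return out
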