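"""Quasi-dynamic ODE decomposition of expression trajectories.

Each node's (gene's or module's) observed expression along the
expression index E is split as y(E) = P_ind(E) + sum_r P_dep_r(E) + e(E):
an independent component — the node's own power curve alpha*E**beta —
plus one dependent component per selected regulator, a Legendre basis
expansion in the regulator's expression.  The rate functions Q of the
underlying ODE system (derivatives with respect to E rather than time)
are recovered from the fitted P curves; a Runge-Kutta forward solve of
those rates is provided as a cross-check, not as the estimator.

Two parameterizations of the dependent component are available (see
NetworkModelConfig): the default "level" design reads the regulator's
observed expression, the "integrated" design accumulates a basis in the
regulator's smoothed curve along the EI grid.  Regulators are chosen
per target by group LASSO followed by adaptive group LASSO on
co-fluctuation features, with extended-BIC tuning along the penalty
path and a Dunbar-style cap on the number of links kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from numpy.polynomial import legendre
from scipy.integrate import cumulative_trapezoid
from sklearn.base import BaseEstimator, RegressorMixin

from ._grouplasso import adaptive_group_lasso_select, mgs_qr
from .allometry import fit_power_matrix
from .io import ExpressionDataset

__all__ = [
    "NetworkModelConfig",
    "RegulatorCurve",
    "QdODEFit",
    "QdODERegressor",
    "dependent_basis",
    "select_regulators",
    "fit_qdode",
    "fit_group_qdode",
    "decompose",
    "integrate_forward",
]


@dataclass(frozen=True)
class NetworkModelConfig:
    """Settings shared by selection, fitting and the permutation test.

    dependent_design:
        "level" (default) — each dependent component is the basis
        expansion of the regulator's observed expression, entering the
        target's level directly; the rate functions Q of the underlying
        ODE are recovered as derivatives.  This keeps the sample-wise
        co-fluctuation between target and regulator, which is what
        identifies *which* candidate regulates a target.
        "integrated" — the dependent component is the cumulative
        trapezoid integral along the EI grid of the basis in the
        regulator's smoothed expression (the rate-level
        parameterization); retained as an option and exercised by the
        Runge-Kutta cross-check, but every candidate's design block is
        then a smooth near-collinear curve of E, which makes regulator
        identity statistically unrecoverable.
    """

    order: int = 4  # Legendre degree of the dependent basis
    cap: int = 5  # max regulators kept per target
    n_lambda: int = 12
    lambda_min_ratio: float = 1e-3
    ebic_gamma: float = 0.5  # extended-BIC model-space weight
    n_factors: int = 0  # extra compositional factor columns in selection
    dependent_design: str = "level"  # "level" | "integrated"
    smooth_regulators: bool = False  # basis sees the regulator's power curve
    select: str = "adaptive"  # "adaptive" | "none" (keep all candidates)


@dataclass(frozen=True)
class RegulatorCurve:
    """What the dependent basis needs to re-evaluate a regulator at any E."""

    node: str
    alpha: float
    beta: float
    lo: float  # rescaling range of the (smoothed) expression
    hi: float

    def expression(self, e):
        return self.alpha * np.asarray(e, float) ** self.beta

    def basis(self, e, order):
        x = self.rescale(self.expression(e))
        return legendre.legvander(x, order)[:, 1:]

    def rescale(self, v):
        return 2.0 * (np.asarray(v, float) - self.lo) / (self.hi - self.lo) - 1.0


@dataclass
class QdODEFit:
    """One target's decomposition in one risk group."""

    target: str
    group: str
    alpha: float
    beta: float
    regulators: list  # ordered node ids
    theta: dict  # node id -> basis coefficients
    reg_curves: dict  # node id -> RegulatorCurve
    ei: np.ndarray  # ordered EI grid (the group's samples)
    observed: np.ndarray
    P_ind: np.ndarray
    P_dep: dict  # node id -> curve on the grid
    rss: float
    order: int = 4
    design: str = "level"

    @property
    def fitted(self) -> np.ndarray:
        out = self.P_ind.copy()
        for v in self.P_dep.values():
            out = out + v
        return out

    @property
    def n(self) -> int:
        return int(self.ei.shape[0])

    @property
    def sigma2(self) -> float:
        return self.rss / self.n

    @property
    def total_dependent(self) -> np.ndarray:
        if not self.P_dep:
            return np.zeros_like(self.ei)
        return np.sum(list(self.P_dep.values()), axis=0)

    def edge_curve(self, regulator: str) -> np.ndarray:
        """Dependent curve used for edge weights: evaluated through the
        regulator's smoothed expression and anchored at zero at the
        smallest EI, so that promotion (effect rising with the
        regulator) gives a positive curve in both designs."""
        if self.design == "integrated":
            return self.P_dep[regulator]  # already anchored at 0 at E_min
        rc = self.reg_curves[regulator]
        curve = rc.basis(self.ei, self.order) @ self.theta[regulator]
        return curve - curve[0]

    def edge_weight(self, regulator: str, at="grid-mean") -> float:
        curve = self.edge_curve(regulator)
        if isinstance(at, str):
            return float(curve.mean())
        return float(np.interp(at, self.ei, curve))

    def q_independent(self, e):
        e = np.asarray(e, float)
        return self.alpha * self.beta * e ** (self.beta - 1.0)

    def q_dependent(self, regulator: str, e):
        """Rate-level influence of a regulator at EI value(s) e.

        Integrated design: the basis expansion itself is the rate.
        Level design: the rate is the EI-derivative of the smoothed
        dependent curve (central finite difference)."""
        rc = self.reg_curves[regulator]
        e = np.asarray(e, float)
        if self.design == "integrated":
            return rc.basis(e, self.order) @ self.theta[regulator]
        h = 1e-5 * (self.ei[-1] - self.ei[0])
        up = rc.basis(e + h, self.order) @ self.theta[regulator]
        dn = rc.basis(e - h, self.order) @ self.theta[regulator]
        return (up - dn) / (2.0 * h)


# ----------------------------------------------------------------------
def dependent_basis(g_reg, order: int):
    """Legendre features (degree 1..order) of expression rescaled to
    [-1, 1] over its observed range; no intercept column, so a null
    regulator contributes exactly zero."""
    if order < 1:
        raise ValueError("order must be >= 1")
    v = np.asarray(g_reg, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite regulator expression")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0:
        raise ValueError("constant regulator expression: no usable basis")
    x = 2.0 * (v - lo) / (hi - lo) - 1.0
    return legendre.legvander(x, order)[:, 1:]


def _integrated(basis: np.ndarray, ei: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of each basis column along the ordered EI
    grid, anchored at zero at the smallest EI (the gauge choice)."""
    return cumulative_trapezoid(basis, ei, axis=0, initial=0.0)


# ----------------------------------------------------------------------
class _System:
    """Precomputed per-group quantities shared by all targets."""

    def __init__(self, Y, ei, node_ids, cfg: NetworkModelConfig):
        order = np.argsort(ei, kind="stable")
        self.ei = np.asarray(ei, float)[order]
        self.Y = np.asarray(Y, float)[:, order]
        self.node_ids = list(node_ids)
        self.cfg = cfg
        a, b, _ = fit_power_matrix(self.Y, self.ei)
        self.alpha0, self.beta0 = a, b
        self.smooth = np.where(
            np.isfinite(a)[:, None],
            np.nan_to_num(a)[:, None] * self.ei[None, :] ** np.nan_to_num(b)[:, None],
            self.Y,
        )
        # Compositional latent factor(s).  EI is the sum of the parts,
        # so each sample's aggregate noise shifts the shared regression
        # axis and shows up as a common factor loading on every node's
        # residual (expression j deviates by -w_j * d_i from any smooth
        # curve of the realized EI).  Estimated, as in RUV-style
        # unwanted-variation removal, by the leading singular vectors of
        # the standardized power-fit residual matrix, and supplied
        # unpenalized to the selection design so candidate regulators
        # cannot earn credit for it.
        self._resid = self.Y - self.smooth
        self._resid_var = np.maximum(self._resid.var(axis=1), 1e-30)
        # per-node, per-sample slope of the fitted curve: the
        # compositional factor loads on node c as -slope_c / sum(slopes)
        a_s = np.nan_to_num(a)
        b_s = np.nan_to_num(b)
        self._slopes = (a_s * b_s)[:, None] * self.ei[None, :] ** (b_s - 1.0)[:, None]
        self.e_latent = self._latent_index(a_s, b_s)
        src = self.smooth if cfg.smooth_regulators else self.Y
        # selection sees varying-coefficient co-fluctuation features:
        # the regulator's residual times a smooth basis of the latent
        # index.  A true regulation y ~ s(g_r) carries the term
        # s'(mu_r(E)) * eps_r, which only the true regulator's features
        # can represent; smooth-curve components are non-identifying
        # (collinear across candidates) and are left to the unpenalized
        # block.
        # For a closed system (the nodes sum to the EI, as at module
        # level) the EI axis carries every node's noise and the pooled
        # latent index is the better smooth coordinate; for an embedded
        # system (EI from a larger analyzed gene set) the EI itself is
        # accurate and is used directly.
        closed = np.allclose(self.Y.sum(axis=0), self.ei, rtol=1e-4)
        self.axis = self.e_latent if closed else self.ei
        le = np.log(self.axis)
        rng_ = max(le.max() - le.min(), 1e-12)
        le = 2.0 * (le - le.min()) / rng_ - 1.0
        self._axis_basis = legendre.legvander(le, max(cfg.order - 1, 0))
        self._smooth_axis_basis = legendre.legvander(le, max(4, cfg.order))
        self.Z, self.Zsel, self.curves = {}, {}, {}
        for j, node in enumerate(self.node_ids):
            v = src[j]
            lo, hi = float(v.min()), float(v.max())
            if hi - lo <= 0:
                continue  # constant node: ineligible as regulator
            B = dependent_basis(v, cfg.order)
            if cfg.dependent_design == "integrated":
                self.Z[node] = _integrated(B, self.ei)
            else:
                self.Z[node] = B
            self.Zsel[node] = self._resid[j][:, None] * self._axis_basis
            aa = a[j] if np.isfinite(a[j]) else 0.0
            bb = b[j] if np.isfinite(b[j]) else 0.0
            self.curves[node] = RegulatorCurve(node, float(aa), float(bb), lo, hi)

    def _latent_index(self, a, b) -> np.ndarray:
        """Per-sample latent expression index pooled across all nodes.

        The realized EI is itself a noisy measurement of the underlying
        index (it contains every node's noise), so regressing on smooth
        functions of the EI leaves structure that any other node can
        proxy for.  The GLS consensus index argmin_E sum_c
        (g_c - mu_c(E))^2 / sigma_c^2 removes that errors-in-variables
        axis ambiguity; solved by damped Gauss-Newton in u = log E from
        u0 = log EI.
        """
        ok = a > 0
        if ok.sum() < 2:
            return self.ei.copy()
        aa = a[ok][:, None]
        bb = b[ok][:, None]
        iv = (1.0 / self._resid_var[ok])[:, None]
        Y = self.Y[ok]
        u = np.log(self.ei)
        lo, hi = u.min() - 0.7, u.max() + 0.7
        for _ in range(25):
            mu = aa * np.exp(bb * u[None, :])
            r = Y - mu
            g1 = -2.0 * (iv * r * bb * mu).sum(axis=0)
            g2 = 2.0 * (iv * (bb * mu) ** 2).sum(axis=0)
            step = g1 / np.maximum(g2, 1e-30)
            step = np.clip(step, -0.2, 0.2)
            u = np.clip(u - step, lo, hi)
            if np.max(np.abs(step)) < 1e-10:
                break
        return np.exp(u)

    def index(self, node: str) -> int:
        return self.node_ids.index(node)

    def factors_for(self, node: str) -> np.ndarray:
        """Compositional-factor estimate for one target's selection.

        EI is the sum of the parts, so each sample's aggregate noise
        d_i shifts the regression axis and enters node c's residual as
        -w_ci * d_i with known loading w_ci = slope_c / sum(slopes).
        d is recovered per sample by weighted least squares across the
        other nodes' residuals (1/sigma^2 weights, which also discounts
        strongly regulated nodes); the target's own row is left out so
        genuine dependent effects cannot enter the factor.
        """
        n = self.ei.shape[0]
        if self.cfg.n_factors <= 0 or self.Y.shape[0] <= 3:
            return np.zeros((n, 0))
        j = self.index(node)
        keep = np.arange(self.Y.shape[0]) != j
        W = self._slopes[keep]
        W = W / np.maximum(self._slopes.sum(axis=0)[None, :], 1e-30)
        r = self._resid[keep]
        iv = (1.0 / self._resid_var[keep])[:, None]
        denom = np.maximum((W * W * iv).sum(axis=0), 1e-30)
        d_hat = -(W * iv * r).sum(axis=0) / denom
        return d_hat[:, None]


@njit(cache=True)
def _gn_profiled(y, le, Q, u0, b0, max_iter, tol):
    """Damped Gauss-Newton on (log alpha, beta) with the dependent
    coefficients profiled out by projection onto span(Q) (orthonormal).

    ``le`` is the centered log-EI; ``Q`` may have zero columns.
    Returns (u, b, objective)."""
    n = y.shape[0]
    k = Q.shape[1]
    u = u0
    b = b0
    f = np.empty(n)
    e = np.empty(n)

    def _eval(u, b):
        obj = 0.0
        f_ = np.exp(u + b * le)
        r = y - f_
        if k > 0:
            qr_ = Q.T @ r
            r = r - Q @ qr_
        for i in range(n):
            obj += r[i] * r[i]
        return obj, f_, r

    obj, f, e = _eval(u, b)
    lam = 1e-3
    for _ in range(max_iter):
        j1 = f.copy()
        j2 = f * le
        if k > 0:
            j1 = j1 - Q @ (Q.T @ j1)
            j2 = j2 - Q @ (Q.T @ j2)
        a11 = a12 = a22 = g1 = g2 = 0.0
        for i in range(n):
            a11 += j1[i] * j1[i]
            a12 += j1[i] * j2[i]
            a22 += j2[i] * j2[i]
            g1 += j1[i] * e[i]
            g2 += j2[i] * e[i]
        stepped = False
        for _retry in range(12):
            m11 = a11 * (1.0 + lam) + 1e-30
            m22 = a22 * (1.0 + lam) + 1e-30
            det = m11 * m22 - a12 * a12
            if abs(det) < 1e-300:
                lam *= 10.0
                continue
            du = (m22 * g1 - a12 * g2) / det
            db = (m11 * g2 - a12 * g1) / det
            # clamp: degenerate targets otherwise drive beta (and hence
            # exp) out of floating-point range
            u_new = min(max(u + du, -200.0), 200.0)
            b_new = min(max(b + db, -50.0), 50.0)
            obj_new, f_new, e_new = _eval(u_new, b_new)
            if obj_new <= obj + 1e-15:
                rel = abs(obj - obj_new) / max(obj, 1e-30)
                u = u_new
                b = b_new
                obj = obj_new
                f = f_new
                e = e_new
                lam = max(lam * 0.3, 1e-12)
                stepped = rel >= tol
                break
            lam *= 10.0
        if not stepped:
            break
    return u, b, obj


def _profiled_power_fit(y, ei, Z, a0, b0, max_iter=200, tol=1e-10,
                        pre_orthonormal=False):
    logE = np.log(ei)
    le0 = logE.mean()
    le = logE - le0
    if Z is not None and Z.size:
        Q = Z if pre_orthonormal else np.linalg.qr(Z)[0]
    else:
        Q = np.zeros((y.shape[0], 0))
    a0 = a0 if np.isfinite(a0) and a0 > 0 else max(float(np.mean(y)), 1e-12)
    b0 = b0 if np.isfinite(b0) else 0.0
    u, b, obj = _gn_profiled(
        np.asarray(y, float), le, np.asarray(Q, float),
        np.log(a0) + b0 * le0, float(b0), max_iter, tol,
    )
    with np.errstate(over="ignore"):
        alpha = float(np.exp(np.clip(u - b * le0, -700, 700)))
    return alpha, float(b), obj


def _fit_target(sys_: _System, target: str, regulators: list) -> QdODEFit:
    j = sys_.index(target)
    y = sys_.Y[j]
    regulators = [r for r in regulators if r in sys_.Z and r != target]
    Z = (
        np.hstack([sys_.Z[r] for r in regulators])
        if regulators
        else np.zeros((y.shape[0], 0))
    )
    if Z.size:
        Qz, Rz = mgs_qr(np.ascontiguousarray(Z))
    else:
        Qz = Rz = None
    alpha, beta, _ = _profiled_power_fit(
        y, sys_.ei, Qz, sys_.alpha0[j], sys_.beta0[j], pre_orthonormal=True
    )
    P_ind = alpha * sys_.ei**beta
    resid0 = y - P_ind
    theta, P_dep = {}, {}
    if Z.size:
        # truncated-SVD solve: smoothed regulator bases can be nearly
        # collinear, and an exact solve would split the fit into huge
        # canceling per-regulator components
        th, *_ = np.linalg.lstsq(Z, resid0, rcond=1e-8)
        p = sys_.cfg.order
        for i, r in enumerate(regulators):
            theta[r] = th[i * p : (i + 1) * p]
            P_dep[r] = sys_.Z[r] @ theta[r]
    fitted = P_ind + (np.sum(list(P_dep.values()), axis=0) if P_dep else 0.0)
    resid = y - fitted
    return QdODEFit(
        target=target,
        group="",
        alpha=alpha,
        beta=beta,
        regulators=regulators,
        theta=theta,
        reg_curves={r: sys_.curves[r] for r in regulators},
        ei=sys_.ei,
        observed=y,
        P_ind=P_ind,
        P_dep=P_dep,
        rss=float(resid @ resid),
        order=sys_.cfg.order,
        design=sys_.cfg.dependent_design,
    )


def _select_for_target(sys_: _System, target: str, candidates=None):
    j = sys_.index(target)
    y = sys_.Y[j]
    if candidates is None:
        candidates = [n for n in sys_.node_ids if n != target]
    cand = [c for c in candidates if c in sys_.Z and c != target]
    if not cand:
        return []
    if sys_.cfg.select == "none":
        return cand[: sys_.cfg.cap]
    # Unpenalized block: the target's own power prediction plus a
    # low-order smooth basis in log EI.  Any smooth-in-E trend is
    # non-identifying in this model class — every candidate's smoothed
    # expression is such a trend, so they are all collinear there — and
    # the shared part-whole warp of the EI adds a further common smooth
    # lack of fit.  Absorbing the smooth directions unpenalized means a
    # candidate group can only earn selection through sample-specific
    # co-fluctuation with the target.
    a0, b0 = sys_.alpha0[j], sys_.beta0[j]
    smooth_E = sys_._smooth_axis_basis
    cols = [smooth_E]
    if sys_.cfg.n_factors > 0:
        cols.append(sys_.factors_for(target))
    if np.isfinite(a0):
        cols.insert(0, (a0 * sys_.ei**b0)[:, None])
    U = np.hstack(cols)
    groups = [sys_.Zsel[c] for c in cand]
    sel_idx, _ = adaptive_group_lasso_select(
        y,
        U,
        groups,
        cap=sys_.cfg.cap,
        n_lambda=sys_.cfg.n_lambda,
        lambda_min_ratio=sys_.cfg.lambda_min_ratio,
        ebic_gamma=sys_.cfg.ebic_gamma,
    )
    return [cand[i] for i in sel_idx]


# ----------------------------------------------------------------------
class QdODERegressor(RegressorMixin, BaseEstimator):
    """scikit-learn estimator for one target's qdODE decomposition.

    ``X`` is an (n, 1 + R) array whose first column is the EI and whose
    remaining columns are candidate-regulator expression values; ``y``
    is the target's expression.  Regulator selection (adaptive group
    LASSO) runs inside ``fit`` unless ``select="none"``.
    """

    def __init__(
        self,
        order: int = 4,
        cap: int = 5,
        select: str = "adaptive",
        n_lambda: int = 12,
        lambda_min_ratio: float = 1e-3,
        smooth_regulators: bool = True,
    ):
        self.order = order
        self.cap = cap
        self.select = select
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.smooth_regulators = smooth_regulators

    def _config(self) -> NetworkModelConfig:
        return NetworkModelConfig(
            order=self.order,
            cap=self.cap,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            smooth_regulators=self.smooth_regulators,
            select=self.select,
        )

    def fit(self, X, y, candidate_ids=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, 1+R) aligned with y")
        ei = X[:, 0]
        R = X.shape[1] - 1
        if candidate_ids is None:
            candidate_ids = [f"reg{i}" for i in range(R)]
        nodes = ["__target__"] + list(candidate_ids)
        Y = np.vstack([y[None, :], X[:, 1:].T])
        sys_ = _System(Y, ei, nodes, self._config())
        sel = _select_for_target(sys_, "__target__")
        fit = _fit_target(sys_, "__target__", sel)
        self.fit_ = fit
        self.alpha_ = fit.alpha
        self.beta_ = fit.beta
        self.regulators_ = fit.regulators
        self.theta_ = fit.theta
        self.rss_ = fit.rss
        self.sigma2_ = fit.sigma2
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        e = X[:, 0] if X.ndim == 2 else X
        fit = self.fit_
        out = fit.alpha * e**fit.beta
        for r in fit.regulators:
            out = out + np.interp(e, fit.ei, fit.P_dep[r])
        return out


# ----------------------------------------------------------------------
def _system_from_dataset(
    ds: ExpressionDataset, cfg: NetworkModelConfig, ei=None
) -> _System:
    """``ei`` overrides the expression index (e.g. the full analyzed
    gene set's EI when fitting a module's genes); defaults to the
    dataset's own column sums."""
    if ei is None:
        e = ds.ei.to_numpy()
    else:
        e = np.asarray(ei.loc[ds.sample_ids] if hasattr(ei, "loc") else ei, float)
    return _System(ds.values.to_numpy(), e, ds.gene_ids, cfg)


def select_regulators(
    target: str,
    ds: ExpressionDataset,
    candidates=None,
    order: int = 4,
    lambdas=None,
    cap: int = 5,
    ei=None,
    **kw,
) -> list:
    """Adaptive group-LASSO regulator set for one target (one group's
    samples)."""
    cfg = NetworkModelConfig(order=order, cap=cap, **kw)
    sys_ = _system_from_dataset(ds, cfg, ei=ei)
    n = ds.n_samples
    if n < 2 * order + 3:
        raise ValueError(f"need at least {2 * order + 3} samples for order {order}")
    return _select_for_target(sys_, target, candidates)


def fit_qdode(
    target: str,
    regulators: list,
    ds: ExpressionDataset,
    order: int = 4,
    group: str = "",
    ei=None,
) -> QdODEFit:
    """Least-squares qdODE fit for one target with a given regulator set."""
    cfg = NetworkModelConfig(order=order)
    sys_ = _system_from_dataset(ds, cfg, ei=ei)
    fit = _fit_target(sys_, target, list(regulators))
    fit.group = group
    return fit


def fit_group_qdode(
    ds: ExpressionDataset,
    cfg: NetworkModelConfig | None = None,
    group: str = "",
    targets=None,
    forced: dict | None = None,
    ei=None,
) -> dict:
    """Select regulators and fit the qdODE decomposition for every node
    of one group's dataset.  Returns {node id: QdODEFit}.

    ``forced`` maps node -> regulators that must be kept in addition to
    the selected set (used to nest grouped models inside a pooled one);
    forced regulators may exceed the cap.
    """
    cfg = cfg or NetworkModelConfig()
    sys_ = _system_from_dataset(ds, cfg, ei=ei)
    out = {}
    for node in targets if targets is not None else sys_.node_ids:
        sel = _select_for_target(sys_, node)
        if forced and node in forced:
            sel = list(dict.fromkeys(list(forced[node]) + sel))
        fit = _fit_target(sys_, node, sel)
        fit.group = group
        out[node] = fit
    return out


# ----------------------------------------------------------------------
def decompose(fit: QdODEFit) -> pd.DataFrame:
    """Observed / independent / per-regulator dependent table over the
    EI grid; the component columns sum to the fitted values."""
    data = {
        "ei": fit.ei,
        "observed": fit.observed,
        "independent": fit.P_ind,
    }
    for r in fit.regulators:
        data[f"dep:{r}"] = fit.P_dep[r]
    data["total_dependent"] = fit.total_dependent
    data["fitted"] = fit.fitted
    return pd.DataFrame(data)


def integrate_forward(fit: QdODEFit, refine: int = 8) -> np.ndarray:
    """Runge-Kutta (RK4) forward solve of the recovered rate functions,
    returned on the fit's EI grid.  Cross-check only: the estimator
    itself works at the integrated (P) level."""
    e0, e1 = float(fit.ei[0]), float(fit.ei[-1])
    n_fine = max(refine * fit.n, 64)
    grid = np.linspace(e0, e1, n_fine)

    def rate(e):
        e = np.atleast_1d(e)
        out = fit.q_independent(e)
        for r in fit.regulators:
            out = out + fit.q_dependent(r, e)
        return out

    h = grid[1] - grid[0]
    y = np.empty(n_fine)
    y[0] = fit.alpha * e0**fit.beta
    if fit.design == "level":
        for r in fit.regulators:
            rc = fit.reg_curves[r]
            y[0] += float(rc.basis(np.array([e0]), fit.order) @ fit.theta[r])
    for i in range(n_fine - 1):
        e = grid[i]
        k1 = rate(e)[0]
        k2 = rate(e + h / 2)[0]
        k3 = rate(e + h / 2)[0]
        k4 = rate(e + h)[0]
        y[i + 1] = y[i] + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return np.interp(fit.ei, grid, y)
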