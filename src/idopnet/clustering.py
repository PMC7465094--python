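"""Power-law mixture functional clustering of genes into modules.

Genes are clustered by the shape of their EI-varying expression: mixture
component ``l`` has a group-specific pair of mean power curves
alpha_{l,k} * E**beta_{l,k} (one per risk group, so genes are grouped by
how they behave across the full range of samples from both groups) and
a component-specific residual variance.  EM alternates responsibilities
with weighted power-curve refits; the number of modules L is chosen by
an information criterion (BIC by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from ._power import powerlaw_fit_pooled
from .allometry import PowerFit, fit_power_matrix
from .io import ExpressionDataset

__all__ = ["ModulePartition", "FunctionalModuleClustering", "em_cluster", "select_L"]

_VAR_FLOOR = 1e-12


@dataclass
class ModulePartition:
    """Hard module assignment plus the fitted mixture it came from."""

    L: int
    labels: dict  # gene id -> module label 1..L
    posteriors: pd.DataFrame  # genes x modules responsibilities
    module_curves: dict  # (module, group) -> PowerFit
    mixing: np.ndarray
    sigma2: np.ndarray
    loglik: float
    aic: float
    bic: float
    selection_table: pd.DataFrame | None = None

    def members(self, module: int) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]


class FunctionalModuleClustering(ClusterMixin, BaseEstimator):
    """EM clustering of expression curves into L modules.

    Parameters
    ----------
    n_modules : mixture size L.
    n_restarts : seeded k-means initializations; best final loglik wins.
    group_specific : if True (default) each module carries one power
        curve per risk group; if False a single pooled curve.
    per_group_variance : per-(module, group) residual variances instead
        of one variance per module.
    tol : absolute loglik-change stopping rule.

    Attributes (after fit)
    ----------------------
    labels_ : (n_genes,) hard assignments in 0..L-1.
    posteriors_ : (n_genes, L) responsibilities.
    curves_ : dict (module index 0-based, group) -> (alpha, beta).
    sigma2_, mixing_, loglik_, aic_, bic_, loglik_trace_.
    """

    def __init__(
        self,
        n_modules: int = 2,
        n_restarts: int = 10,
        max_iter: int = 200,
        tol: float = 1e-6,
        group_specific: bool = True,
        per_group_variance: bool = False,
        random_state: int = 0,
    ):
        self.n_modules = n_modules
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.group_specific = group_specific
        self.per_group_variance = per_group_variance
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y=None, *, ei=None, groups=None):
        Y = np.asarray(X, dtype=float)
        if ei is None:
            raise ValueError("ei (per-sample expression index) is required")
        e = np.asarray(ei, dtype=float)
        m, n = Y.shape
        if e.shape[0] != n:
            raise ValueError("ei length does not match sample count")
        L = int(self.n_modules)
        if L < 1 or L > m:
            raise ValueError("n_modules must be in [1, n_genes]")
        if groups is None or not self.group_specific:
            grp = np.zeros(n, dtype=int)
            group_names = ["pooled"]
        else:
            groups = np.asarray(groups)
            group_names = sorted(set(groups.tolist()))
            if self.group_specific and len(group_names) < 1:
                raise ValueError("no groups")
            grp = np.array([group_names.index(g) for g in groups])
            for gi, gname in enumerate(group_names):
                if not np.any(grp == gi):
                    raise ValueError(f"no samples in group {gname!r}")
        K = len(group_names)
        gmasks = [grp == gi for gi in range(K)]

        feats = self._init_features(Y, e, gmasks)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, int(self.n_restarts)) if L > 1 else 1):
            rs = int(rng.integers(2**31 - 1))
            gamma0 = self._init_resp(feats, L, rs)
            out = self._em(Y, e, gmasks, gamma0)
            if best is None or out["loglik"] > best["loglik"]:
                best = out

        self.group_names_ = group_names
        self.posteriors_ = best["gamma"]
        self.labels_ = best["gamma"].argmax(axis=1)
        self.curves_ = best["curves"]
        self.sigma2_ = best["sigma2"]
        self.mixing_ = best["pi"]
        self.loglik_ = best["loglik"]
        self.loglik_trace_ = best["trace"]
        p = L * (2 * K + (K if self.per_group_variance else 1)) + (L - 1)
        self.n_parameters_ = p
        self.aic_ = -2.0 * self.loglik_ + 2.0 * p
        self.bic_ = -2.0 * self.loglik_ + p * np.log(m)
        return self

    def fit_predict(self, X, y=None, **kw):
        return self.fit(X, **kw).labels_

    # ------------------------------------------------------------------
    def _init_features(self, Y, e, gmasks):
        cols = []
        for mask in gmasks:
            a, b, _ = fit_power_matrix(Y[:, mask], e[mask])
            with np.errstate(divide="ignore", invalid="ignore"):
                la = np.log(np.where(a > 0, a, np.nan))
            cols += [la, b]
        F = np.column_stack(cols)
        col_mean = np.nanmean(np.where(np.isfinite(F), F, np.nan), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        F = np.where(np.isfinite(F), F, col_mean)
        sd = F.std(axis=0)
        return (F - F.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    def _init_resp(self, feats, L, random_state):
        m = feats.shape[0]
        if L == 1:
            return np.ones((m, 1))
        km = KMeans(n_clusters=L, n_init=1, random_state=random_state).fit(feats)
        gamma = np.full((m, L), 1e-6)
        gamma[np.arange(m), km.labels_] = 1.0
        return gamma / gamma.sum(axis=1, keepdims=True)

    def _em(self, Y, e, gmasks, gamma):
        m, n = Y.shape
        L = gamma.shape[1]
        K = len(gmasks)
        trace = []
        loglik = -np.inf
        curves = {}
        sigma2 = np.ones(L)
        for _ in range(self.max_iter):
            # ---- M-step
            pi = gamma.mean(axis=0)
            mu = np.empty((L, n))
            for l in range(L):
                w = gamma[:, l]
                if w.sum() <= 1e-10:
                    w = np.full(m, 1e-10)
                for gi, mask in enumerate(gmasks):
                    a, b, _ = powerlaw_fit_pooled(Y[:, mask], e[mask], w[:, None])
                    # the inner solver restarts from log-OLS; keep the previous
                    # curve if it is better, so the EM objective stays monotone
                    prev = curves.get((l, gi))
                    if prev is not None:
                        mu_new = a * e[mask] ** b
                        mu_old = prev[0] * e[mask] ** prev[1]
                        d_new = Y[:, mask] - mu_new
                        d_old = Y[:, mask] - mu_old
                        if w @ (d_old * d_old).sum(axis=1) < w @ (d_new * d_new).sum(axis=1):
                            a, b = prev
                    curves[(l, gi)] = (a, b)
                    mu[l, mask] = a * e[mask] ** b
            SSE = np.empty((m, L))
            for l in range(L):
                d = Y - mu[l]
                SSE[:, l] = (d * d).sum(axis=1)
            if self.per_group_variance:
                # sigma2 stored per (l, k); likelihood assembled per group
                sig = np.empty((L, K))
                for l in range(L):
                    for gi, mask in enumerate(gmasks):
                        d = Y[:, mask] - mu[l][mask]
                        gs = max(float(gamma[:, l].sum()), 1e-300)
                        sig[l, gi] = max(
                            float((gamma[:, l] @ (d * d).sum(axis=1)) / (gs * mask.sum())),
                            _VAR_FLOOR,
                        )
                sigma2 = sig
                ll_mat = np.zeros((m, L))
                for l in range(L):
                    for gi, mask in enumerate(gmasks):
                        d = Y[:, mask] - mu[l][mask]
                        nk = int(mask.sum())
                        ll_mat[:, l] += (
                            -0.5 * nk * np.log(2 * np.pi * sig[l, gi])
                            - (d * d).sum(axis=1) / (2 * sig[l, gi])
                        )
            else:
                gsum = np.maximum(gamma.sum(axis=0), 1e-300)  # empty-component guard
                s2 = (gamma * SSE).sum(axis=0) / (gsum * n)
                sigma2 = np.maximum(s2, _VAR_FLOOR)
                ll_mat = -0.5 * n * np.log(2 * np.pi * sigma2)[None, :] - SSE / (
                    2 * sigma2[None, :]
                )
            # ---- E-step
            with np.errstate(divide="ignore"):
                logpi = np.log(np.maximum(pi, 1e-300))
            joint = logpi[None, :] + ll_mat
            norm = logsumexp(joint, axis=1)
            gamma = np.exp(joint - norm[:, None])
            new_loglik = float(norm.sum())
            trace.append(new_loglik)
            if np.isfinite(loglik) and abs(new_loglik - loglik) < self.tol:
                loglik = new_loglik
                break
            loglik = new_loglik
        return {
            "gamma": gamma,
            "pi": pi,
            "curves": dict(curves),
            "sigma2": sigma2,
            "loglik": loglik,
            "trace": np.array(trace),
        }


# ----------------------------------------------------------------------
def _partition_from_estimator(
    est: FunctionalModuleClustering, ds: ExpressionDataset
) -> ModulePartition:
    check_is_fitted(est, "labels_")
    genes = ds.gene_ids
    labels = {g: int(l) + 1 for g, l in zip(genes, est.labels_)}
    L = est.n_modules
    post = pd.DataFrame(
        est.posteriors_, index=genes, columns=[m + 1 for m in range(L)]
    )
    curves = {}
    n_by_group = {}
    for gi, gname in enumerate(est.group_names_):
        if est.group_names_ == ["pooled"]:
            n_by_group[gname] = ds.n_samples
        else:
            n_by_group[gname] = int((ds.risk == gname).sum())
    for (l, gi), (a, b) in est.curves_.items():
        gname = est.group_names_[gi]
        curves[(l + 1, gname)] = PowerFit(
            alpha=float(a), beta=float(b), rss=np.nan, n_used=n_by_group[gname]
        )
    return ModulePartition(
        L=L,
        labels=labels,
        posteriors=post,
        module_curves=curves,
        mixing=est.mixing_,
        sigma2=np.atleast_1d(est.sigma2_),
        loglik=est.loglik_,
        aic=est.aic_,
        bic=est.bic_,
    )


def em_cluster(
    ds: ExpressionDataset, L: int, seed: int = 0, n_restarts: int = 10, **kw
) -> ModulePartition:
    """Cluster a dataset's genes into L modules (EM, seeded restarts)."""
    ds = ds.order_by_ei()
    groups = ds.risk.to_numpy() if ds.risk is not None else None
    est = FunctionalModuleClustering(
        n_modules=L, n_restarts=n_restarts, random_state=seed, **kw
    ).fit(ds.values.to_numpy(), ei=ds.ei.to_numpy(), groups=groups)
    return _partition_from_estimator(est, ds)


def select_L(
    ds: ExpressionDataset,
    L_range,
    criterion: str = "bic",
    seed: int = 0,
    n_restarts: int = 10,
    **kw,
) -> ModulePartition:
    """Fit every L in ``L_range`` and keep the information-criterion
    minimizer; the full criterion curve is attached as
    ``selection_table``."""
    L_list = list(L_range)
    if not L_list:
        raise ValueError("empty L range")
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    rows, parts = [], {}
    for L in L_list:
        part = em_cluster(ds, L, seed=seed, n_restarts=n_restarts, **kw)
        parts[L] = part
        rows.append(
            {"L": L, "loglik": part.loglik, "aic": part.aic, "bic": part.bic}
        )
    table = pd.DataFrame(rows)
    best_L = int(table.loc[table[criterion].idxmin(), "L"])
    best = parts[best_L]
    best.selection_table = table
    return best
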