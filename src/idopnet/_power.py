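"""Vectorized power-law least squares.

Fits y = alpha * E**beta per row of a matrix by damped Gauss-Newton
(Levenberg) on the original scale, initialized from weighted OLS on
log y vs log E over strictly positive entries.  One solver serves
single-gene fits, batched per-gene fits and the responsibility-weighted
single-curve fits of the mixture M-step, which is why it is hand-rolled
rather than looped through scipy.optimize: the EM and permutation layers
refit thousands of curves.

Internally E is rescaled by its geometric mean so that E**beta stays
well-conditioned for expression-index magnitudes of 1e4 and larger.
"""

from __future__ import annotations

import numpy as np

__all__ = ["powerlaw_fit_rows", "powerlaw_fit_pooled"]

_LOG_FLOOR = 1e-300


def _log_ols_init(Y, logE, W):
    """Weighted OLS of log y on log E over positive-y entries, per row.

    Returns (u0, b0) where the working model is y = exp(u0) * e**b0 on
    the rescaled index e.  Rows without >= 2 positive entries get a flat
    fallback (u0 = log weighted-mean, b0 = 0).
    """
    pos = (Y > 0) & (W > 0)
    Wp = W * pos
    logY = np.log(np.where(pos, Y, 1.0))
    sw = Wp.sum(axis=1)
    ok = pos.sum(axis=1) >= 2
    sw_safe = np.where(sw > 0, sw, 1.0)
    mx = (Wp * logE).sum(axis=1) / sw_safe
    my = (Wp * logY).sum(axis=1) / sw_safe
    dx = logE - mx[:, None]
    sxx = (Wp * dx * dx).sum(axis=1)
    sxy = (Wp * dx * (logY - my[:, None])).sum(axis=1)
    b0 = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    u0 = my - b0 * mx
    # fallback for degenerate rows: flat curve at the weighted mean
    wmean = (W * Y).sum(axis=1) / np.where(W.sum(axis=1) > 0, W.sum(axis=1), 1.0)
    u_flat = np.log(np.maximum(wmean, _LOG_FLOOR))
    u0 = np.where(ok, u0, u_flat)
    b0 = np.where(ok, b0, 0.0)
    return u0, b0


def _objective(u, b, Y, logE, W):
    f = np.exp(u[:, None] + b[:, None] * logE)
    r = Y - f
    return (W * r * r).sum(axis=1), f, r


def powerlaw_fit_rows(
    Y,
    ei,
    weights=None,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
):
    """Fit y = alpha * E**beta independently for each row of ``Y``.

    Parameters
    ----------
    Y : (G, N) array of non-negative observations.
    ei : (N,) or (G, N) positive expression-index values.
    weights : optional (G, N) non-negative weights.
    tol : relative objective-change convergence tolerance.

    Returns
    -------
    alpha, beta, rss : (G,) arrays.  Rows whose weighted data are all
    zero get alpha=0, beta=0, rss=0 (flat zero curve, flagged upstream).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, N = Y.shape
    E = np.asarray(ei, dtype=float)
    if E.ndim == 1:
        E = np.broadcast_to(E, (G, N))
    if np.any(E <= 0) or not np.all(np.isfinite(E)):
        raise ValueError("expression index values must be positive and finite")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite expression values")
    W = np.ones_like(Y) if weights is None else np.asarray(weights, dtype=float)
    W = np.broadcast_to(W, Y.shape).copy()

    # rescale E by per-row geometric mean: y = exp(u) * e**b, e = E/E0
    logE_raw = np.log(E)
    logE0 = logE_raw.mean(axis=1, keepdims=True)
    logE = logE_raw - logE0

    u, b = _log_ols_init(Y, logE, W)
    obj, f, r = _objective(u, b, Y, logE, W)
    lam = np.full(G, 1e-3)
    active = np.ones(G, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        wf = W * f
        S_uu = (wf * f).sum(axis=1)
        S_ub = (wf * f * logE).sum(axis=1)
        S_bb = (wf * f * logE * logE).sum(axis=1)
        g_u = (wf * r).sum(axis=1)
        g_b = (wf * r * logE).sum(axis=1)
        improved = np.zeros(G, dtype=bool)
        for _retry in range(12):
            todo = active & ~improved
            if not todo.any():
                break
            d_uu = S_uu * (1.0 + lam) + 1e-30
            d_bb = S_bb * (1.0 + lam) + 1e-30
            det = d_uu * d_bb - S_ub * S_ub
            det = np.where(np.abs(det) > 1e-300, det, 1e-300)
            du = (d_bb * g_u - S_ub * g_b) / det
            db = (d_uu * g_b - S_ub * g_u) / det
            u_new = np.where(todo, u + du, u)
            b_new = np.where(todo, b + db, b)
            obj_new, f_new, r_new = _objective(u_new, b_new, Y, logE, W)
            better = todo & (obj_new <= obj + 1e-15)
            u = np.where(better, u_new, u)
            b = np.where(better, b_new, b)
            f = np.where(better[:, None], f_new, f)
            r = np.where(better[:, None], r_new, r)
            rel = np.abs(obj - obj_new) / np.maximum(obj, 1e-30)
            converged = better & (rel < tol)
            obj = np.where(better, obj_new, obj)
            lam = np.where(better, lam * 0.3, np.where(todo, lam * 10.0, lam))
            improved |= better
            active &= ~converged
        active &= improved  # rows where no damped step helps are done

    alpha = np.exp(u - b * logE0[:, 0])
    # rows with no usable signal: all weighted data zero
    dead = (W * Y).sum(axis=1) <= 0
    alpha = np.where(dead, 0.0, alpha)
    beta = np.where(dead, 0.0, b)
    rss = np.where(dead, 0.0, obj)
    return alpha, beta, rss


def powerlaw_fit_pooled(Y, ei, weights=None, **kw):
    """Fit a single power curve to all entries of ``Y`` jointly.

    Used by the mixture M-step: ``weights`` carries per-gene
    responsibilities broadcast over samples.  Returns (alpha, beta, rss)
    scalars.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, N = Y.shape
    E = np.asarray(ei, dtype=float)
    if E.ndim == 1:
        E = np.broadcast_to(E, (G, N))
    W = np.ones_like(Y) if weights is None else np.broadcast_to(
        np.asarray(weights, dtype=float), Y.shape
    )
    a, b, rss = powerlaw_fit_rows(
        Y.reshape(1, -1), E.reshape(1, -1), W.reshape(1, -1), **kw
    )
    return float(a[0]), float(b[0]), float(rss[0])
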