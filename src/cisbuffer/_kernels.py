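"""Numba-compiled per-gene kernels for the NB GLM.

Each gene is an independent small problem (n units, p coefficients, one
dispersion), so the kernels loop genes serially with explicit inner
loops; this is orders of magnitude faster than batched numpy at the
problem sizes the calibration and bootstrap stages need (thousands of
whole-cohort refits).

Parameterisation: ``K ~ NB(mu, alpha)`` with ``Var = mu + alpha*mu^2``,
``log mu = X beta + offset``.
"""

from __future__ import annotations

from math import exp, lgamma, log

import numpy as np
from numba import njit

_RIDGE = 1e-10
_ETA_CLIP = 40.0
_GOLDEN = 0.6180339887498949


#: below this dispersion the Poisson limit is used: for r = 1/alpha
#: beyond ~1e9 the lgamma(k + r) - lgamma(r) differences drown in
#: floating-point roundoff while the NB is numerically Poisson anyway
_POISSON_ALPHA = 1e-9


@njit(cache=True)
def _nb_ll_const(k, alpha):
    """Terms of the NB log-likelihood that do not depend on mu."""
    if alpha < _POISSON_ALPHA:
        c = 0.0
        for t in range(k.shape[0]):
            c -= lgamma(k[t] + 1.0)
        return c
    r = 1.0 / alpha
    c = k.shape[0] * (r * log(r) - lgamma(r))
    for t in range(k.shape[0]):
        c += lgamma(k[t] + r) - lgamma(k[t] + 1.0)
    return c


@njit(cache=True)
def _nb_ll_mu(k, mu, alpha, const):
    """NB log-likelihood given the precomputed mu-free constant."""
    ll = const
    if alpha < _POISSON_ALPHA:
        for t in range(k.shape[0]):
            ll += k[t] * log(mu[t]) - mu[t]
        return ll
    r = 1.0 / alpha
    for t in range(k.shape[0]):
        ll += k[t] * log(mu[t]) - (k[t] + r) * log(r + mu[t])
    return ll


@njit(cache=True)
def _nb_ll(k, mu, alpha):
    return _nb_ll_mu(k, mu, alpha, _nb_ll_const(k, alpha))


@njit(cache=True)
def _update_mu(X, beta, off, mu):
    n, p = X.shape
    for t in range(n):
        e = off[t]
        for j in range(p):
            e += X[t, j] * beta[j]
        if e > _ETA_CLIP:
            e = _ETA_CLIP
        elif e < -_ETA_CLIP:
            e = -_ETA_CLIP
        mu[t] = exp(e)


@njit(cache=True)
def _irls(k, X, off, alpha, beta, max_iter, tol):
    """Fisher scoring with step-halving at fixed dispersion.

    ``beta`` is updated in place; returns ``(loglik, converged)``.
    """
    n, p = X.shape
    mu = np.empty(n)
    _update_mu(X, beta, off, mu)
    const = _nb_ll_const(k, alpha)  # lgamma terms fixed within this alpha
    ll = _nb_ll_mu(k, mu, alpha, const)
    xtwx = np.empty((p, p))
    xtwz = np.empty(p)
    cand = np.empty(p)
    converged = False
    for _ in range(max_iter):
        for i in range(p):
            xtwz[i] = 0.0
            for j in range(p):
                xtwx[i, j] = 0.0
        for t in range(n):
            w = mu[t] / (1.0 + alpha * mu[t])
            # working response less offset: x.beta + (k-mu)/mu
            z = log(mu[t]) - off[t] + (k[t] - mu[t]) / mu[t]
            for i in range(p):
                xw = X[t, i] * w
                xtwz[i] += xw * z
                for j in range(i, p):
                    xtwx[i, j] += xw * X[t, j]
        for i in range(p):
            xtwx[i, i] += _RIDGE
            for j in range(i + 1, p):
                xtwx[j, i] = xtwx[i, j]
        sol = np.linalg.solve(xtwx, xtwz)
        scale = 1.0
        ll_new = ll
        accepted = False
        for _half in range(7):
            for i in range(p):
                cand[i] = beta[i] + scale * (sol[i] - beta[i])
            _update_mu(X, cand, off, mu)
            ll_new = _nb_ll_mu(k, mu, alpha, const)
            if ll_new >= ll - 1e-12:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            _update_mu(X, beta, off, mu)
            converged = True  # cannot improve further
            break
        delta = 0.0
        for i in range(p):
            d = abs(scale * (sol[i] - beta[i]))
            if d > delta:
                delta = d
            beta[i] = cand[i]
        ll = ll_new
        if delta < tol:
            converged = True
            break
    return ll, converged


@njit(cache=True)
def _logdet_info(X, mu, alpha):
    n, p = X.shape
    a = np.zeros((p, p))
    for t in range(n):
        w = mu[t] / (1.0 + alpha * mu[t])
        for i in range(p):
            for j in range(i, p):
                a[i, j] += X[t, i] * w * X[t, j]
    for i in range(p):
        a[i, i] += _RIDGE
        for j in range(i + 1, p):
            a[j, i] = a[i, j]
    chol = np.linalg.cholesky(a)
    s = 0.0
    for i in range(p):
        s += log(chol[i, i])
    return 2.0 * s


@njit(cache=True)
def _profile_obj(k, X, off, logalpha, beta, adjust_cr, use_pen, log_trend,
                 prior_var, max_iter, tol):
    alpha = exp(logalpha)
    ll, _ = _irls(k, X, off, alpha, beta, max_iter, tol)
    obj = ll
    if adjust_cr:
        mu = np.empty(X.shape[0])
        _update_mu(X, beta, off, mu)
        obj -= 0.5 * _logdet_info(X, mu, alpha)
    if use_pen:
        obj -= (logalpha - log_trend) ** 2 / (2.0 * prior_var)
    return obj


@njit(cache=True)
def _dispersion_one(k, X, off, beta, lo, hi, n_coarse, golden_iters,
                    adjust_cr, use_pen, log_trend, prior_var):
    """Maximise the profile objective over log-dispersion in [lo, hi]."""
    step = (hi - lo) / (n_coarse - 1)
    best_i = 0
    best_f = -1e300
    for i in range(n_coarse):
        x = lo + step * i
        fx = _profile_obj(k, X, off, x, beta, adjust_cr, use_pen, log_trend,
                          prior_var, 25, 1e-8)
        if fx > best_f:
            best_f = fx
            best_i = i
    a = lo + step * (best_i - 1 if best_i > 0 else 0)
    b = lo + step * (best_i + 1 if best_i < n_coarse - 1 else n_coarse - 1)
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = _profile_obj(k, X, off, c, beta, adjust_cr, use_pen, log_trend,
                      prior_var, 25, 1e-8)
    fd = _profile_obj(k, X, off, d, beta, adjust_cr, use_pen, log_trend,
                      prior_var, 25, 1e-8)
    for _ in range(golden_iters):
        if fc > fd:
            b = d
            d = c
            fd = fc
            c = b - _GOLDEN * (b - a)
            fc = _profile_obj(k, X, off, c, beta, adjust_cr, use_pen,
                              log_trend, prior_var, 25, 1e-8)
        else:
            a = c
            c = d
            fc = fd
            d = a + _GOLDEN * (b - a)
            fd = _profile_obj(k, X, off, d, beta, adjust_cr, use_pen,
                              log_trend, prior_var, 25, 1e-8)
    return c if fc > fd else d


@njit(cache=True)
def _ols_start(k, X, off, xtx_chol_inv, beta):
    """Log-linear least-squares start: beta = (X'X)^-1 X' (log(k+0.5)-off)."""
    n, p = X.shape
    xty = np.zeros(p)
    for t in range(n):
        y = log(k[t] + 0.5) - off[t]
        for i in range(p):
            xty[i] += X[t, i] * y
    for i in range(p):
        s = 0.0
        for j in range(p):
            s += xtx_chol_inv[i, j] * xty[j]
        beta[i] = s


@njit(cache=True)
def fit_cohort(K, X, off, alpha_in, estimate_disp, adjust_cr, use_pen,
               log_trend, prior_var, log_lo, log_hi, log_floor, log_ceil,
               n_coarse, golden_iters, se_observed):
    """Fit every gene: dispersion search (optional), final IRLS, Wald SEs.

    Returns ``(beta, alpha, se, loglik, converged, se_fallback)``.
    """
    G, n = K.shape
    p = X.shape[1]
    beta = np.empty((G, p))
    alpha = np.empty(G)
    se = np.empty((G, p))
    ll = np.empty(G)
    conv = np.empty(G, np.bool_)
    fallback = np.zeros(G, np.bool_)

    xtx = np.zeros((p, p))
    for t in range(n):
        for i in range(p):
            for j in range(p):
                xtx[i, j] += X[t, i] * X[t, j]
    for i in range(p):
        xtx[i, i] += _RIDGE
    xtx_inv = np.linalg.inv(xtx)

    mu = np.empty(n)
    info = np.empty((p, p))
    info_exp = np.empty((p, p))
    for g in range(G):
        k = K[g]
        o = off[g]
        b = beta[g]
        _ols_start(k, X, o, xtx_inv, b)
        if estimate_disp:
            la = _dispersion_one(k, X, o, b, log_lo[g], log_hi[g], n_coarse,
                                 golden_iters, adjust_cr, use_pen,
                                 log_trend[g], prior_var)
            if la < log_floor:
                la = log_floor
            elif la > log_ceil:
                la = log_ceil
            alpha[g] = exp(la)
        else:
            alpha[g] = alpha_in[g]
        ll[g], conv[g] = _irls(k, X, o, alpha[g], b, 150, 1e-12)
        _update_mu(X, b, o, mu)

        for i in range(p):
            for j in range(p):
                info[i, j] = 0.0
                info_exp[i, j] = 0.0
        a = alpha[g]
        for t in range(n):
            denom = 1.0 + a * mu[t]
            w_exp = mu[t] / denom
            u = w_exp + a * mu[t] * (k[t] - mu[t]) / (denom * denom)
            for i in range(p):
                for j in range(i, p):
                    xij = X[t, i] * X[t, j]
                    info_exp[i, j] += xij * w_exp
                    info[i, j] += xij * u
        for i in range(p):
            info[i, i] += _RIDGE
            info_exp[i, i] += _RIDGE
            for j in range(i + 1, p):
                info[j, i] = info[i, j]
                info_exp[j, i] = info_exp[i, j]
        if not se_observed:
            for i in range(p):
                for j in range(p):
                    info[i, j] = info_exp[i, j]
        cov = np.linalg.inv(info)
        ok = True
        for i in range(p):
            if not np.isfinite(cov[i, i]) or cov[i, i] <= 0.0:
                ok = False
        if not ok and se_observed:
            fallback[g] = True
            cov = np.linalg.inv(info_exp)
        for i in range(p):
            v = cov[i, i]
            se[g, i] = np.sqrt(v) if v > 0.0 else np.nan
    return beta, alpha, se, ll, conv, fallback
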