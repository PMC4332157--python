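"""Negative-binomial GLM with log link and per-unit offsets.

Every gene in an allele-specific count matrix shares one design matrix
(the sample/allele units) but has its own counts, offsets and
dispersion.  The public functions take count stacks ``K`` of shape
``(G, n)``, one design ``X`` of shape ``(n, p)`` and offsets ``(G, n)``,
and dispatch to compiled per-gene kernels (:mod:`cisbuffer._kernels`).

Coefficients are maximum likelihood via Fisher-scoring IRLS at fixed
dispersion; the dispersion maximises the (optionally Cox-Reid adjusted,
optionally log-normal-penalised) profile log-likelihood by a bracketed
golden-section search on the log scale.

The NB parameterisation is mean/dispersion: ``Var = mu + alpha * mu**2``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from . import _kernels

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 50.0


def nb_loglik(k, mu, alpha):
    """NB log-likelihood summed over the trailing axis (numpy, broadcast).

    ``alpha`` may be scalar or per-row (one dispersion per gene).
    """
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == k.ndim - 1:
        alpha = alpha[..., None]
    r = 1.0 / alpha
    ll = (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * np.log(r / (r + mu))
        + k * np.log(mu / (r + mu))
    )
    return ll.sum(axis=-1)


def _as_stack(K, X, offset, alpha):
    K = np.ascontiguousarray(K, dtype=np.float64)
    X = np.ascontiguousarray(X, dtype=np.float64)
    G = K.shape[0]
    if offset is None:
        offset = np.zeros_like(K)
    offset = np.ascontiguousarray(
        np.broadcast_to(np.asarray(offset, dtype=np.float64), K.shape))
    alpha = np.ascontiguousarray(
        np.broadcast_to(np.asarray(alpha, dtype=np.float64).reshape(-1), (G,)))
    return K, X, offset, alpha


def fit_beta(K, X, offset, alpha, beta0=None, max_iter=150, tol=1e-12):
    """ML coefficients at fixed per-gene dispersion.

    Returns ``(beta, mu, loglik, converged)``.
    """
    K, X, offset, alpha = _as_stack(K, X, offset, alpha)
    G, n = K.shape
    p = X.shape[1]
    if beta0 is None:
        pinv = np.linalg.pinv(X)
        beta = np.ascontiguousarray((np.log(K + 0.5) - offset) @ pinv.T)
    else:
        beta = np.array(beta0, dtype=np.float64, copy=True)
    ll = np.empty(G)
    converged = np.empty(G, dtype=bool)
    for g in range(G):
        ll[g], converged[g] = _kernels._irls(
            K[g], X, offset[g], alpha[g], beta[g], max_iter, tol)
    eta = np.clip(beta @ X.T + offset, -40.0, 40.0)
    return beta, np.exp(eta), ll, converged


def profile_loglik(K, X, offset, alpha, beta0=None, adjust="cox-reid",
                   penalty=None):
    """Profile log-likelihood of the dispersion (beta maximised out).

    ``adjust='cox-reid'`` subtracts ``0.5*logdet(X'WX)``, the standard
    small-sample correction for having estimated p coefficients.
    ``penalty=(log_alpha_trend, prior_var)`` adds a log-normal prior
    term (trended MAP shrinkage).  Returns ``(objective, beta)``.
    """
    K, X, offset, alpha = _as_stack(K, X, offset, alpha)
    G = K.shape[0]
    adjust_cr = _check_adjust(adjust)
    use_pen, log_trend, prior_var = _check_penalty(penalty, G)
    if beta0 is None:
        pinv = np.linalg.pinv(X)
        beta = np.ascontiguousarray((np.log(K + 0.5) - offset) @ pinv.T)
    else:
        beta = np.array(beta0, dtype=np.float64, copy=True)
    obj = np.empty(G)
    for g in range(G):
        obj[g] = _kernels._profile_obj(
            K[g], X, offset[g], np.log(alpha[g]), beta[g], adjust_cr,
            use_pen, log_trend[g], prior_var, 150, 1e-10)
    return obj, beta


def _check_adjust(adjust):
    if adjust == "cox-reid":
        return True
    if adjust in (None, "none"):
        return False
    raise ValueError(f"unknown adjustment {adjust!r}")


def _check_penalty(penalty, G):
    if penalty is None:
        return False, np.zeros(G), 1.0
    log_trend, prior_var = penalty
    log_trend = np.ascontiguousarray(
        np.broadcast_to(np.asarray(log_trend, dtype=np.float64).reshape(-1), (G,)))
    if prior_var <= 0:
        raise ValueError("prior variance must be positive")
    return True, log_trend, float(prior_var)


def estimate_dispersions(K, X, offset, adjust="cox-reid", penalty=None,
                         floor=DISPERSION_FLOOR, ceil=DISPERSION_CEIL,
                         n_coarse=12, golden_iters=18, bracket=None):
    """Per-gene dispersion maximising the profile objective.

    A coarse log-spaced grid brackets the optimum for every gene and a
    golden-section search refines it.  ``bracket=(log_lo, log_hi)``
    (per-gene arrays on the log scale) restricts the search, e.g. around
    a known neighbourhood for MAP refinement.  Genes with no evidence
    of overdispersion end up at ``floor`` (the Poisson limit).
    """
    K, X, offset, _ = _as_stack(K, X, offset, 1.0)
    G = K.shape[0]
    adjust_cr = _check_adjust(adjust)
    use_pen, log_trend, prior_var = _check_penalty(penalty, G)
    if bracket is None:
        log_lo = np.full(G, np.log(floor))
        log_hi = np.full(G, np.log(ceil))
    else:
        log_lo = np.clip(np.ascontiguousarray(bracket[0], dtype=np.float64),
                         np.log(floor), np.log(ceil))
        log_hi = np.clip(np.ascontiguousarray(bracket[1], dtype=np.float64),
                         np.log(floor), np.log(ceil))
    _, alpha, _, _, _, _ = _kernels.fit_cohort(
        K, X, offset, np.ones(G), True, adjust_cr, use_pen, log_trend,
        prior_var, log_lo, log_hi, np.log(floor), np.log(ceil),
        n_coarse, golden_iters, True)
    return alpha


def wald_fit(K, X, offset, alpha, se_mode="observed"):
    """Final fit plus Wald standard errors at fixed per-gene dispersion.

    ``se_mode='observed'`` uses the observed information, falling back
    to the expected (Fisher) information for genes where the observed
    matrix is not positive definite.  Returns a dict with ``beta, se,
    mu, loglik, converged, se_fallback, alpha``.
    """
    if se_mode not in ("observed", "expected"):
        raise ValueError(f"unknown se_mode {se_mode!r}")
    K, X, offset, alpha = _as_stack(K, X, offset, alpha)
    G = K.shape[0]
    lo = np.full(G, np.log(DISPERSION_FLOOR))
    hi = np.full(G, np.log(DISPERSION_CEIL))
    beta, alpha_out, se, ll, conv, fallback = _kernels.fit_cohort(
        K, X, offset, alpha, False, False, False, np.zeros(G), 1.0,
        lo, hi, np.log(DISPERSION_FLOOR), np.log(DISPERSION_CEIL), 2, 0,
        se_mode == "observed")
    eta = np.clip(beta @ X.T + offset, -40.0, 40.0)
    return {
        "beta": beta,
        "se": se,
        "mu": np.exp(eta),
        "loglik": ll,
        "converged": conv,
        "se_fallback": fallback,
        "alpha": alpha_out,
    }


def fit_cohort(K, X, offset, dispersion=None, adjust="cox-reid", penalty=None,
               floor=DISPERSION_FLOOR, ceil=DISPERSION_CEIL, n_coarse=12,
               golden_iters=18, se_mode="observed"):
    """One-pass cohort fit: dispersion search (unless given) + Wald fit.

    ``dispersion=None`` estimates per-gene dispersions; an array fixes
    them.  Returns the same dict as :func:`wald_fit`.
    """
    if se_mode not in ("observed", "expected"):
        raise ValueError(f"unknown se_mode {se_mode!r}")
    K, X, offset, _ = _as_stack(K, X, offset, 1.0)
    G = K.shape[0]
    adjust_cr = _check_adjust(adjust)
    use_pen, log_trend, prior_var = _check_penalty(penalty, G)
    estimate = dispersion is None
    alpha_in = (np.ones(G) if estimate else
                np.ascontiguousarray(np.broadcast_to(
                    np.asarray(dispersion, dtype=np.float64).reshape(-1), (G,))))
    lo = np.full(G, np.log(floor))
    hi = np.full(G, np.log(ceil))
    beta, alpha, se, ll, conv, fallback = _kernels.fit_cohort(
        K, X, offset, alpha_in, estimate, adjust_cr, use_pen, log_trend,
        prior_var, lo, hi, np.log(floor), np.log(ceil), n_coarse,
        golden_iters, se_mode == "observed")
    eta = np.clip(beta @ X.T + offset, -40.0, 40.0)
    return {
        "beta": beta,
        "se": se,
        "mu": np.exp(eta),
        "loglik": ll,
        "converged": conv,
        "se_fallback": fallback,
        "alpha": alpha,
    }
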