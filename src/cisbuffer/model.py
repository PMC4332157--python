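"""Per-gene NB GLM fitting, Wald testing and gene calling.

The central estimator, :class:`AlleleSpecificGLM`, fits one negative
binomial GLM per gene over the (sample, allele) units with known log
offsets (size factor x allele frequency x allele length) and the layout's
design matrix.  Dispersion is estimated per gene by Cox-Reid-adjusted
profile maximum likelihood and, by default, shrunk toward a parametric
mean-dispersion trend with a log-normal prior (MAP), the standard
remedy for the very small residual degrees of freedom (two, for the
canonical eight-unit design).  Coefficients are unshrunken maximum
likelihood: the buffering estimator downstream needs raw ratios.

Wald tests use the observed information; BH multiple-testing correction
is applied separately per coefficient family, and genes are called at a
fold-change plus FDR threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from . import glm
from .design import EFFECT_COLUMNS, SPORE_HYBRID, build_design, canonical_sample_sheet

#: aliases accepted wherever a coefficient is named
_ALIASES = {"cis": "cis", "local_trans": "trans", "trans": "trans",
            "rna_cis": "cis", "te_cis": "trans"}


def resolve_coefficient(name: str, dataset_kind: str) -> str:
    """Map 'cis'/'local_trans' (or a literal column name) to the design
    column carrying that effect in the given layout."""
    if name in _ALIASES:
        return EFFECT_COLUMNS[dataset_kind][_ALIASES[name]]
    raise ValueError(f"unknown coefficient {name!r}")


def fit_dispersion_trend(alpha_genewise, mean_counts, floor=glm.DISPERSION_FLOOR):
    """Parametric mean-dispersion trend ``alpha(mu) = a0 + a1/mu``.

    Fitted by an iterated Gamma GLM with identity link on the gene-wise
    estimates (excluding genes at the floor and, between iterations,
    extreme outliers), as is standard for NB count models.  Returns
    ``(trend_values, (a0, a1))``.
    """
    import statsmodels.api as sm

    alpha_genewise = np.asarray(alpha_genewise, dtype=float)
    mean_counts = np.asarray(mean_counts, dtype=float)
    use = (alpha_genewise > 10 * floor) & (mean_counts > 0)
    if use.sum() < 10:
        med = (np.median(alpha_genewise[use]) if use.any()
               else max(np.median(alpha_genewise), floor))
        coef = (float(max(med, floor)), 0.0)
        return np.full_like(alpha_genewise, coef[0]), coef
    x = sm.add_constant(1.0 / mean_counts[use])
    y = alpha_genewise[use]
    coef = np.array([np.median(y), 1.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(10):
            try:
                res = sm.GLM(y, x, family=sm.families.Gamma(
                    sm.families.links.Identity())).fit(
                        start_params=coef, maxiter=100)
                new = np.asarray(res.params)
            except Exception:
                break
            if not np.all(np.isfinite(new)) or new[0] <= 0:
                break
            ratio = y / np.maximum(x @ new, floor)
            ok = (ratio > 1e-4) & (ratio < 15)
            done = ok.all() or np.allclose(new, coef, rtol=1e-6)
            coef = new
            if done:
                break
            x, y = x[ok], y[ok]
    a0 = float(max(coef[0], floor))
    a1 = float(max(coef[1], 0.0))
    trend = np.maximum(a0 + a1 / np.maximum(mean_counts, 1e-8), floor)
    return trend, (a0, a1)


class AlleleSpecificGLM(BaseEstimator):
    """Per-gene negative-binomial GLM for allele-specific counts.

    Parameters
    ----------
    dataset_kind : 'spore_hybrid' or 'ribo'
        Which published design-matrix layout to build when none is given.
    dispersion_mode : 'trended', 'genewise' or 'fixed'
        'trended' (default): gene-wise Cox-Reid profile ML followed by
        MAP shrinkage toward the fitted mean-dispersion trend.
        'genewise': no shrinkage.  'fixed': use the ``dispersion``
        parameter as-is.
    dispersion : array-like or None
        Per-gene dispersions for ``dispersion_mode='fixed'``.
    prior_var_floor : float
        Lower bound on the log-dispersion prior variance used for MAP
        shrinkage.
    se_mode : 'observed' or 'expected'
        Information matrix used for Wald standard errors.
    test : 'wald' or 'lrt'
        Per-coefficient test for the effect columns.

    Attributes (after fit)
    ----------------------
    design_, coef_, se_, dispersion_, genewise_dispersion_,
    trend_coef_, prior_var_, pvalues_, converged_, results_
    """

    def __init__(self, dataset_kind=SPORE_HYBRID, dispersion_mode="trended",
                 dispersion=None, adjust="cox-reid", se_mode="observed",
                 dispersion_floor=glm.DISPERSION_FLOOR,
                 prior_var_floor=0.25, test="wald", alt_allele=None):
        self.dataset_kind = dataset_kind
        self.dispersion_mode = dispersion_mode
        self.dispersion = dispersion
        self.adjust = adjust
        self.se_mode = se_mode
        self.dispersion_floor = dispersion_floor
        self.prior_var_floor = prior_var_floor
        self.test = test
        self.alt_allele = alt_allele

    # -- fitting ----------------------------------------------------------

    def fit(self, counts, sample_sheet=None, offsets=None, design=None):
        """Fit every gene.

        ``counts``: DataFrame (genes x units) of integer counts.
        ``offsets``: per-gene-per-unit log offsets (log(s*f*l)); zero if
        omitted.  ``design`` overrides the built-in layout.
        """
        counts = pd.DataFrame(counts)
        if sample_sheet is None and design is None:
            sample_sheet = canonical_sample_sheet(self.dataset_kind)
        if design is None:
            design = build_design(sample_sheet, self.dataset_kind,
                                  self.alt_allele)
        if list(design.index) != list(counts.columns):
            missing = [c for c in counts.columns if c not in design.index]
            if missing:
                raise ValueError(
                    f"count columns missing from the design/sample sheet: "
                    f"{missing}")
            design = design.reindex(counts.columns)
        X = design.to_numpy(dtype=float)
        n, p = X.shape
        if n - p < 2 and self.dispersion_mode != "fixed":
            raise ValueError(
                "need at least 2 residual degrees of freedom to estimate "
                f"dispersion (n={n}, p={p})")
        K = counts.to_numpy(dtype=float)
        if offsets is None:
            off = np.zeros_like(K)
        else:
            off = (offsets.reindex(index=counts.index,
                                   columns=counts.columns).to_numpy(float)
                   if isinstance(offsets, pd.DataFrame)
                   else np.broadcast_to(np.asarray(offsets, float), K.shape))
        if not np.isfinite(off).all():
            raise ValueError("offsets must be finite")

        floor = self.dispersion_floor
        if self.dispersion_mode == "fixed":
            if self.dispersion is None:
                raise ValueError("dispersion_mode='fixed' needs dispersion")
            alpha = np.broadcast_to(
                np.asarray(self.dispersion, float).reshape(-1), (K.shape[0],))
            self.genewise_dispersion_ = None
            self.trend_coef_ = None
            self.prior_var_ = None
        else:
            # for 'trended' the gene-wise pass only locates the trend and
            # prior width, so a shorter refinement suffices
            gw_golden = 8 if self.dispersion_mode == "trended" else 18
            a_gw = glm.estimate_dispersions(K, X, off, adjust=self.adjust,
                                            floor=floor,
                                            golden_iters=gw_golden)
            self.genewise_dispersion_ = a_gw
            if self.dispersion_mode == "genewise":
                alpha = a_gw
                self.trend_coef_ = None
                self.prior_var_ = None
            elif self.dispersion_mode == "trended":
                mu_bar = (K / np.exp(off)).mean(axis=1)
                trend, coef = fit_dispersion_trend(a_gw, mu_bar, floor)
                use = a_gw > 10 * floor
                resid_df = (n - p) / 2.0
                if use.sum() >= 3:
                    lr = np.log(a_gw[use]) - np.log(trend[use])
                    s2 = (1.4826 * np.median(np.abs(lr - np.median(lr)))) ** 2
                else:
                    s2 = 0.0
                prior_var = max(s2 - polygamma(1, resid_df), self.prior_var_floor)
                # the MAP optimum lies between the gene-wise estimate and
                # the trend; bracket it with a wide safety margin
                la, lt = np.log(np.maximum(a_gw, floor)), np.log(trend)
                bracket = (np.minimum(la, lt) - 2.0, np.maximum(la, lt) + 2.0)
                alpha = glm.estimate_dispersions(
                    K, X, off, adjust=self.adjust, floor=floor,
                    penalty=(np.log(trend), prior_var),
                    n_coarse=6, golden_iters=15, bracket=bracket)
                self.trend_coef_ = coef
                self.dispersion_trend_ = trend
                self.prior_var_ = float(prior_var)
            else:
                raise ValueError(
                    f"unknown dispersion_mode {self.dispersion_mode!r}")

        fit = glm.wald_fit(K, X, off, alpha, se_mode=self.se_mode)
        self.design_ = design
        self.sample_sheet_ = sample_sheet
        self.gene_names_ = counts.index
        self.coef_ = fit["beta"]
        self.se_ = fit["se"]
        self.dispersion_ = fit["alpha"]
        self.converged_ = fit["converged"]
        self.se_fallback_ = fit["se_fallback"]
        self.loglik_ = fit["loglik"]
        self.mean_count_ = K.mean(axis=1)
        self._offsets = off
        self._K = K

        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef_ / self.se_
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        if self.test == "lrt":
            for name in EFFECT_COLUMNS[self.dataset_kind].values():
                j = list(design.columns).index(name)
                pvals[:, j] = self._lrt_pvalues(K, X, off, j)
        elif self.test != "wald":
            raise ValueError(f"unknown test {self.test!r}")
        self.zvalues_ = z
        self.pvalues_ = pvals
        return self

    def _lrt_pvalues(self, K, X, off, j):
        X_red = np.delete(X, j, axis=1)
        _, _, ll_red, _ = glm.fit_beta(K, X_red, off, self.dispersion_)
        lr = 2.0 * (self.loglik_ - ll_red)
        return stats.chi2.sf(np.maximum(lr, 0.0), df=1)

    # -- results ----------------------------------------------------------

    def results(self) -> pd.DataFrame:
        """Per-gene fit table: mean count, dispersion, coefficients with
        standard errors, and test p-values for the effect columns."""
        cols = list(self.design_.columns)
        out = pd.DataFrame(index=self.gene_names_)
        out["mean_count"] = self.mean_count_
        out["dispersion"] = self.dispersion_
        for j, c in enumerate(cols):
            out[f"beta_{c}"] = self.coef_[:, j]
        for j, c in enumerate(cols):
            out[f"se_{c}"] = self.se_[:, j]
        for name in EFFECT_COLUMNS[self.dataset_kind].values():
            j = cols.index(name)
            out[f"z_{name}"] = self.zvalues_[:, j]
            out[f"p_{name}"] = self.pvalues_[:, j]
        out["converged"] = self.converged_
        return out


# ---------------------------------------------------------------------------
# module-level operation wrappers


def estimate_dispersion(counts_i, design, offsets=None, adjust="cox-reid",
                        floor=glm.DISPERSION_FLOOR) -> float:
    """Gene-wise profile-ML dispersion for a single gene (no shrinkage).

    Non-convergent/Poisson-like genes land on the floor.
    """
    X = design.to_numpy(float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    k = np.asarray(counts_i, float).reshape(1, -1)
    off = None if offsets is None else np.asarray(offsets, float).reshape(1, -1)
    return float(glm.estimate_dispersions(k, X, off, adjust=adjust,
                                          floor=floor)[0])


def fit_gene(counts_i, design, offsets=None, dispersion=None,
             se_mode="observed") -> pd.Series:
    """Fit a single gene at a given (or gene-wise estimated) dispersion."""
    X = design.to_numpy(float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    cols = (list(design.columns) if isinstance(design, pd.DataFrame)
            else [f"x{j}" for j in range(X.shape[1])])
    k = np.asarray(counts_i, float).reshape(1, -1)
    off = None if offsets is None else np.asarray(offsets, float).reshape(1, -1)
    if dispersion is None:
        dispersion = estimate_dispersion(counts_i, design, offsets)
    fit = glm.wald_fit(k, X, off, np.asarray([dispersion], float),
                       se_mode=se_mode)
    data = {"dispersion": fit["alpha"][0], "converged": fit["converged"][0]}
    for j, c in enumerate(cols):
        data[f"beta_{c}"] = fit["beta"][0, j]
        data[f"se_{c}"] = fit["se"][0, j]
    return pd.Series(data)


def wald_fdr(results: pd.DataFrame, coefficients=None,
             dataset_kind=SPORE_HYBRID) -> pd.DataFrame:
    """BH-adjust the per-gene p-values, separately per coefficient
    family (cis genes and local-trans genes are separate lists)."""
    if coefficients is None:
        coefficients = list(EFFECT_COLUMNS[dataset_kind].values())
    out = results.copy()
    for c in coefficients:
        p = out[f"p_{c}"].to_numpy()
        fdr = np.full_like(p, np.nan)
        fin = np.isfinite(p)
        if fin.any():
            fdr[fin] = multipletests(p[fin], method="fdr_bh")[1]
        out[f"fdr_{c}"] = fdr
    return out


def call_genes(results: pd.DataFrame, fold: float = 1.5, fdr: float = 0.2,
               coefficient: str = "cis",
               dataset_kind: str = SPORE_HYBRID) -> pd.Series:
    """Genes with ``|beta| > ln(fold)`` (strict) and BH FDR below ``fdr``."""
    if fold <= 0 or fdr <= 0:
        raise ValueError("fold and fdr thresholds must be positive")
    name = (coefficient if f"beta_{coefficient}" in results.columns
            else resolve_coefficient(coefficient, dataset_kind))
    beta = results[f"beta_{name}"]
    q = results[f"fdr_{name}"]
    called = (beta.abs() > np.log(fold)) & (q < fdr)
    return called.fillna(False)
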