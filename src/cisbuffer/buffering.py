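"""The buffering coefficient: estimation, calibration, significance.

For a called cis gene the allelic log-ratio is ``beta_cis`` in the
hybrid (both alleles share one trans environment) and
``beta_cis + beta_lt`` in the pool of spores (the local genotype
co-segregates with its linked trans factors).  The buffering
coefficient is one minus the ratio of the spore allelic log-ratio to
the hybrid allelic log-ratio,

    C = 1 - (beta_cis + beta_lt) / beta_cis = -beta_lt / beta_cis,

so C = 0 means no buffering, C = 1 complete compensation, C < 0
enhancement of the cis effect.  The plug-in ("raw") estimator
``-beta_lt_hat / beta_cis_hat`` is biased — cis genes are selected for
large ``|beta_cis_hat|`` — so it is calibrated empirically: genomewide
counts are re-simulated from the fitted parameters with the local-trans
coefficient substituted by ``-c * beta_cis_hat`` over a grid of true
``c``, the complete analysis is re-run per grid point, and the linear
regression of the median raw coefficient on the true value becomes the
calibration function.  Cohort significance uses a semi-parametric
permutation bootstrap: local-trans estimates are permuted between
genes, counts redrawn, the whole analysis re-run, and the observed
median compared with the bootstrap medians.

The translational analogue replaces (cis, local-trans) with
(RNA-cis, TE-cis) from the ribosome-profiling layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone

from .design import EFFECT_COLUMNS, RIBO, SPORE_HYBRID
from .pipeline import PipelineResult, run_ase_pipeline

DEFAULT_GRID = tuple(np.round(np.linspace(0.0, 0.5, 11), 3))
PAPER_GRID = tuple(np.round(np.arange(0.0, 0.5 + 1e-9, 0.005), 3))


def _raw_one(beta_cis: float, beta_lt: float, fold: float) -> float:
    if not abs(beta_cis) > np.log(fold):
        raise ValueError(
            "buffering is ill-defined without a sufficiently large cis "
            f"effect (|beta_cis| = {abs(beta_cis):.4f} <= ln {fold})")
    return -beta_lt / beta_cis


def raw_buffering(fit, dataset_kind: str = SPORE_HYBRID,
                  fold: float = 1.5) -> float | pd.Series:
    """Raw buffering coefficient ``-beta_lt / beta_cis``.

    ``fit`` is one gene's fit (Series with ``beta_cis``/``beta_lt``
    style fields; raises if the cis effect is below the fold threshold)
    or a whole fit table (returns a Series, NaN for ineligible genes —
    not called / not converged).  Invariant under allele relabelling:
    numerator and denominator negate together.
    """
    cis_col = EFFECT_COLUMNS[dataset_kind]["cis"]
    lt_col = EFFECT_COLUMNS[dataset_kind]["trans"]
    if isinstance(fit, pd.Series):
        return _raw_one(fit[f"beta_{cis_col}"], fit[f"beta_{lt_col}"], fold)
    beta_cis = fit[f"beta_{cis_col}"]
    beta_lt = fit[f"beta_{lt_col}"]
    if f"called_{cis_col}" in fit.columns:
        eligible = fit[f"called_{cis_col}"].astype(bool)
    else:
        eligible = beta_cis.abs() > np.log(fold)
    if "converged" in fit.columns:
        eligible = eligible & fit["converged"].astype(bool)
    c = -beta_lt / beta_cis
    return c.where(eligible)


def raw_translational_buffering(fit, fold: float = 1.5):
    """Raw buffering of RNA cis effects at the ribosome-bound level:
    ``-beta_TEcis / beta_RNAcis``."""
    return raw_buffering(fit, dataset_kind=RIBO, fold=fold)


# ---------------------------------------------------------------------------
# re-simulation from fitted parameters


def simulate_from_result(result: PipelineResult, beta_lt_new: np.ndarray,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Redraw genomewide counts from the fitted model, with the
    local-trans (TE-cis) coefficients replaced by ``beta_lt_new`` and
    every other parameter fixed at its estimate."""
    model = result.model
    cols = list(result.design.columns)
    j = cols.index(result.trans_column)
    beta = model.coef_.copy()
    beta[:, j] = beta_lt_new
    X = result.design.to_numpy(float)
    mu = np.exp(np.clip(beta @ X.T + result.total_offsets, -40.0, 40.0))
    alpha = np.maximum(result.fits["dispersion"].to_numpy(), 1e-12)
    lam = rng.gamma(1.0 / alpha[:, None], alpha[:, None] * mu)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=result.fits.index,
                        columns=result.design.index)


def _rerun(result: PipelineResult, counts: pd.DataFrame) -> PipelineResult:
    """The exact same analysis as the primary dataset, on new counts."""
    return run_ase_pipeline(
        counts, sample_sheet=result.sample_sheet,
        fl_offsets=result.fl_offsets, dataset_kind=result.dataset_kind,
        model=clone(result.model), **result.params)


def _median_raw(res: PipelineResult) -> tuple[float, int]:
    c = raw_buffering(res.fits, dataset_kind=res.dataset_kind,
                      fold=res.params.get("fold", 1.5)).dropna()
    return (float(np.median(c)) if len(c) else np.nan), len(c)


# ---------------------------------------------------------------------------
# calibration


class BufferingCalibrator(BaseEstimator):
    """Empirical bias calibration of the raw buffering coefficient.

    ``fit`` simulates the calibration grid from a fitted primary
    analysis and regresses the per-grid-point median raw coefficient on
    the injected true value; ``transform`` applies the inverse affine
    map ``(raw - intercept_) / slope_``.

    Parameters
    ----------
    grid : sequence of true C values in [0, 0.5]
        Desk-scale default: 11 points.  ``PAPER_GRID`` is the 101-point
        (0.005-spaced) full-scale protocol.
    min_cis_genes : int
        Grid runs yielding fewer called cis genes are flagged and
        excluded from the regression.
    random_state : int
        Seeds the count redraws.
    """

    def __init__(self, grid=DEFAULT_GRID, min_cis_genes: int = 20,
                 random_state: int = 0):
        self.grid = grid
        self.min_cis_genes = min_cis_genes
        self.random_state = random_state

    def fit(self, result: PipelineResult, y=None):
        grid = np.asarray(self.grid, dtype=float)
        if grid.min() < 0.0 or grid.max() > 0.5:
            raise ValueError("calibration grid must lie within [0, 0.5]")
        cis_hat = result.fits[f"beta_{result.cis_column}"].to_numpy()
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.random_state,
                                   spawn_key=(201,)))
        medians = np.empty(grid.size)
        n_cis = np.empty(grid.size, dtype=int)
        for i, c in enumerate(grid):
            counts = simulate_from_result(result, -c * cis_hat, rng)
            medians[i], n_cis[i] = _median_raw(_rerun(result, counts))
        ok = np.isfinite(medians) & (n_cis >= self.min_cis_genes)
        if ok.sum() < 3:
            raise RuntimeError(
                "too few usable calibration runs "
                f"({ok.sum()} of {grid.size}); cohort too small?")
        if not ok.all():
            import warnings
            warnings.warn(
                f"{(~ok).sum()} calibration run(s) with fewer than "
                f"{self.min_cis_genes} cis genes excluded from the fit")
        reg = stats.linregress(grid[ok], medians[ok])
        self.grid_ = grid
        self.median_raw_ = medians
        self.n_cis_ = n_cis
        self.used_ = ok
        self.slope_ = float(reg.slope)
        self.intercept_ = float(reg.intercept)
        self.pearson_r_ = float(reg.rvalue)
        return self

    def transform(self, raw):
        """Calibrated C for raw coefficient(s)."""
        if not hasattr(self, "slope_"):
            raise RuntimeError("calibrator is not fitted")
        return (raw - self.intercept_) / self.slope_

    def curve(self) -> pd.DataFrame:
        """Calibration diagnostics: grid value, median raw C, cis-gene
        count, and whether the point entered the regression."""
        return pd.DataFrame({
            "true_c": self.grid_, "median_raw_c": self.median_raw_,
            "n_cis_genes": self.n_cis_, "used": self.used_})

    def plot(self, path=None):
        """Diagnostic scatter of the grid vs median raw C with the
        fitted calibration line (requires matplotlib)."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(self.grid_[self.used_], self.median_raw_[self.used_],
                   s=18, label="grid runs")
        if (~self.used_).any():
            ax.scatter(self.grid_[~self.used_], self.median_raw_[~self.used_],
                       s=18, marker="x", color="crimson", label="excluded")
        xs = np.array([self.grid_.min(), self.grid_.max()])
        ax.plot(xs, self.intercept_ + self.slope_ * xs, color="gray",
                label=f"fit (r={self.pearson_r_:.3f})")
        ax.set_xlabel("true C (injected)")
        ax.set_ylabel("median raw C")
        ax.legend(frameon=False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def calibrate(result: PipelineResult, grid=DEFAULT_GRID, seed: int = 0,
              min_cis_genes: int = 20) -> tuple[BufferingCalibrator, pd.Series]:
    """Fit the calibration on ``result`` and return
    ``(calibrator, calibrated per-gene C for the called cis genes)``."""
    cal = BufferingCalibrator(grid=grid, min_cis_genes=min_cis_genes,
                              random_state=seed).fit(result)
    raw = raw_buffering(result.fits, dataset_kind=result.dataset_kind,
                        fold=result.params.get("fold", 1.5))
    return cal, cal.transform(raw).dropna()


# ---------------------------------------------------------------------------
# permutation bootstrap


def bootstrap_pvalue(observed: float, medians) -> float:
    """One-sided Monte-Carlo p-value ``(1 + #{b : m_b >= obs}) / (B + 1)``.

    Ties count toward the numerator (conservative); bounded in
    ``[1/(B+1), 1]``.  Non-finite bootstrap values are dropped.
    """
    medians = np.asarray(medians, dtype=float)
    medians = medians[np.isfinite(medians)]
    if medians.size == 0:
        raise ValueError("no finite bootstrap values")
    return float((1.0 + np.sum(medians >= observed)) / (medians.size + 1.0))


@dataclass
class BootstrapResult:
    """One-sided cohort significance of the median buffering coefficient.

    ``p_value = (1 + #{b : median_b >= median_obs}) / (B + 1)``, ties
    counting against the observed value (conservative).  Medians are of
    the *raw* coefficient on both sides; the affine calibration is
    monotone increasing, so the p-value is unchanged by calibrating
    both.
    """

    p_value: float
    observed_median: float
    medians: np.ndarray
    n_effective: int
    n_cis_observed: int


def bootstrap_significance(result: PipelineResult, B: int = 1000,
                           random_state: int = 0) -> BootstrapResult:
    """Semi-parametric permutation bootstrap of the cohort median.

    Under the null the local-trans effect is independent of the cis
    effect: the fitted local-trans coefficients are permuted between
    genes (all filtered genes), counts redrawn with everything else
    fixed, and the complete analysis re-run B times.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs, n_cis = _median_raw(result)
    if not np.isfinite(obs):
        raise ValueError("no called cis genes in the observed dataset")
    lt_hat = result.fits[f"beta_{result.trans_column}"].to_numpy()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=random_state, spawn_key=(202,)))
    medians = np.full(B, np.nan)
    for b in range(B):
        permuted = rng.permutation(lt_hat)
        counts = simulate_from_result(result, permuted, rng)
        medians[b], _ = _median_raw(_rerun(result, counts))
    n_eff = int(np.isfinite(medians).sum())
    if n_eff == 0:
        raise RuntimeError("every bootstrap replicate failed to call cis genes")
    p = bootstrap_pvalue(obs, medians)
    return BootstrapResult(p_value=float(p), observed_median=obs,
                           medians=medians, n_effective=n_eff,
                           n_cis_observed=n_cis)
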