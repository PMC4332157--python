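"""Synthetic allele-specific count data with known ground truth.

Emulates the count structure of an allele-specific RNA-seq study of a
yeast hybrid and its pool of spores: per-gene NB counts over the
canonical (sample, allele) units, with configurable cis effects,
local-trans effects (parameterised through the buffering coefficient),
per-gene dispersions, per-sample size factors, allele-length ratios and
selection-skewed spore allele frequencies.  A ribosome-profiling variant
and a per-SNP genomic allele-count table (for the frequency smoother)
are generated by the same machinery.

Counts are drawn by the exact Gamma-Poisson mixture representation of
the negative binomial, so the mean of each count is exactly
``s_j * f_ij * l_ij * exp(x_j' beta_i)`` and the variance is
``mu + alpha_i * mu^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design as design_mod
from .design import RIBO, SPORE_HYBRID, build_design, canonical_sample_sheet

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SnpSimConfig",
    "simulate_truth",
    "simulate_counts",
    "simulate_ribo_counts",
    "simulate_snp_counts",
    "offsets_from_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating distributions for a synthetic cohort.

    Effects are on the natural-log scale.  ``buffering`` sets the true
    buffering coefficient C (scalar, ``("uniform", lo, hi)``, or an
    array of per-gene values); the local-trans effect is then
    ``beta_lt = -C * beta_cis``.  Setting ``buffering=None`` instead
    draws ``beta_lt ~ N(0, lt_sd)`` *independently* of the cis effect
    (the null of no cis/local-trans coupling).
    """

    n_genes: int = 2000
    seed: int = 0
    # cis effects: ~15% of genes exceed the 1.5-fold threshold at sd 0.4
    cis_mean: float = 0.0
    cis_sd: float = 0.4
    buffering: object = 0.0
    lt_sd: float = 0.1
    # per-gene dispersion: log-normal, typical bulk RNA-seq range
    dispersion_median: float = 0.05
    dispersion_log_sd: float = 0.5
    # baseline expression level q (mean counts before the 0.5 allele split);
    # the median emulates deep bulk RNA-seq (hundreds of reads per allele)
    baseline_median: float = 500.0
    baseline_log_sd: float = 1.0
    # per-sample sequencing-depth factors (hybrid A/B, spore A/B)
    size_factors: tuple = (1.0, 0.85, 1.15, 0.95)
    # allele length ratio l_alt/l_ref, tight around 1
    length_ratio_log_sd: float = 0.02
    # spore-pool allele frequency of the variant allele
    spore_freq_model: str = "constant"  # "constant" | "skewed"
    spore_freq: float = 0.5
    skew_sd: float = 0.1  # logit-scale sd of per-gene selection skew
    # nuisance coefficients (Table-1-style confounders)
    diploid_effect: float = 0.1
    hybrid_b_effect: float = 0.05
    spore_b_effect: float = -0.05
    # ribosome-profiling nuisances
    rna_bias_effect: float = 0.3
    rep2_effect: float = 0.05
    n_hybrid_reps: int = 2
    n_spore_reps: int = 2

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if any(s <= 0 for s in self.size_factors):
            raise ValueError("size factors must be positive")
        if not 0.0 < self.spore_freq < 1.0:
            raise ValueError("spore allele frequency must be in (0, 1)")
        if self.dispersion_median <= 0:
            raise ValueError("dispersion must be positive")
        if self.spore_freq_model not in ("constant", "skewed"):
            raise ValueError(
                f"unknown spore_freq_model {self.spore_freq_model!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth generating parameters, one row per gene.

    ``genes`` columns: beta_cis, beta_lt, true_c, dispersion,
    log_baseline, spore_freq (variant allele), length_ratio.
    ``size_factors``: per sample.  Where ``beta_cis != 0`` the identity
    ``true_c == -beta_lt / beta_cis`` holds.
    """

    genes: pd.DataFrame
    size_factors: pd.Series
    config: SimulationConfig

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _true_c(config: SimulationConfig, rng, n: int):
    spec = config.buffering
    if spec is None:
        return None
    if isinstance(spec, (int, float)):
        return np.full(n, float(spec))
    if isinstance(spec, (tuple, list)) and len(spec) == 3 and spec[0] == "uniform":
        return rng.uniform(float(spec[1]), float(spec[2]), n)
    arr = np.asarray(spec, dtype=float)
    if arr.shape != (n,):
        raise ValueError(
            "buffering must be a scalar, ('uniform', lo, hi) or an array "
            f"of length n_genes; got {spec!r}")
    return arr


def simulate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw one generating parameter set per gene (deterministic in seed)."""
    rng = _rng_for(config, 0)
    n = config.n_genes
    beta_cis = rng.normal(config.cis_mean, config.cis_sd, n)
    true_c = _true_c(config, rng, n)
    if true_c is None:
        beta_lt = rng.normal(0.0, config.lt_sd, n)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_col = np.where(beta_cis != 0.0, -beta_lt / beta_cis, np.nan)
    else:
        beta_lt = -true_c * beta_cis
        c_col = true_c
    dispersion = np.exp(rng.normal(
        np.log(config.dispersion_median), config.dispersion_log_sd, n))
    log_baseline = rng.normal(
        np.log(config.baseline_median), config.baseline_log_sd, n)
    length_ratio = np.exp(rng.normal(0.0, config.length_ratio_log_sd, n))
    if config.spore_freq_model == "constant":
        spore_freq = np.full(n, config.spore_freq)
    else:  # per-gene selection skew on the logit scale
        logit = np.log(config.spore_freq / (1 - config.spore_freq))
        z = logit + rng.normal(0.0, config.skew_sd, n)
        spore_freq = 1.0 / (1.0 + np.exp(-z))
    genes = pd.DataFrame({
        "beta_cis": beta_cis,
        "beta_lt": beta_lt,
        "true_c": c_col,
        "dispersion": dispersion,
        "log_baseline": log_baseline,
        "spore_freq": spore_freq,
        "length_ratio": length_ratio,
    }, index=pd.Index([f"gene{i:05d}" for i in range(n)], name="gene"))

    n_samples = config.n_hybrid_reps + config.n_spore_reps
    sf = np.asarray(config.size_factors, dtype=float)
    if sf.size < n_samples:
        raise ValueError(
            f"need {n_samples} size factors, got {sf.size}")
    sheet = canonical_sample_sheet(
        SPORE_HYBRID, config.n_hybrid_reps, config.n_spore_reps)
    samples = sheet["sample"].unique()
    size_factors = pd.Series(sf[:n_samples], index=samples, name="size_factor")
    return SyntheticTruth(genes=genes, size_factors=size_factors, config=config)


def _truth_beta(truth: SyntheticTruth, columns, dataset_kind: str) -> np.ndarray:
    cfg = truth.config
    g = truth.genes
    named = {
        "intercept": g["log_baseline"].to_numpy(),
        "cis": g["beta_cis"].to_numpy(),
        "local_trans": g["beta_lt"].to_numpy(),
        "diploid": np.full(len(g), cfg.diploid_effect),
        "rna_cis": g["beta_cis"].to_numpy(),
        "te_cis": g["beta_lt"].to_numpy(),
        "rna_bias": np.full(len(g), cfg.rna_bias_effect),
    }
    beta = np.zeros((len(g), len(columns)))
    for j, col in enumerate(columns):
        if col in named:
            beta[:, j] = named[col]
        elif col == "hybrid_b":
            beta[:, j] = cfg.hybrid_b_effect
        elif col == "spore_b":
            beta[:, j] = cfg.spore_b_effect
        elif col.startswith("hybrid_rep"):
            beta[:, j] = cfg.rep2_effect
        elif col.startswith(("hybrid_", "spore_")):
            beta[:, j] = 0.0  # extra replicates beyond B: no effect
        else:
            raise ValueError(f"no true value for design column {col!r}")
    return beta


def _unit_factors(truth: SyntheticTruth, sheet: pd.DataFrame,
                  dataset_kind: str):
    """Per gene x unit (size factor, allele frequency, allele length)."""
    n_genes = truth.n_genes
    alt = sheet.attrs.get("alt_allele",
                          design_mod.DEFAULT_ALLELES[dataset_kind][0])
    is_alt = (sheet["allele"] == alt).to_numpy()
    if dataset_kind == SPORE_HYBRID:
        s = truth.size_factors.reindex(sheet["sample"]).to_numpy()
        is_spore = (sheet["generation"] == "spore").to_numpy()
        f_alt = truth.genes["spore_freq"].to_numpy()[:, None]
        f = np.where(is_spore, np.where(is_alt, f_alt, 1.0 - f_alt), 0.5)
        f = np.broadcast_to(f, (n_genes, len(sheet)))
    else:
        sf = np.asarray(truth.config.size_factors, dtype=float)
        samples = sheet["sample"].unique()
        s = pd.Series(sf[: len(samples)], index=samples).reindex(
            sheet["sample"]).to_numpy()
        f = np.full((n_genes, len(sheet)), 0.5)
    lr = truth.genes["length_ratio"].to_numpy()[:, None]
    l = np.where(is_alt, lr, 1.0)
    l = np.broadcast_to(l, (n_genes, len(sheet)))
    return np.broadcast_to(s, (n_genes, len(sheet))), f, l


def offsets_from_truth(truth: SyntheticTruth, sheet: pd.DataFrame,
                       dataset_kind: str = SPORE_HYBRID,
                       include_size_factors: bool = False) -> pd.DataFrame:
    """Known per-unit log offsets ``log(f * l)`` (optionally ``+ log s``).

    Size factors are normally excluded: the analysis pipeline
    re-estimates them from the counts, mirroring how the real study only
    knows f (from genomic DNA) and l (from annotation) a priori.
    """
    s, f, l = _unit_factors(truth, sheet, dataset_kind)
    off = np.log(f) + np.log(l)
    if include_size_factors:
        off = off + np.log(s)
    return pd.DataFrame(off, index=truth.genes.index, columns=sheet.index)


def _draw_nb(rng, mu, alpha):
    """Exact NB draw via the Gamma-Poisson mixture; Poisson below 1e-12."""
    alpha = np.broadcast_to(np.asarray(alpha, float)[:, None], mu.shape)
    lam = np.where(
        alpha > 1e-12,
        rng.gamma(1.0 / np.maximum(alpha, 1e-12),
                  np.maximum(alpha, 1e-12) * mu),
        mu)
    return rng.poisson(lam)


def _simulate(truth: SyntheticTruth, dataset_kind: str, seed_stream: int,
              sheet: pd.DataFrame | None, rng=None):
    if sheet is None:
        cfg = truth.config
        if dataset_kind == SPORE_HYBRID:
            sheet = canonical_sample_sheet(
                SPORE_HYBRID, cfg.n_hybrid_reps, cfg.n_spore_reps)
        else:
            sheet = canonical_sample_sheet(RIBO, cfg.n_hybrid_reps)
    X = build_design(sheet, dataset_kind).to_numpy(dtype=float)
    columns = build_design(sheet, dataset_kind).columns
    beta = _truth_beta(truth, columns, dataset_kind)
    s, f, l = _unit_factors(truth, sheet, dataset_kind)
    mu = s * f * l * np.exp(beta @ X.T)
    bad = ~np.isfinite(mu).all(axis=1)
    if bad.any():
        name = truth.genes.index[np.argmax(bad)]
        raise ValueError(f"non-finite expected count for gene {name!r}")
    if rng is None:
        rng = _rng_for(truth.config, seed_stream)
    counts = _draw_nb(rng, mu, truth.genes["dispersion"].to_numpy())
    counts = pd.DataFrame(counts, index=truth.genes.index,
                          columns=sheet.index)
    return counts, sheet


def simulate_counts(truth: SyntheticTruth, sheet: pd.DataFrame | None = None,
                    rng=None):
    """Hybrid + spore-pool allele-specific counts.

    Returns ``(counts, sample_sheet)``; the expected value of each count
    is exactly ``s_j * f_ij * l_ij * exp(x_j' beta_i)``.
    """
    return _simulate(truth, SPORE_HYBRID, 1, sheet, rng)


def simulate_ribo_counts(truth: SyntheticTruth,
                         sheet: pd.DataFrame | None = None, rng=None):
    """RNA + ribosome-profiling allele-specific counts (hybrid only).

    The ribosome-bound fraction is the product of the RNA level and the
    allele's binding affinity, so the TE-cis effect adds to the RNA-cis
    effect in the RIBO units only.
    """
    return _simulate(truth, RIBO, 2, sheet, rng)


# ---------------------------------------------------------------------------
# Genomic SNP counts for the spore pool


@dataclass(frozen=True)
class SnpSimConfig:
    """Per-SNP genomic allele counts around a smooth latent frequency.

    The latent curve emulates selection during spore growth (natural
    selection plus the technical selection for one mating type): smooth
    excursions of the reference-allele frequency away from 0.5 along
    each chromosome, with binomial sampling noise at Poisson depths on
    top, and an optional global mapping bias toward the reference.
    """

    chromosomes: tuple = (("chrI", 400_000), ("chrII", 300_000))
    mean_spacing_bp: int = 400
    mean_depth: float = 60.0
    n_bumps_per_mb: float = 8.0
    bump_amplitude_sd: float = 0.12
    bump_width_bp: tuple = (20_000, 60_000)
    mapping_bias: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.mean_spacing_bp <= 0 or self.mean_depth < 0:
            raise ValueError("spacing and depth must be positive")
        if not 0.0 < self.mapping_bias < 1.0:
            raise ValueError("mapping bias must be in (0, 1)")


def _logit(p):
    return np.log(p / (1.0 - p))


def simulate_snp_counts(config: SnpSimConfig):
    """Returns ``(snp_table, latent)`` DataFrames.

    ``snp_table``: chrom, pos (1-based, strictly increasing per
    chromosome), ref_count, alt_count.  ``latent`` adds the true smooth
    reference-allele frequency per SNP for recovery tests.  SNPs may
    have zero depth (dropout); the smoother must handle them.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(100,)))
    rows = []
    lat_rows = []
    for chrom, length in config.chromosomes:
        gaps = rng.exponential(config.mean_spacing_bp,
                               int(2 * length / config.mean_spacing_bp) + 10)
        pos = np.unique(np.cumsum(gaps).astype(np.int64) + 1)
        pos = pos[pos <= length]
        n_bumps = max(1, rng.poisson(config.n_bumps_per_mb * length / 1e6))
        centers = rng.uniform(0, length, n_bumps)
        widths = rng.uniform(*config.bump_width_bp, n_bumps)
        amps = rng.normal(0.0, config.bump_amplitude_sd, n_bumps)
        z = np.zeros(pos.size)
        for c, w, a in zip(centers, widths, amps):
            z += a * np.exp(-0.5 * ((pos - c) / w) ** 2)
        latent = 1.0 / (1.0 + np.exp(-z))  # logistic keeps it in (0,1)
        p_obs = 1.0 / (1.0 + np.exp(
            -(z + _logit(config.mapping_bias) - _logit(0.5))))
        depth = rng.poisson(config.mean_depth, pos.size)
        ref = rng.binomial(depth, p_obs)
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref_count": ref,
            "alt_count": depth - ref}))
        lat_rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "latent_freq": latent}))
    snps = pd.concat(rows, ignore_index=True)
    latent = pd.concat(lat_rows, ignore_index=True)
    return snps, latent
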