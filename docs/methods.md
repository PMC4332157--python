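# Methods

## The model

A cis-regulatory variant changes the expression of the allele on its own
chromosome and therefore produces an allelic expression imbalance (ADE)
wherever that allele is observed: both in the F1 hybrid and in a bulk
pool of its meiotic spores.  A *local trans* effect — a diffusible
regulator or feedback loop inherited together with its target gene —
acts on both alleles in the hybrid, where the two alleles share a single
trans environment, but co-segregates with the gene in the spores and so
contributes to ADE only there.  Comparing allele-specific expression
between the two generations separates the two effect classes.

Allele-specific read counts `K_ijk` (gene i, sample j, allele k) are
modelled as negative binomial,

    K_ijk ~ NB(mean = s_j * f_ij * l_ij * q_ij,  dispersion = alpha_i)
    log q_ij = x_j' beta_i

with known multiplicative offsets: `s_j` the per-sample size factor
(median-of-ratios), `f_ij` the allele frequency of the gene in the
sample (0.5 exactly in the hybrid; estimated from genomic DNA of the
spore pool, which is skewed by natural selection and the technical
selection for one mating type), and `l_ij` the allele length (the two
parental alleles differ slightly).  The covariate vector follows the
published eight-unit layouts: for the spore/hybrid dataset the columns
are cis, local-trans, diploid and one indicator per extra replicate of
each generation; for the RNA/ribosome-profiling dataset they are
RNA-cis, TE-cis, RNA-bias and a replicate indicator.  In this
parameterisation the hybrid allelic log-ratio is `beta_cis` and the
spore-pool allelic log-ratio is `beta_cis + beta_lt`.

## Fitting and testing

Each gene is fitted by Fisher-scoring IRLS at fixed dispersion with the
offsets entering as known constants (mirroring the plug-in use of
genomic allele frequencies).  Coefficients are reported as raw maximum
likelihood without fold-change shrinkage: the buffering estimator below
needs unshrunken ratios.

The canonical design has eight observations and six coefficients — two
residual degrees of freedom — so gene-wise dispersion estimates are far
too noisy to support calibrated Wald tests (measured type-I error of
~0.15 at nominal 0.05 with gene-wise Cox–Reid profile ML, ~0.27
without the Cox–Reid adjustment).  The default is therefore the
standard empirical-Bayes remedy for NB count models:

1. gene-wise Cox–Reid-adjusted profile ML dispersion per gene
   (`alpha` maximising `l(alpha, beta_hat(alpha)) - 0.5 logdet(X'WX)`,
   floor 1e-8, searched by a bracketed golden-section on the log scale);
2. a parametric mean–dispersion trend `alpha(mu) = a0 + a1/mu` fitted
   by an iterated Gamma GLM on the non-floor gene-wise estimates;
3. a log-normal prior around the trend whose variance is the robust
   spread of the gene-wise estimates minus the sampling variance
   `trigamma((n-p)/2)`, floored at 0.25;
4. MAP re-estimation of each gene's dispersion under that prior.

Gene-wise (unshrunk) and fixed dispersion modes remain available
(`dispersion_mode="genewise" | "fixed"`).  Wald tests use the observed
information (with a fallback to the expected information when the
observed matrix is not positive definite); a likelihood-ratio test is
available behind `test="lrt"`.  Under a null cohort the Wald p < 0.05
fraction is ~0.05 for both effect coefficients (see the acceptance
tests).  P-values are BH-adjusted separately for the cis and the
local-trans family, and genes are called at `|beta| > ln(fold)`
(strict) and FDR < threshold; defaults 1.5-fold and 0.2.

Genes with fewer than 10 mean reads over all units are removed before
fitting; size factors are median-of-ratios per count column, rescaled
to geometric mean 1.

## Buffering coefficient

For a called cis gene, `C = 1 - (beta_cis + beta_lt)/beta_cis
= -beta_lt/beta_cis`: 0 means no buffering, 1 complete compensation,
negative values enhancement.  C is ill-defined when the hybrid ratio is
near zero, hence the restriction to genes with a large and significant
cis effect.  The plug-in estimator `-beta_lt_hat/beta_cis_hat` is
biased: cis genes are selected for large `|beta_cis_hat|`, so the
estimation errors of the two coefficients (which are negatively
correlated by construction of the design) do not cancel.  Calibration
is empirical: for each grid value c of true C, `beta_lt` is replaced by
`-c * beta_cis_hat` for every gene, genomewide counts are redrawn from
the fitted model with all other parameters fixed, the complete analysis
(filter, normalisation, fits, calling) is re-run, and the median raw
coefficient over the re-called cis genes is recorded.  The linear
regression of these medians on the grid is the calibration function;
calibrated C is `(raw - intercept)/slope`.  The desk-scale default grid
is 11 points over [0, 0.5]; `PAPER_GRID` provides the full-scale
101-point, 0.005-spaced protocol.  Grid runs with fewer than 20 called
cis genes are flagged and excluded from the regression.

Cohort significance uses a semi-parametric permutation bootstrap: under
the null of independence between cis and local-trans effects, the
fitted `beta_lt` values are permuted between genes (all filtered genes
form the pool), counts redrawn, the full analysis re-run, and the
median raw coefficient recorded, B times (default 1000; desk-scale 99).
The one-sided p-value is `(1 + #{b : median_b >= median_obs})/(B + 1)`;
ties count toward the numerator (conservative).  Both sides of the
comparison use raw medians — the affine calibration is increasing, so
calibrating both sides leaves the p-value unchanged.  Bootstrap or
calibration refits that fail to converge are dropped from that run's
median only.

### Known limitation: residual calibration bias

The calibration re-simulates from *fitted* coefficients, whose
distribution is wider than the truth (sd of fitted beta_cis ~=
sqrt(sd_true^2 + SE^2), with SE(beta_cis) ~= 0.23 at dispersion 0.05 —
dispersion-dominated, so deeper sequencing does not shrink it).  Grid
runs therefore experience a milder winner's curse than the primary
data, and the fitted line under-corrects: on synthetic cohorts of 2,000
genes with constant true C, the calibrated cohort median overshoots by
roughly +0.04 on average.  This asymmetry is intrinsic to the empirical
calibration (only fitted values are available on real data); the
corresponding recovery tests in `tests/test_acceptance.py` document it
and are expected to fail for small true C.  The calibration
*relationship* itself is tightly linear (Pearson r 0.99+), and the
permutation bootstrap is unaffected because both of its sides use
fitted-parameter simulations.

## Spore allele frequencies

Per-SNP genomic allele counts are smoothed by local binomial
likelihood: at each SNP the smoothed frequency is the tricube-weighted
binomial MLE `sum(w*ref)/sum(w*depth)` over SNPs within half a 28 kb
window (about 10 cM in yeast) on either side.  A local-constant fit was
chosen over local-quadratic: it has a closed form testable against
direct enumeration.  Zero-depth SNPs carry no weight; SNPs whose whole
window has zero depth are flagged and excluded downstream.  The global
mapping bias toward the better-annotated reference genome is removed on
the logit scale — `logit(corrected) = logit(raw) - logit(bias) +
logit(0.5)` — which keeps frequencies in (0,1) and is exactly
invertible.  Gene-level frequencies are the mean of smoothed values at
SNPs overlapping the gene (1-based closed intervals); genes without SNP
coverage fall back to the nearest smoothed SNP within 28 kb, else 0.5
with a flag.

## Stratified analyses

Expression level is the average read count divided by the mean gene
length over both strains, cut at the empirical 1/3 and 2/3 quantiles
into Low/Middle/High terciles (stable ties).  Per gene category the
cis-gene proportion is reported with an exact Clopper–Pearson 95% CI
(reproducible without approximation choices) and a two-sided Fisher
exact test against all other genes pooled.  Buffering comparisons
between groups use the rank-sum test — exact enumeration for tie-free
samples up to n=50, normal approximation with tie correction above —
and the cohort-level "median C > 0" check is a one-sided signed-rank
test.  Matched resampling against an external cohort draws, with
replacement, exactly the target number of genes per expression tercile
(restricted to a category, e.g. non-essential), 1,000 times by default.

## Synthetic data generator

The generator emulates the study's count structure, not its reads: four
samples (hybrid A/B, spore pool A/B) by two alleles, NB counts drawn by
the exact Gamma–Poisson mixture so the mean is exactly
`s*f*l*exp(x'beta)` for any dispersion.  Defaults (one choice per
parameter, stated here once):

- cis effects `N(0, 0.4)` on the natural-log scale (~15–30% of genes
  beyond the 1.5-fold threshold, a realistic calling regime);
- true C applied as `beta_lt = -C * beta_cis` (scalar, uniform range,
  or per-gene array); `buffering=None` draws `beta_lt ~ N(0, 0.1)`
  independently of cis — the null of no coupling;
- gene dispersions log-normal, median 0.05, log-sd 0.5 (typical bulk
  RNA-seq);
- baseline expression log-normal, median 500 mean counts, log-sd 1.0,
  emulating deep bulk RNA-seq of the study's scale;
- size factors (1.0, 0.85, 1.15, 0.95); allele length ratios log-normal
  with log-sd 0.02; nuisance effects diploid 0.1, hybrid-B 0.05,
  spore-B −0.05; ribo layout RNA-bias 0.3, replicate 0.05;
- spore allele frequency 0.5, or per-gene logit-normal selection skew.

SNP tables are Poisson-spaced positions along chromosomes with a smooth
latent reference-allele frequency (logistic of a sum of Gaussian bumps,
emulating selection during spore growth), binomial counts at Poisson
depths, and an optional global mapping bias; the latent curve is
returned for recovery tests.

What the generator does not emulate — and hence what passing tests do
not show about real data: read-level artefacts (mapping bias beyond one
scalar, positional coverage, PCR duplicates), correlated expression
across genes, linkage between genes' allele frequencies and their
cis effects, and any relationship between gene category and buffering
(the stratified tests plant their own effects).

## Numerical choices

Per-gene kernels are numba-compiled (counts per gene are only eight
numbers; whole-cohort refits must run thousands of times inside the
calibration and bootstrap).  IRLS uses step-halving on likelihood
decrease, a 1e-10 ridge on the normal equations, and a linear-predictor
clip at ±40; below dispersion 1e-9 the Poisson limit of the likelihood
is used (beyond that the lgamma differences drown in roundoff).  The
dispersion search runs a 12-point coarse log-grid plus 18
golden-section iterations (agreement with a dense grid oracle to 1e-3);
inside the estimator the gene-wise pass preceding MAP shrinkage uses a
shorter refinement, and the MAP pass brackets the optimum between the
gene-wise value and the trend with a ±2 log-unit margin.  All
randomness flows through `numpy.random.Generator` seeded via
`SeedSequence(entropy=seed, spawn_key=...)`, so every stage is
bit-reproducible given its seed.

Problem sizes used by the test suite and the acceptance script —
chosen as desk-scale defaults of this package: 2,000-gene cohorts for
calibration/type-I experiments, an 11-point calibration grid, 300-gene
cohorts with B=99 for the bootstrap-null study (50 repetitions), and
the 101-point/B=1000 paper-scale presets left available behind
`PAPER_GRID` and `bootstrap_b`.
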