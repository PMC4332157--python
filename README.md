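# cisbuffer

Dissecting **cis** from **local-trans** regulation with allele-specific
RNA-seq of a yeast hybrid and its pool of spores, and quantifying how
much local trans regulation *buffers* cis-regulatory variation.

## The problem

A cis-regulatory variant acts only on the allele on its own chromosome,
so it produces an allelic expression imbalance both in an F1 hybrid and
in a bulk pool of the hybrid's spores.  A *local trans* effect — a
diffusible regulator or a feedback loop inherited together with its
target gene — acts on **both** alleles in the hybrid (one shared trans
environment) but co-segregates with the gene in the spores, where it
contributes to the allelic imbalance.  Comparing the two generations
separates the two effect classes.

Allele-specific counts are modelled per gene as

    K_ijk ~ NB(mu = s_j · f_ij · l_ij · q_ij,  alpha_i),
    log q_ij = x_j' beta_i

with size factor `s_j`, allele frequency `f_ij` (0.5 in the hybrid;
estimated from spore-pool genomic DNA, smoothed along the chromosome
and corrected for mapping bias), allele length `l_ij`, and the
published 8-row design matrices (spore/hybrid and RNA/ribosome-profiling
layouts).  The hybrid allelic log-ratio is `beta_cis`; the spore-pool
log-ratio is `beta_cis + beta_lt`.  The **buffering coefficient**

    C = 1 − (beta_cis + beta_lt) / beta_cis = −beta_lt / beta_cis

is 0 without buffering, 1 for complete compensation, negative when
local trans effects enhance the cis effect.  Its plug-in estimator is
biased by the selection of cis genes, so it is calibrated by
re-simulating genomewide counts from the fitted model over a grid of
true C and re-running the complete analysis; cohort significance comes
from a permutation bootstrap (local-trans effects permuted between
genes).

The package is for computational biologists who want to run this
dissection on allele-specific count tables, or to study the estimator
itself on synthetic data: the generator, the GLM, the calibration, the
bootstrap and the stratified analyses are all first-class, tested code.

## Worked example

```python
import numpy as np
import cisbuffer as cb

cfg   = cb.SimulationConfig(n_genes=1000, seed=7, buffering=0.2)
truth = cb.simulate_truth(cfg)                    # known ground truth
counts, sheet = cb.simulate_counts(truth)         # genes x 8 units
fl    = cb.offsets_from_truth(truth, sheet)       # log(f·l) offsets

res = cb.run_ase_pipeline(counts, sheet, fl_offsets=fl)
print(len(res.cis_genes))                         # 283

raw = cb.raw_buffering(res.fits).dropna()
print(np.median(raw))                             # 0.372

cal = cb.BufferingCalibrator(random_state=7).fit(res)
print(cal.slope_, cal.intercept_, cal.pearson_r_) # 0.736  0.2454  0.9716
print(np.median(cal.transform(raw)))              # 0.1721

boot = cb.bootstrap_significance(res, B=99, random_state=7)
print(boot.p_value)                               # 0.01
```

Reading the numbers: of 1,000 simulated genes, 283 are called cis genes
(>1.5-fold, FDR < 0.2).  Their median *raw* buffering coefficient,
0.372, is far above the injected truth of 0.2 — that is the selection
bias of the estimator.  The calibration grid finds the affine
relationship between injected and recovered medians (slope 0.736,
intercept 0.245, Pearson r 0.97 on this small cohort); inverting it
gives a calibrated cohort median of 0.172, close to the true 0.2.  The
bootstrap p of 0.01 (the floor at B=99) says a median this large never
arose when local-trans effects were shuffled between genes.

The same stages are available from a shell:

```sh
cisbuffer simulate --n-genes 1000 --buffering 0.2 --seed 7 --out-dir sim
cisbuffer fit --counts sim/counts.tsv --samples sim/samples.tsv \
          --offsets sim/offsets.tsv --out-dir fit
cisbuffer buffer --fits fit/fits.tsv --out buffering.tsv
cisbuffer calibrate --counts sim/counts.tsv --samples sim/samples.tsv \
          --offsets sim/offsets.tsv --seed 7 --out-dir calib
cisbuffer bootstrap --counts sim/counts.tsv --samples sim/samples.tsv \
          --offsets sim/offsets.tsv --bootstrap-b 99 --seed 7 --out-dir boot
```

Every command writes a JSON provenance record (config, seed, version,
input hashes) next to its outputs.

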