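"""Sample sheets and design matrices for the allele-specific NB GLM.

Two experimental layouts are supported:

``spore_hybrid``
    Hybrid diploid replicates plus bulk spore-pool replicates, two
    alleles each.  Covariates: a *cis* indicator (effect of the variant
    allele's own cis-regulation, visible wherever the variant allele is
    observed), a *local-trans* indicator (a diffusible effect of the
    linked locus: present on both alleles in the hybrid, where the two
    alleles share one trans environment, but only on the variant allele
    in the spore pool, where the local genotype co-segregates with the
    gene), a diploid indicator and one indicator per extra replicate of
    each generation.

``ribo``
    Hybrid RNA-seq plus ribosome-profiling fractions.  Covariates:
    RNA-level cis effect, translation-efficiency cis effect (visible
    only in the ribosome-bound fraction), an RNA-fraction bias term and
    one indicator per extra replicate.

Design rows are (sample, allele) units; entries are 0/1.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

SPORE_HYBRID = "spore_hybrid"
RIBO = "ribo"

#: default allele labels: the first carries the cis / local-trans effects
DEFAULT_ALLELES = {SPORE_HYBRID: ("SK1", "S96"), RIBO: ("SCER", "SPAR")}


def unit_name(sample: str, allele: str) -> str:
    return f"{sample}_{allele}"


def canonical_sample_sheet(dataset_kind: str = SPORE_HYBRID,
                           n_hybrid_reps: int = 2, n_spore_reps: int = 2,
                           alleles: tuple[str, str] | None = None) -> pd.DataFrame:
    """The study layout: replicated hybrids and spore pools (or RNA/RIBO
    fractions), two alleles each, one row per (sample, allele) unit."""
    if alleles is None:
        alleles = DEFAULT_ALLELES[dataset_kind]
    rows = []
    if dataset_kind == SPORE_HYBRID:
        reps = [chr(ord("A") + i) for i in range(max(n_hybrid_reps, n_spore_reps))]
        for gen, n in (("hybrid", n_hybrid_reps), ("spore", n_spore_reps)):
            for rep, allele in itertools.product(reps[:n], alleles):
                sample = f"{gen}{rep}"
                rows.append((unit_name(sample, allele), sample, gen, rep, allele))
        sheet = pd.DataFrame(
            rows, columns=["unit", "sample", "generation", "replicate", "allele"]
        ).set_index("unit")
    elif dataset_kind == RIBO:
        for frac, allele, rep in itertools.product(
                ("RNA", "RIBO"), alleles, range(1, n_hybrid_reps + 1)):
            sample = f"hybrid{frac}{rep}"
            rows.append((unit_name(sample, allele), sample, frac.lower(),
                         str(rep), allele))
        sheet = pd.DataFrame(
            rows, columns=["unit", "sample", "fraction", "replicate", "allele"]
        ).set_index("unit")
    else:
        raise ValueError(f"unknown dataset kind {dataset_kind!r}")
    sheet.attrs["dataset_kind"] = dataset_kind
    sheet.attrs["alt_allele"] = alleles[0]
    return sheet


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < X.shape[1]:
        # name a minimal aliased set by greedy elimination
        cols = list(X.columns)
        aliased = []
        for col in cols:
            rest = X.drop(columns=[col] + aliased).to_numpy(dtype=float)
            if np.linalg.matrix_rank(rest) == rank:
                aliased.append(col)
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}")


def build_design(sample_sheet: pd.DataFrame, dataset_kind: str | None = None,
                 alt_allele: str | None = None) -> pd.DataFrame:
    """Design matrix (one 0/1 row per unit, intercept included).

    For the canonical eight-unit layouts the result reproduces the
    published covariate tables row for row; extra replicates get one
    extra indicator column each.
    """
    if dataset_kind is None:
        dataset_kind = sample_sheet.attrs.get("dataset_kind", SPORE_HYBRID)
    if alt_allele is None:
        alt_allele = sample_sheet.attrs.get(
            "alt_allele", DEFAULT_ALLELES[dataset_kind][0])
    if alt_allele not in set(sample_sheet["allele"]):
        raise ValueError(f"alt allele {alt_allele!r} not found in sample sheet")

    alt = (sample_sheet["allele"] == alt_allele).astype(int)
    X = pd.DataFrame(index=sample_sheet.index)
    X["intercept"] = 1

    if dataset_kind == SPORE_HYBRID:
        required = {"generation", "replicate", "allele"}
        if not required.issubset(sample_sheet.columns):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        hybrid = (sample_sheet["generation"] == "hybrid").astype(int)
        spore = 1 - hybrid
        X["cis"] = alt
        # shared trans environment in the diploid; co-segregating in spores
        X["local_trans"] = (hybrid | (spore & alt)).astype(int)
        X["diploid"] = hybrid
        for gen in ("hybrid", "spore"):
            gen_mask = sample_sheet["generation"] == gen
            reps = sorted(sample_sheet.loc[gen_mask, "replicate"].unique())
            for rep in reps[1:]:
                X[f"{gen}_{rep.lower()}"] = (
                    gen_mask & (sample_sheet["replicate"] == rep)).astype(int)
    elif dataset_kind == RIBO:
        required = {"fraction", "replicate", "allele"}
        if not required.issubset(sample_sheet.columns):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        ribo = (sample_sheet["fraction"] == "ribo").astype(int)
        X["rna_cis"] = alt
        X["te_cis"] = (alt & ribo).astype(int)
        X["rna_bias"] = 1 - ribo
        reps = sorted(sample_sheet["replicate"].unique())
        for rep in reps[1:]:
            X[f"hybrid_rep{rep}"] = (sample_sheet["replicate"] == rep).astype(int)
    else:
        raise ValueError(f"unknown dataset kind {dataset_kind!r}")

    _check_rank(X)
    return X


#: coefficient tested for cis effects / local-trans effects, per layout
EFFECT_COLUMNS = {
    SPORE_HYBRID: {"cis": "cis", "trans": "local_trans"},
    RIBO: {"cis": "rna_cis", "trans": "te_cis"},
}
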