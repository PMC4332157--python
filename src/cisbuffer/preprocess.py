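"""Spore allele-frequency estimation and count offsets.

The spore pool is a bulk of haploid segregants, so each gene's two
alleles are not at 50/50: natural selection and the technical selection
for one mating type skew the local allele frequency.  The frequency is
estimated from genomic DNA SNP counts, smoothed along the chromosome by
local binomial likelihood (a tricube-weighted binomial MLE over a fixed
28 kb window, about 10 cM in yeast), corrected for the global mapping
bias toward the better-annotated reference genome, and averaged over the
SNPs of each gene to give the per-gene offset ``f``.

Also here: DESeq-style median-of-ratios size factors and the
minimum-expression filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_WINDOW_BP = 28_000


def _check_snp_table(snps: pd.DataFrame) -> None:
    required = {"chrom", "pos", "ref_count", "alt_count"}
    if not required.issubset(snps.columns):
        raise ValueError(f"SNP table must have columns {sorted(required)}")
    if (snps[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError("SNP counts must be non-negative")
    for chrom, sub in snps.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
            raise ValueError(
                f"SNP positions must be strictly increasing on {chrom}")


def smooth_allele_frequencies(snps: pd.DataFrame,
                              window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Local-binomial-likelihood smoothing of per-SNP allele frequencies.

    At each SNP position the smoothed frequency is the weighted binomial
    MLE ``sum(w * ref) / sum(w * depth)`` over SNPs within half a window
    on either side, with tricube weights in distance.  Zero-depth SNPs
    contribute nothing; a SNP whose whole window has zero depth gets
    ``NaN`` and ``ok=False``.

    Returns a frame with columns chrom, pos, depth, raw_freq,
    smoothed_freq, eff_depth, ok.  The smoothed frequency refers to the
    same allele as ``ref_count`` (the reference strain).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    _check_snp_table(snps)
    half = window_bp / 2.0
    out = []
    for chrom, sub in snps.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=float)
        ref = sub["ref_count"].to_numpy(dtype=float)
        depth = ref + sub["alt_count"].to_numpy(dtype=float)
        m = pos.size
        smoothed = np.empty(m)
        eff = np.empty(m)
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        for i in range(m):
            sl = slice(lo[i], hi[i])
            d = np.abs(pos[sl] - pos[i]) / half
            w = (1.0 - np.minimum(d, 1.0) ** 3) ** 3
            trials = np.sum(w * depth[sl])
            eff[i] = trials
            smoothed[i] = np.sum(w * ref[sl]) / trials if trials > 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(depth > 0, ref / np.maximum(depth, 1.0), np.nan)
        out.append(pd.DataFrame({
            "chrom": chrom, "pos": sub["pos"].to_numpy(),
            "depth": depth.astype(int), "raw_freq": raw,
            "smoothed_freq": smoothed, "eff_depth": eff,
            "ok": np.isfinite(smoothed),
        }))
    res = pd.concat(out, ignore_index=True)
    res.attrs["window_bp"] = window_bp
    return res


def logit_shift(p, bias: float):
    """``logit(out) = logit(p) - logit(bias) + logit(0.5)``, elementwise."""
    p = np.asarray(p, dtype=float)
    z = np.log(p / (1.0 - p)) - np.log(bias / (1.0 - bias))
    return 1.0 / (1.0 + np.exp(-z))


def correct_mapping_bias(freqs: pd.DataFrame, hybrid_bias: float) -> pd.DataFrame:
    """Remove a global mapping bias toward the reference genome.

    ``hybrid_bias`` is the frequency the reference allele attains in a
    sample known to be balanced (e.g. the median reference-allele
    frequency in the hybrid).  The correction is a logit-scale shift, so
    corrected values stay in (0, 1) and the transform is exactly
    invertible; a bias of 0.5 is the identity.
    """
    if not 0.0 < hybrid_bias < 1.0:
        raise ValueError("hybrid_bias must be strictly inside (0, 1)")
    out = freqs.copy()
    for col in ("raw_freq", "smoothed_freq"):
        if col in out.columns:
            out[col] = logit_shift(out[col], hybrid_bias)
    out.attrs = dict(freqs.attrs)
    out.attrs["mapping_bias_corrected"] = hybrid_bias
    return out


def gene_allele_frequency(freqs: pd.DataFrame, genes: pd.DataFrame,
                          max_gap_bp: int = DEFAULT_WINDOW_BP,
                          default: float = 0.5) -> pd.DataFrame:
    """Per-gene allele frequency from smoothed SNP frequencies.

    ``genes`` needs columns chrom, start, end (1-based, closed).  The
    gene value is the mean smoothed frequency over SNPs inside the
    interval; genes without SNP coverage take the nearest smoothed SNP
    within ``max_gap_bp``, else ``default`` (flagged in ``source``).
    """
    required = {"chrom", "start", "end"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    usable = freqs[freqs["ok"]] if "ok" in freqs.columns else freqs
    by_chrom = {c: sub.sort_values("pos") for c, sub in usable.groupby("chrom")}
    vals = np.empty(len(genes))
    source = np.empty(len(genes), dtype=object)
    for i, (_, row) in enumerate(genes.iterrows()):
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            vals[i], source[i] = default, "default"
            continue
        pos = sub["pos"].to_numpy()
        sm = sub["smoothed_freq"].to_numpy()
        lo = np.searchsorted(pos, row["start"], side="left")
        hi = np.searchsorted(pos, row["end"], side="right")
        if hi > lo:
            vals[i], source[i] = float(np.mean(sm[lo:hi])), "snps"
            continue
        mid = 0.5 * (row["start"] + row["end"])
        j = np.clip(np.searchsorted(pos, mid), 1, pos.size - 1)
        j = j if abs(pos[j] - mid) < abs(pos[j - 1] - mid) else j - 1
        if abs(pos[j] - mid) <= max_gap_bp:
            vals[i], source[i] = float(sm[j]), "nearest"
        else:
            vals[i], source[i] = default, "default"
    out = genes.copy()
    out["freq"] = vals
    out["source"] = source
    return out


def build_offset_table(sample_sheet: pd.DataFrame,
                       spore_freq: pd.Series | float = 0.5,
                       length_ratio: pd.Series | float = 1.0,
                       size_factors: pd.Series | None = None,
                       alt_allele: str | None = None) -> pd.DataFrame:
    """Per gene x unit log offsets ``log(f * l)`` (+ ``log s`` if given).

    ``spore_freq`` is the variant-allele frequency per gene in the spore
    pool (the hybrid is 0.5 exactly); ``length_ratio`` the variant/
    reference allele length ratio per gene.  Scalars broadcast.
    """
    from .design import DEFAULT_ALLELES, SPORE_HYBRID

    kind = sample_sheet.attrs.get("dataset_kind", SPORE_HYBRID)
    if alt_allele is None:
        alt_allele = sample_sheet.attrs.get("alt_allele",
                                            DEFAULT_ALLELES[kind][0])
    f_alt = np.asarray(pd.Series(spore_freq), dtype=float).reshape(-1, 1)
    l_alt = np.asarray(pd.Series(length_ratio), dtype=float).reshape(-1, 1)
    n_genes = max(f_alt.shape[0], l_alt.shape[0])
    if (np.any(f_alt <= 0) or np.any(f_alt >= 1) or np.any(l_alt <= 0)):
        raise ValueError("frequencies must be in (0,1) and lengths positive")
    is_alt = (sample_sheet["allele"] == alt_allele).to_numpy()
    if "generation" in sample_sheet.columns:
        is_spore = (sample_sheet["generation"] == "spore").to_numpy()
    else:  # ribo layout: all hybrid, balanced alleles
        is_spore = np.zeros(len(sample_sheet), dtype=bool)
    f = np.where(is_spore, np.where(is_alt, f_alt, 1.0 - f_alt), 0.5)
    f = np.broadcast_to(f, (n_genes, len(sample_sheet)))
    l = np.broadcast_to(np.where(is_alt, l_alt, 1.0),
                        (n_genes, len(sample_sheet)))
    off = np.log(f) + np.log(l)
    if size_factors is not None:
        s = pd.Series(size_factors).reindex(sample_sheet.index)
        if s.isna().any():
            raise ValueError("size factors missing for some units")
        off = off + np.log(s.to_numpy())
    index = (spore_freq.index if isinstance(spore_freq, pd.Series)
             else length_ratio.index if isinstance(length_ratio, pd.Series)
             else pd.RangeIndex(n_genes))
    return pd.DataFrame(off, index=index, columns=sample_sheet.index)


# ---------------------------------------------------------------------------
# Size factors and expression filter


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per count column.

    Over genes with all-positive counts, each column's factor is the
    median ratio of the count to the gene's geometric mean across
    columns; factors are rescaled so their geometric mean is 1.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "size factors need at least one gene with all-positive counts")
    logs = np.log(mat[positive])
    log_gm = logs.mean(axis=1, keepdims=True)
    log_s = np.median(logs - log_gm, axis=0)
    log_s -= log_s.mean()  # geometric mean of the factors is 1
    return pd.Series(np.exp(log_s), index=counts.columns, name="size_factor")


class SizeFactorNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer dividing counts by median-of-ratios
    size factors learned in :meth:`fit`."""

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.size_factors_ = estimate_size_factors(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from fit")
        return X / self.size_factors_.to_numpy()


@dataclass
class FilterReport:
    kept: int
    removed: int
    threshold: float


def filter_min_expression(counts: pd.DataFrame, threshold_mean: float = 10.0):
    """Keep genes whose mean count over all sample/allele units is at
    least ``threshold_mean`` (low counts carry too little information
    for the per-gene GLM).  Returns ``(filtered, FilterReport)``."""
    mean = counts.mean(axis=1)
    keep = mean >= threshold_mean
    report = FilterReport(kept=int(keep.sum()), removed=int((~keep).sum()),
                          threshold=float(threshold_mean))
    return counts.loc[keep], report
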