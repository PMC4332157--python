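"""Frequency smoothing, bias correction, offsets, size factors, filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cisbuffer import (SnpSimConfig, build_offset_table, correct_mapping_bias,
                       estimate_size_factors, filter_min_expression,
                       gene_allele_frequency, simulate_snp_counts,
                       smooth_allele_frequencies)
from cisbuffer.preprocess import SizeFactorNormalizer, logit_shift


def snp_frame(pos, ref, alt, chrom="chrI"):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ref_count": ref,
                         "alt_count": alt})


# -- smoothing --------------------------------------------------------------


def test_balanced_snps_smooth_to_half():
    snps = snp_frame(np.arange(1, 20001, 500), 50, 50)
    sm = smooth_allele_frequencies(snps)
    np.testing.assert_allclose(sm["smoothed_freq"], 0.5)


def test_isolated_snp_equals_raw_mle():
    snps = snp_frame([100, 500_000], [30, 10], [10, 30])
    sm = smooth_allele_frequencies(snps)
    np.testing.assert_allclose(sm["smoothed_freq"], [0.75, 0.25])


def test_smoother_matches_bruteforce_enumeration():
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(np.arange(1, 100_000), 200, replace=False))
    depth = rng.poisson(40, 200)
    ref = rng.binomial(depth, 0.6)
    snps = snp_frame(pos, ref, depth - ref)
    window = 28_000
    sm = smooth_allele_frequencies(snps, window)
    half = window / 2
    for i in rng.choice(200, 25, replace=False):
        d = np.abs(pos - pos[i]) / half
        w = np.where(d < 1, (1 - d**3) ** 3, 0.0)
        expected = np.sum(w * ref) / np.sum(w * depth)
        assert abs(sm["smoothed_freq"].iloc[i] - expected) < 1e-12


def test_smoothing_is_shift_equivariant():
    rng = np.random.default_rng(1)
    pos = np.sort(rng.choice(np.arange(1, 60_000), 80, replace=False))
    depth = rng.poisson(30, 80)
    ref = rng.binomial(depth, 0.5)
    a = smooth_allele_frequencies(snp_frame(pos, ref, depth - ref))
    b = smooth_allele_frequencies(snp_frame(pos + 7919, ref, depth - ref))
    np.testing.assert_allclose(a["smoothed_freq"], b["smoothed_freq"])


def test_zero_depth_snp_is_flagged_not_dropped():
    snps = snp_frame([100, 1_000_000], [0, 20], [0, 20])
    sm = smooth_allele_frequencies(snps)
    assert len(sm) == 2
    assert not sm["ok"].iloc[0] and np.isnan(sm["smoothed_freq"].iloc[0])
    assert sm["ok"].iloc[1]


def test_zero_depth_neighbours_carry_no_weight():
    snps = snp_frame([100, 200, 300], [0, 40, 0], [0, 10, 0])
    sm = smooth_allele_frequencies(snps)
    np.testing.assert_allclose(sm["smoothed_freq"], 0.8)


def test_unsorted_or_invalid_snps_rejected():
    with pytest.raises(ValueError, match="strictly increasing"):
        smooth_allele_frequencies(snp_frame([10, 5], [1, 1], [1, 1]))
    with pytest.raises(ValueError):
        smooth_allele_frequencies(snp_frame([10], [-1], [1]))
    with pytest.raises(ValueError):
        smooth_allele_frequencies(snp_frame([10], [1], [1]), window_bp=0)


def test_smoothing_recovers_latent_better_than_raw():
    snps, latent = simulate_snp_counts(SnpSimConfig(seed=3, mean_depth=40.0))
    sm = smooth_allele_frequencies(snps)
    m = sm.merge(latent, on=["chrom", "pos"]).dropna(subset=["raw_freq"])
    mae_raw = (m["raw_freq"] - m["latent_freq"]).abs().mean()
    mae_sm = (m["smoothed_freq"] - m["latent_freq"]).abs().mean()
    assert mae_sm < mae_raw


# -- mapping bias -----------------------------------------------------------


def test_bias_half_is_identity():
    snps = snp_frame([100, 200], [30, 10], [10, 30])
    sm = smooth_allele_frequencies(snps)
    out = correct_mapping_bias(sm, 0.5)
    np.testing.assert_allclose(out["smoothed_freq"], sm["smoothed_freq"])


def test_observed_bias_maps_to_balance():
    # a frequency equal to the hybrid's median bias is, by definition,
    # balanced after correction
    assert abs(logit_shift(0.52, 0.52) - 0.5) < 1e-14


def test_correction_round_trip_is_exact():
    rng = np.random.default_rng(2)
    p = rng.uniform(0.05, 0.95, 100)
    corrected = logit_shift(p, 0.52)
    # the inverse shift swaps the roles of bias and balance
    back = logit_shift(corrected, 1 - 0.52)
    np.testing.assert_allclose(back, p, atol=1e-12)


def test_correction_preserves_ordering():
    p = np.linspace(0.05, 0.95, 50)
    assert np.all(np.diff(logit_shift(p, 0.63)) > 0)


@pytest.mark.parametrize("bias", [0.0, 1.0, -0.1])
def test_degenerate_bias_rejected(bias):
    snps = snp_frame([100], [10], [10])
    with pytest.raises(ValueError):
        correct_mapping_bias(smooth_allele_frequencies(snps), bias)


# -- gene-level frequency ---------------------------------------------------


def _freq_frame(pos, freq, chrom="chrI"):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "smoothed_freq": freq,
                         "ok": True})


def test_gene_frequency_constant_track():
    freqs = _freq_frame(np.arange(100, 5000, 100), 0.42)
    genes = pd.DataFrame({"chrom": ["chrI"], "start": [500], "end": [900]})
    out = gene_allele_frequency(freqs, genes)
    assert out["freq"].iloc[0] == pytest.approx(0.42)
    assert out["source"].iloc[0] == "snps"


def test_gene_frequency_matches_enumeration():
    rng = np.random.default_rng(3)
    pos = np.sort(rng.choice(np.arange(1, 50_000), 120, replace=False))
    f = rng.uniform(0.2, 0.8, 120)
    freqs = _freq_frame(pos, f)
    start, end = 10_000, 20_000
    genes = pd.DataFrame({"chrom": ["chrI"], "start": [start], "end": [end]})
    out = gene_allele_frequency(freqs, genes)
    inside = (pos >= start) & (pos <= end)  # 1-based closed interval
    assert out["freq"].iloc[0] == pytest.approx(f[inside].mean())


def test_gene_without_snps_falls_back():
    freqs = _freq_frame([1000], 0.3)
    genes = pd.DataFrame({"chrom": ["chrI", "chrI"],
                          "start": [5000, 500_000],
                          "end": [6000, 501_000]})
    out = gene_allele_frequency(freqs, genes)
    assert out["source"].tolist() == ["nearest", "default"]
    assert out["freq"].tolist() == [0.3, 0.5]


# -- size factors -----------------------------------------------------------


def test_identical_columns_give_unit_factors():
    rng = np.random.default_rng(4)
    col = rng.poisson(50, 40)
    counts = pd.DataFrame({f"u{j}": col for j in range(6)})
    np.testing.assert_allclose(estimate_size_factors(counts), 1.0)


def test_doubled_column_against_bruteforce():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(rng.poisson(100, (60, 4)) + 1,
                          columns=list("abcd"))
    counts["d"] = counts["d"] * 2
    s = estimate_size_factors(counts)
    # brute-force median-of-ratios with geometric-mean normalisation
    mat = counts.to_numpy(float)
    logs = np.log(mat)
    ratios = logs - logs.mean(axis=1, keepdims=True)
    expected = np.median(ratios, axis=0)
    expected = np.exp(expected - expected.mean())
    np.testing.assert_allclose(s.to_numpy(), expected, rtol=1e-12)
    assert s["d"] > s[["a", "b", "c"]].max()


def test_size_factors_scale_and_order_invariance():
    rng = np.random.default_rng(6)
    counts = pd.DataFrame(rng.poisson(80, (50, 8)) + 1)
    s1 = estimate_size_factors(counts)
    np.testing.assert_allclose(estimate_size_factors(counts * 3), s1,
                               rtol=1e-12)
    shuffled = counts.sample(frac=1.0, random_state=0)
    np.testing.assert_allclose(estimate_size_factors(shuffled), s1,
                               rtol=1e-12)
    with_zeros = pd.concat([counts, counts.iloc[:3] * 0])
    np.testing.assert_allclose(estimate_size_factors(with_zeros), s1,
                               rtol=1e-12)


def test_size_factors_need_positive_gene():
    counts = pd.DataFrame([[0, 1], [1, 0]])
    with pytest.raises(ValueError):
        estimate_size_factors(counts)


def test_normalizer_transformer_roundtrip():
    from sklearn.base import clone
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(rng.poisson(60, (40, 4)) + 1)
    norm = SizeFactorNormalizer().fit(counts)
    clone(norm)  # sklearn-compatible params
    out = norm.transform(counts)
    np.testing.assert_allclose(
        out.to_numpy(),
        counts.to_numpy() / norm.size_factors_.to_numpy())


# -- minimum-expression filter ----------------------------------------------


def test_filter_boundary_and_report():
    counts = pd.DataFrame({"a": [10, 9, 100], "b": [10, 10.98, 1]},
                          index=["keep_exact", "drop", "keep"])
    kept, report = filter_min_expression(counts, 10.0)
    assert list(kept.index) == ["keep_exact", "keep"]
    assert (report.kept, report.removed) == (2, 1)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_filter_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(rng.poisson(12, (30, 8)))
    kept, _ = filter_min_expression(counts, 10.0)
    expected = counts[counts.to_numpy().mean(axis=1) >= 10.0]
    pd.testing.assert_frame_equal(kept, expected)


# -- offset table -----------------------------------------------------------


def test_offset_table_hybrid_is_exactly_half(sheet):
    f = pd.Series([0.6, 0.4], index=["g1", "g2"])
    off = build_offset_table(sheet, spore_freq=f, length_ratio=1.0)
    hybrid_cols = [u for u in sheet.index if u.startswith("hybrid")]
    np.testing.assert_allclose(off[hybrid_cols], np.log(0.5))
    assert off.loc["g1", "sporeA_SK1"] == pytest.approx(np.log(0.6))
    assert off.loc["g1", "sporeA_S96"] == pytest.approx(np.log(0.4))


def test_offset_table_rejects_bad_inputs(sheet):
    with pytest.raises(ValueError):
        build_offset_table(sheet, spore_freq=1.5)
    with pytest.raises(ValueError):
        build_offset_table(sheet, length_ratio=-1.0)
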