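"""Stratified analyses: terciles, proportions, rank tests, resampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

from cisbuffer import (assign_terciles, build_annotation,
                       cis_proportion_by_category, compare_buffering,
                       matched_resample, median_above_zero)


def test_terciles_of_one_to_nine():
    t = assign_terciles(pd.Series(range(1, 10)))
    assert t.tolist() == ["Low"] * 3 + ["Middle"] * 3 + ["High"] * 3


def test_equal_levels_fill_by_stable_order():
    with pytest.warns(UserWarning, match="equal"):
        t = assign_terciles(pd.Series([5.0] * 6, index=list("abcdef")))
    assert t.loc[list("ab")].tolist() == ["Low", "Low"]
    assert t.loc[list("ef")].tolist() == ["High", "High"]


@settings(max_examples=30, deadline=None)
@given(st.integers(3, 400), st.integers(0, 2**31 - 1))
def test_tercile_sizes_within_one(n, seed):
    rng = np.random.default_rng(seed)
    t = assign_terciles(pd.Series(rng.normal(size=n)))
    sizes = t.value_counts()
    assert sizes.max() - sizes.min() <= 1
    assert sizes.sum() == n


def test_annotation_expression_level_definition():
    ann = build_annotation(
        category=pd.Series(["essential", "non-essential", "ncRNA"],
                           index=list("abc")),
        mean_counts=pd.Series([100.0, 600.0, 30.0], index=list("abc")),
        mean_length=pd.Series([1000.0, 2000.0, 300.0], index=list("abc")))
    np.testing.assert_allclose(ann["expression_level"], [0.1, 0.3, 0.1])
    assert set(ann["tercile"].cat.categories) == {"Low", "Middle", "High"}


def fisher_oracle(k, n, k_out, n_out):
    """Two-sided Fisher p by hypergeometric point-probability enumeration."""
    total_pos = k + k_out
    total = n + n_out
    rv = stats.hypergeom(total, total_pos, n)
    p_obs = rv.pmf(k)
    support = np.arange(max(0, total_pos - n_out), min(n, total_pos) + 1)
    return float(rv.pmf(support)[rv.pmf(support) <= p_obs * (1 + 1e-9)].sum())


def test_fisher_matches_hypergeometric_enumeration():
    rng = np.random.default_rng(0)
    cases = [(10, 100, 20, 100)]
    for _ in range(40):
        n, n_out = rng.integers(2, 21, 2)
        k, k_out = rng.integers(0, n + 1), rng.integers(0, n_out + 1)
        cases.append((int(k), int(n), int(k_out), int(n_out)))
    for k, n, k_out, n_out in cases:
        genes = [f"g{i}" for i in range(n + n_out)]
        ann = pd.DataFrame({"category": ["A"] * n + ["B"] * n_out},
                           index=genes)
        called = pd.Series([True] * k + [False] * (n - k)
                           + [True] * k_out + [False] * (n_out - k_out),
                           index=genes)
        got = cis_proportion_by_category(called, ann).loc["A", "fisher_p"]
        assert got == pytest.approx(fisher_oracle(k, n, k_out, n_out),
                                    abs=1e-9)


def test_identical_category_and_complement_gives_p_one():
    genes = [f"g{i}" for i in range(40)]
    ann = pd.DataFrame({"category": ["A", "B"] * 20}, index=genes)
    called = pd.Series([True, True, False, False] * 10, index=genes)
    out = cis_proportion_by_category(called, ann)
    assert out.loc["A", "fisher_p"] == pytest.approx(1.0)


def test_zero_cis_category_ci_starts_at_zero():
    genes = [f"g{i}" for i in range(30)]
    ann = pd.DataFrame({"category": ["A"] * 10 + ["B"] * 20}, index=genes)
    called = pd.Series([False] * 10 + [True] * 10 + [False] * 10, index=genes)
    out = cis_proportion_by_category(called, ann)
    assert out.loc["A", "proportion"] == 0.0
    assert out.loc["A", "ci_low"] == 0.0
    assert 0 < out.loc["A", "ci_high"] < 1


def test_clopper_pearson_against_beta_quantiles():
    from cisbuffer.stratify import _clopper_pearson
    lo, hi = _clopper_pearson(3, 10)
    assert lo == pytest.approx(stats.beta.ppf(0.025, 3, 8))
    assert hi == pytest.approx(stats.beta.ppf(0.975, 4, 7))


def test_identical_groups_rank_test_near_one():
    c = pd.Series(np.arange(20, dtype=float) / 20)
    groups = pd.Series(["x"] * 10 + ["y"] * 10, index=c.index)
    c[10:] = c[:10].to_numpy()  # identical samples
    out = compare_buffering(c, groups, "x", "y", alternative="two-sided")
    assert out["p_value"] > 0.9


def test_shifted_group_detected():
    rng = np.random.default_rng(1)
    c = pd.Series(np.concatenate([rng.normal(0, 1, 50),
                                  rng.normal(1, 1, 50)]))
    groups = pd.Series(["lo"] * 50 + ["hi"] * 50, index=c.index)
    out = compare_buffering(c, groups, "hi", "lo", alternative="greater")
    assert out["p_value"] < 1e-6


def test_small_rank_sum_matches_exact_enumeration():
    """n=4 vs 4: p equals the exact permutation tail of the rank sum."""
    a = np.array([0.9, 0.7, 0.6, 0.45])
    b = np.array([0.5, 0.3, 0.2, 0.1])
    c = pd.Series(np.concatenate([a, b]))
    groups = pd.Series(["a"] * 4 + ["b"] * 4, index=c.index)
    out = compare_buffering(c, groups, "a", "b", alternative="greater")
    assert out["method"] == "exact"
    ranks = stats.rankdata(np.concatenate([a, b]))
    obs = ranks[:4].sum()
    tail = 0
    combos = list(itertools.combinations(range(8), 4))
    for idx in combos:
        if ranks[list(idx)].sum() >= obs:
            tail += 1
    assert out["p_value"] == pytest.approx(tail / len(combos))


def test_cohort_median_above_zero():
    rng = np.random.default_rng(2)
    out = median_above_zero(pd.Series(rng.normal(0.15, 0.3, 200)))
    assert out["p_value"] < 1e-6
    null = median_above_zero(pd.Series(rng.normal(0.0, 0.3, 200)))
    assert null["p_value"] > 0.01


def test_planted_stratified_ordering_recovered():
    """With true C higher for essential genes, the one-sided rank test
    finds the ordering with power > 0.8 at 300 cis genes."""
    hits = 0
    for rep in range(25):
        rng = np.random.default_rng(100 + rep)
        n = 300
        cat = pd.Series(rng.choice(["essential", "non-essential"], n,
                                   p=[0.4, 0.6]))
        c = pd.Series(rng.normal(0.1, 0.35, n))
        c[cat == "essential"] += 0.15
        out = compare_buffering(c, cat, "essential", "non-essential",
                                alternative="greater")
        hits += out["p_value"] < 0.05
    assert hits / 25 > 0.8


def test_matched_resample_own_distribution_recovers_median():
    rng = np.random.default_rng(3)
    n = 300
    c = pd.Series(rng.normal(0.2, 0.3, n),
                  index=[f"g{i}" for i in range(n)])
    ann = pd.DataFrame({
        "category": "non-essential",
        "tercile": assign_terciles(pd.Series(rng.uniform(size=n),
                                             index=c.index)),
    }, index=c.index)
    target = ann["tercile"].value_counts().to_dict()
    meds, summary = matched_resample(c, ann, target, n_draws=400,
                                     random_state=4)
    assert abs(summary["median_of_medians"] - c.median()) < 0.05


def test_matched_resample_single_tercile_only_uses_it():
    rng = np.random.default_rng(5)
    idx = [f"g{i}" for i in range(90)]
    c = pd.Series(np.concatenate([np.zeros(30), np.ones(30),
                                  np.full(30, 2.0)]), index=idx)
    ann = pd.DataFrame({"category": "non-essential",
                        "tercile": ["Low"] * 30 + ["Middle"] * 30
                        + ["High"] * 30}, index=idx)
    meds, _ = matched_resample(c, ann, {"High": 10}, n_draws=50,
                               random_state=6)
    np.testing.assert_allclose(meds, 2.0)


def test_matched_resample_reproducible():
    rng = np.random.default_rng(7)
    idx = [f"g{i}" for i in range(60)]
    c = pd.Series(rng.normal(size=60), index=idx)
    ann = pd.DataFrame({"category": "non-essential",
                        "tercile": assign_terciles(pd.Series(
                            rng.uniform(size=60), index=idx))}, index=idx)
    m1, _ = matched_resample(c, ann, {"Low": 5, "High": 5}, 20, 8)
    m2, _ = matched_resample(c, ann, {"Low": 5, "High": 5}, 20, 8)
    np.testing.assert_array_equal(m1, m2)
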