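"""Gene-category and expression-stratified analyses.

Genes are annotated with a category (ncRNA / non-essential / essential)
and an expression level — mean read count divided by mean gene length
over both strains — cut into three equally sized terciles (Low, Middle,
High).  On top of this: per-category cis-gene proportions with exact
binomial confidence intervals and Fisher tests, rank-sum comparisons of
the buffering coefficient between gene groups, and matched resampling
to compare the buffering cohort against an external dataset with a
different category/expression make-up.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

TERCILES = ("Low", "Middle", "High")
CATEGORIES = ("ncRNA", "non-essential", "essential")


def expression_level(mean_counts, mean_length) -> pd.Series:
    """Expression level = average read count / mean gene length (bp)."""
    level = pd.Series(mean_counts, dtype=float) / pd.Series(mean_length,
                                                            dtype=float)
    level.name = "expression_level"
    return level


def assign_terciles(levels: pd.Series) -> pd.Series:
    """Sort and cut into three equally sized groups (sizes within one of
    each other); ties are broken by stable input order."""
    levels = pd.Series(levels)
    n = len(levels)
    if n == 0:
        return pd.Series(dtype=object)
    if levels.nunique() == 1:
        warnings.warn("all expression levels equal; terciles filled by "
                      "input order")
    order = np.argsort(levels.to_numpy(), kind="stable")
    labels = np.empty(n, dtype=object)
    bounds = [round(n / 3), round(2 * n / 3)]
    labels[order[: bounds[0]]] = TERCILES[0]
    labels[order[bounds[0]: bounds[1]]] = TERCILES[1]
    labels[order[bounds[1]:]] = TERCILES[2]
    return pd.Series(pd.Categorical(labels, categories=list(TERCILES),
                                    ordered=True),
                     index=levels.index, name="tercile")


def build_annotation(category: pd.Series, mean_counts: pd.Series,
                     mean_length: pd.Series) -> pd.DataFrame:
    """Gene annotation table: category, mean length, expression level
    and expression tercile."""
    ann = pd.DataFrame({
        "category": category,
        "mean_length": pd.Series(mean_length, dtype=float),
    })
    ann["expression_level"] = expression_level(mean_counts, mean_length)
    ann["tercile"] = assign_terciles(ann["expression_level"])
    return ann


def cis_proportion_by_category(called: pd.Series,
                               annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-category proportion of called cis genes, exact
    (Clopper-Pearson) 95% CI, and two-sided Fisher exact p versus all
    other genes pooled."""
    called = called.astype(bool)
    cats = annotation["category"]
    common = called.index.intersection(cats.index)
    called, cats = called.loc[common], cats.loc[common]
    rows = []
    for cat in pd.unique(cats):
        in_cat = cats == cat
        k = int(called[in_cat].sum())
        n = int(in_cat.sum())
        k_out = int(called[~in_cat].sum())
        n_out = int((~in_cat).sum())
        lo, hi = _clopper_pearson(k, n)
        _, p = stats.fisher_exact([[k, n - k], [k_out, n_out - k_out]],
                                  alternative="two-sided")
        rows.append({"category": cat, "n_genes": n, "n_cis": k,
                     "proportion": k / n if n else np.nan,
                     "ci_low": lo, "ci_high": hi, "fisher_p": p})
    return pd.DataFrame(rows).set_index("category")


def _clopper_pearson(k: int, n: int, conf: float = 0.95):
    if n == 0:
        return np.nan, np.nan
    a = 1.0 - conf
    lo = stats.beta.ppf(a / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def compare_buffering(c_values: pd.Series, groups: pd.Series,
                      group_a: str, group_b: str,
                      alternative: str = "greater") -> dict:
    """Rank-sum (Mann-Whitney) test of the buffering coefficient between
    two gene groups.

    ``alternative='greater'`` tests whether group_a's C values are
    stochastically larger than group_b's.  Exact enumeration for small
    tie-free samples, normal approximation with tie correction
    otherwise (scipy's switch).
    """
    c_values = pd.Series(c_values).dropna()
    groups = pd.Series(groups).reindex(c_values.index)
    a = c_values[groups == group_a].to_numpy()
    b = c_values[groups == group_b].to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one C value")
    tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 50 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_a": int(a.size), "n_b": int(b.size), "method": method,
            "median_a": float(np.median(a)), "median_b": float(np.median(b))}


def median_above_zero(c_values: pd.Series) -> dict:
    """One-sided signed-rank test that the cohort median C exceeds zero."""
    c = pd.Series(c_values).dropna().to_numpy()
    if c.size == 0:
        raise ValueError("no C values")
    res = stats.wilcoxon(c, alternative="greater")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n": int(c.size), "median": float(np.median(c))}


def matched_resample(c_values: pd.Series, annotation: pd.DataFrame,
                     target_counts: dict, n_draws: int = 1000,
                     random_state: int = 0, category: str | None = None):
    """Resample medians under a matched expression-tercile make-up.

    Restricts to ``category`` (if given), then draws, with replacement,
    exactly ``target_counts[tercile]`` genes from each tercile,
    ``n_draws`` times; returns ``(medians, summary)`` where medians is
    the array of per-draw medians of C.
    """
    c_values = pd.Series(c_values).dropna()
    ann = annotation.loc[annotation.index.intersection(c_values.index)]
    if category is not None:
        ann = ann[ann["category"] == category]
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=random_state, spawn_key=(301,)))
    pools = {}
    for terc, want in target_counts.items():
        pool = c_values.loc[ann.index[ann["tercile"] == terc]].to_numpy()
        if want > 0 and pool.size == 0:
            raise ValueError(f"no genes available in tercile {terc!r}")
        pools[terc] = (pool, int(want))
    medians = np.empty(n_draws)
    for i in range(n_draws):
        draw = np.concatenate([
            rng.choice(pool, size=want, replace=True)
            for pool, want in pools.values() if want > 0])
        medians[i] = np.median(draw)
    summary = {"median_of_medians": float(np.median(medians)),
               "mean": float(medians.mean()), "sd": float(medians.std(ddof=1)),
               "n_per_draw": int(sum(w for _, w in pools.values()))}
    return medians, summary
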