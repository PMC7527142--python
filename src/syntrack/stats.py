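"""Relationship-category statistics for pairwise strain-similarity values.

Every unordered sample pair falls into one of three categories —
intraindividual (same person, different timepoints), same family
(co-twins), unrelated (different families). Because pairs sharing a sample
are not independent, category differences are tested with subsampled
bootstrapped Wilcoxon rank-sum tests: per replicate the larger category is
subsampled without replacement to the smaller category's size and the mean
p-value over replicates is reported (the median is recorded too).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CATEGORIES = ("intraindividual", "same_family", "unrelated")


# ---------------------------------------------------------------------------
# Pair categorization


def categorize_pairs(metadata: pd.DataFrame) -> pd.DataFrame:
    """Category (and shared-genotype stratum) of every unordered sample pair.

    Returns a frame with sample_a, sample_b, category, genotype (the common
    genotype, or 'mixed' when the pair spans genotypes). The three
    categories partition all C(S, 2) pairs.
    """
    _check_metadata(metadata)
    info = metadata.set_index("sample_id")[["individual_id", "family_id", "genotype"]]
    samples = sorted(metadata["sample_id"])
    rows = []
    for sa, sb in itertools.combinations(samples, 2):
        ia, ib = info.loc[sa], info.loc[sb]
        if ia["individual_id"] == ib["individual_id"]:
            cat = "intraindividual"
        elif ia["family_id"] == ib["family_id"]:
            cat = "same_family"
        else:
            cat = "unrelated"
        gt = ia["genotype"] if ia["genotype"] == ib["genotype"] else "mixed"
        rows.append({"sample_a": sa, "sample_b": sb, "category": cat, "genotype": gt})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "category", "genotype"])


def _check_metadata(metadata: pd.DataFrame) -> None:
    if metadata["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    per_ind = metadata.groupby("individual_id")[["family_id", "genotype"]].nunique()
    bad = per_ind[(per_ind > 1).any(axis=1)]
    if len(bad):
        raise ValueError(f"individual(s) with inconsistent family/genotype: {list(bad.index)}")


def annotate_pairs(values: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Attach category/genotype columns to a (sample_a, sample_b, value) table."""
    known = set(metadata["sample_id"])
    for col in ("sample_a", "sample_b"):
        missing = set(values[col]) - known
        if missing:
            raise ValueError(f"sample(s) absent from metadata: {sorted(missing)}")
    cats = categorize_pairs(metadata)
    key = lambda df: df.apply(
        lambda r: tuple(sorted((r["sample_a"], r["sample_b"]))), axis=1
    )
    cats = cats.assign(_key=key(cats)).set_index("_key")[["category", "genotype"]]
    out = values.copy()
    out["_key"] = key(out)
    out = out.join(cats, on="_key").drop(columns="_key")
    return out


# ---------------------------------------------------------------------------
# Rank-sum machinery


def mann_whitney(values_a, values_b) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    Exact by full enumeration for small tie-free samples (total <= 12),
    otherwise the normal approximation with tie and continuity correction.
    Two identical samples give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 12 and not has_ties:
        return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def _rowwise_asymptotic_p(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided tie-corrected normal-approximation p per row of (A | B)."""
    n_a, n_b = A.shape[1], B.shape[1]
    data = np.concatenate([A, B], axis=1)
    ranks = sps.rankdata(data, axis=1)
    r1 = ranks[:, :n_a].sum(axis=1)
    u1 = r1 - n_a * (n_a + 1) / 2.0
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    s = np.sort(data, axis=1)
    ties = np.zeros(data.shape[0])
    eq = s[:, 1:] == s[:, :-1]
    for i in range(data.shape[0]):
        if eq[i].any():
            _, counts = np.unique(s[i], return_counts=True)
            ties[i] = np.sum(counts**3 - counts)
    var = n_a * n_b / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    p = np.ones(data.shape[0])
    ok = var > 0
    z = (np.abs(u1[ok] - mu) - 0.5) / np.sqrt(var[ok])
    z = np.maximum(z, 0.0)
    p[ok] = np.minimum(2.0 * sps.norm.sf(z), 1.0)
    return p


@dataclass
class BootstrapTestResult:
    category_a: str
    category_b: str
    n_a: int
    n_b: int
    subsample_size: int
    n_boot: int
    mean_p: float
    median_p: float
    seed: int
    na: bool = False
    alternative: str = "two-sided"


def bootstrap_wilcoxon(
    values_by_category: dict[str, np.ndarray],
    cat_a: str,
    cat_b: str,
    n_boot: int = 9999,
    seed: int = 0,
    min_n: int = 4,
) -> BootstrapTestResult:
    """Subsampled bootstrapped rank-sum test between two categories.

    Per replicate the larger group is subsampled without replacement to the
    smaller group's size; the mean (and median) p over replicates is
    reported. Flagged NA when either category has 3 or fewer values. When
    group sizes are equal every replicate would use all data, so a single
    test is performed.
    """
    a = np.asarray(values_by_category[cat_a], dtype=float)
    b = np.asarray(values_by_category[cat_b], dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n_a, n_b = a.size, b.size
    m = min(n_a, n_b)
    if m < min_n:
        return BootstrapTestResult(
            cat_a, cat_b, n_a, n_b, m, 0, np.nan, np.nan, seed, na=True
        )
    if n_a == n_b:
        p = mann_whitney(a, b)
        return BootstrapTestResult(cat_a, cat_b, n_a, n_b, m, 1, p, p, seed)
    small, large = (a, b) if n_a < n_b else (b, a)
    rng = np.random.default_rng(seed)
    ps = np.empty(n_boot)
    use_exact = 2 * m <= 12
    chunk = max(1, min(n_boot, 2000))
    small_tiled = np.broadcast_to(small, (chunk, m))
    done = 0
    while done < n_boot:
        c = min(chunk, n_boot - done)
        idx = rng.random((c, large.size)).argsort(axis=1)[:, :m]
        sub = large[idx]
        if use_exact:
            for i in range(c):
                ps[done + i] = mann_whitney(small, sub[i])
        else:
            ps[done : done + c] = _rowwise_asymptotic_p(small_tiled[:c], sub)
        done += c
    return BootstrapTestResult(
        cat_a, cat_b, n_a, n_b, m, n_boot, float(ps.mean()), float(np.median(ps)), seed
    )


def category_tests(
    annotated: pd.DataFrame,
    n_boot: int = 9999,
    seed: int = 0,
    value_col: str = "value",
    min_n: int = 4,
) -> pd.DataFrame:
    """Bootstrap tests for every category pair on an annotated value table."""
    vals = {
        c: annotated.loc[annotated["category"] == c, value_col].dropna().to_numpy()
        for c in CATEGORIES
    }
    rows = []
    for cat_a, cat_b in itertools.combinations(CATEGORIES, 2):
        r = bootstrap_wilcoxon(vals, cat_a, cat_b, n_boot=n_boot, seed=seed, min_n=min_n)
        rows.append(
            {
                "category_a": cat_a,
                "category_b": cat_b,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "mean_a": float(np.mean(vals[cat_a])) if r.n_a else np.nan,
                "mean_b": float(np.mean(vals[cat_b])) if r.n_b else np.nan,
                "subsample_size": r.subsample_size,
                "n_boot": r.n_boot,
                "mean_p": r.mean_p,
                "median_p": r.median_p,
                "na": r.na,
            }
        )
    return pd.DataFrame(rows)


def genotype_stability_test(
    intra_values: pd.DataFrame,
    value_col: str = "value",
    aggregate_by_individual: bool = True,
) -> float:
    """Rank-sum test of intraindividual values between host genotypes.

    ``intra_values`` needs columns individual_id, genotype and the value
    column. By default values are averaged within each individual first
    (testing mean intraindividual similarity); returns NaN when a genotype
    stratum is missing or has fewer than 3 values.
    """
    df = intra_values.dropna(subset=[value_col])
    if aggregate_by_individual:
        df = (
            df.groupby(["individual_id", "genotype"], as_index=False)[value_col].mean()
        )
    groups = [g[value_col].to_numpy() for _, g in df.groupby("genotype")]
    if len(groups) != 2 or any(len(g) < 3 for g in groups):
        return float("nan")
    return mann_whitney(groups[0], groups[1])


def subsampled_spearman(
    x,
    y,
    group_labels,
    n_sub: int = 15,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Mean Spearman rho over permutations subsampling each group to n_sub.

    Balances unequal group sizes before correlating: per permutation,
    ``n_sub`` members of each group are drawn without replacement, pooled,
    and rho is computed on the pool; the mean over permutations is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(group_labels)
    rng = np.random.default_rng(seed)
    group_idx = []
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        if idx.size < n_sub:
            raise ValueError(f"group {g!r} has {idx.size} members (< n_sub = {n_sub})")
        group_idx.append(idx)
    rhos = np.empty(n_perm)
    for i in range(n_perm):
        pick = np.concatenate([rng.choice(idx, n_sub, replace=False) for idx in group_idx])
        rhos[i] = sps.spearmanr(x[pick], y[pick]).statistic
    return float(rhos.mean())
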