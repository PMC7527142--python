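import itertools
import math

import numpy as np
import pandas as pd
import pytest

from syntrack.stats import (
    annotate_pairs,
    bootstrap_wilcoxon,
    categorize_pairs,
    category_tests,
    genotype_stability_test,
    mann_whitney,
    subsampled_spearman,
)


def _metadata(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "individual_id", "family_id", "genotype", "timepoint"]
    )


TOY_META = _metadata(
    [
        ("a1", "A", "F1", "GG", 1),
        ("a2", "A", "F1", "GG", 2),
        ("b1", "B", "F1", "GG", 1),
        ("c1", "C", "F2", "AA", 1),
        ("c2", "C", "F2", "AA", 2),
    ]
)


class TestCategorizePairs:
    def test_definitions(self):
        cats = categorize_pairs(TOY_META).set_index(["sample_a", "sample_b"])["category"]
        assert cats[("a1", "a2")] == "intraindividual"
        assert cats[("a1", "b1")] == "same_family"  # co-twins
        assert cats[("a1", "c1")] == "unrelated"

    def test_partition_counts(self, default_cohort):
        md = default_cohort.metadata
        cats = categorize_pairs(md)
        S = len(md)
        assert len(cats) == S * (S - 1) // 2
        counts = cats["category"].value_counts()
        assert counts.sum() == S * (S - 1) // 2
        assert set(counts.index) <= {"intraindividual", "same_family", "unrelated"}

    def test_43_samples_903_pairs(self, default_cohort):
        md = default_cohort.metadata.iloc[:43]
        cats = categorize_pairs(md)
        assert len(cats) == 903  # C(43,2)

    def test_unknown_sample_rejected(self):
        values = pd.DataFrame({"sample_a": ["a1"], "sample_b": ["zz"], "value": [1.0]})
        with pytest.raises(ValueError, match="zz"):
            annotate_pairs(values, TOY_META)

    def test_inconsistent_metadata_rejected(self):
        bad = _metadata(
            [("x1", "X", "F1", "GG", 1), ("x2", "X", "F2", "GG", 2)]
        )
        with pytest.raises(ValueError, match="inconsistent"):
            categorize_pairs(bad)


class TestMannWhitney:
    def test_exact_enumeration(self):
        # P(most extreme split) = 2/C(6,3) = 0.1
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p1(self):
        assert mann_whitney([5, 5, 5], [5, 5, 5]) == 1.0
        assert mann_whitney([1, 2], [1, 2]) == 1.0

    def test_matches_enumeration_oracle(self):
        # brute-force two-sided p over all C(7,3) labelings
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0, 7.0]
        pooled = a + b
        ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
        u_obs = sum(ranks[v] for v in a) - len(a) * (len(a) + 1) / 2
        mu = len(a) * len(b) / 2
        count = 0
        total = 0
        for combo in itertools.combinations(pooled, len(a)):
            u = sum(ranks[v] for v in combo) - len(a) * (len(a) + 1) / 2
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
            total += 1
        assert mann_whitney(a, b) == pytest.approx(count / total, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBootstrapWilcoxon:
    def test_equal_sizes_single_test(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.5, 3.5, 4.5, 5.5, 6.5]
        r = bootstrap_wilcoxon({"a": a, "b": b}, "a", "b", n_boot=999, seed=0)
        assert r.n_boot == 1
        assert r.mean_p == pytest.approx(mann_whitney(a, b))

    def test_na_below_minimum(self):
        r = bootstrap_wilcoxon(
            {"a": [1.0, 2.0, 3.0], "b": [4.0] * 10}, "a", "b", n_boot=99, seed=0
        )
        assert r.na and math.isnan(r.mean_p)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        vals = {"a": rng.normal(0, 1, 10), "b": rng.normal(0.5, 1, 40)}
        r1 = bootstrap_wilcoxon(vals, "a", "b", n_boot=499, seed=7)
        r2 = bootstrap_wilcoxon(vals, "a", "b", n_boot=499, seed=7)
        r3 = bootstrap_wilcoxon(vals, "a", "b", n_boot=499, seed=8)
        assert r1.mean_p == r2.mean_p
        assert r1.mean_p != r3.mean_p
        assert abs(r1.mean_p - r3.mean_p) < 0.05  # stable across reseeds

    def test_power_two_sd_offset(self):
        # groups offset by 2 sd, n = 20 vs 200 -> mean_p < 0.01 nearly always
        rng = np.random.default_rng(2)
        hits = 0
        reps = 60
        for i in range(reps):
            vals = {"a": rng.normal(2, 1, 20), "b": rng.normal(0, 1, 200)}
            r = bootstrap_wilcoxon(vals, "a", "b", n_boot=199, seed=i)
            hits += r.mean_p < 0.01
        assert hits >= 0.95 * reps

    def test_subsample_size_is_smaller_group(self):
        rng = np.random.default_rng(3)
        vals = {"a": rng.normal(0, 1, 12), "b": rng.normal(0, 1, 50)}
        r = bootstrap_wilcoxon(vals, "a", "b", n_boot=99, seed=0)
        assert r.subsample_size == 12
        assert r.n_a == 12 and r.n_b == 50


class TestGenotypeStability:
    def _frame(self, gg, aa):
        rows = []
        for i, v in enumerate(gg):
            rows.append({"individual_id": f"g{i}", "genotype": "GG", "value": v})
        for i, v in enumerate(aa):
            rows.append({"individual_id": f"a{i}", "genotype": "AA", "value": v})
        return pd.DataFrame(rows)

    def test_separated_groups_small_p(self):
        df = self._frame([1, 2, 3, 4, 5, 6], [11, 12, 13, 14, 15, 16])
        assert genotype_stability_test(df) < 0.01

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            df = self._frame(rng.normal(0, 1, 8), rng.normal(0, 1, 8))
            ps.append(genotype_stability_test(df))
        assert 0.35 < np.mean(ps) < 0.65  # mean of uniform ~ 0.5

    def test_missing_stratum_nan(self):
        df = self._frame([1, 2, 3, 4], [])
        assert math.isnan(genotype_stability_test(df))

    def test_aggregation_by_individual(self):
        rows = [
            {"individual_id": "g1", "genotype": "GG", "value": v} for v in (1.0, 9.0)
        ] + [
            {"individual_id": f"g{i}", "genotype": "GG", "value": 5.0} for i in (2, 3)
        ] + [
            {"individual_id": f"a{i}", "genotype": "AA", "value": float(i)} for i in (4, 5, 6)
        ]
        df = pd.DataFrame(rows)
        p_agg = genotype_stability_test(df, aggregate_by_individual=True)
        p_raw = genotype_stability_test(df, aggregate_by_individual=False)
        assert not math.isnan(p_agg) and not math.isnan(p_raw)


class TestSubsampledSpearman:
    def test_perfect_monotone(self):
        x = np.arange(40.0)
        labels = ["g"] * 20 + ["a"] * 20
        assert subsampled_spearman(x, x, labels, n_sub=15, n_perm=50, seed=0) == pytest.approx(1.0)
        assert subsampled_spearman(x, -x, labels, n_sub=15, n_perm=50, seed=0) == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 120)
        y = rng.normal(0, 1, 120)
        labels = ["g"] * 60 + ["a"] * 60
        rho = subsampled_spearman(x, y, labels, n_sub=15, n_perm=200, seed=1)
        assert abs(rho) < 0.1

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match="n_sub"):
            subsampled_spearman([1, 2], [1, 2], ["g", "a"], n_sub=15)


class TestCategoryTests:
    def test_all_pairs_reported(self, default_cohort):
        md = default_cohort.metadata
        cats = categorize_pairs(md)
        rng = np.random.default_rng(6)
        cats["value"] = rng.normal(0, 1, len(cats))
        res = category_tests(cats, n_boot=99, seed=0)
        assert len(res) == 3
        assert set(res["category_a"]) <= {"intraindividual", "same_family"}
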