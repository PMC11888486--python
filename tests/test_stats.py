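import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from csfcyto import (age_trend, compare_groups, median_log10_fold_change,
                     wilcoxon_rank_sum)
from csfcyto.stats import significance_stars


def _enumerated_rank_sum(x, y):
    """Exact U and two-sided p by enumerating every group assignment."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(a, b):
        return sum(1.0 if ai > bj else 0.5 if ai == bj else 0.0
                   for ai in a for bj in b)

    u_obs = u_stat(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(a, b))
    us = np.array(us)
    p = 2 * min((us >= u_obs).mean(), (us <= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestWilcoxonRankSum:
    def test_fully_separated_small_samples(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)   # 2 / C(6,3)

    def test_fully_tied_samples(self):
        u, p = wilcoxon_rank_sum([5.0], [5.0])
        assert p == 1.0

    def test_pairwise_count_statistic(self):
        u, _ = wilcoxon_rank_sum([0.9, 0.4], [0.5, 0.1])
        assert u == 3.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_symmetry_of_p(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=6), rng.normal(1, 1, size=5)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            u1, _ = wilcoxon_rank_sum(x, y)
            u2, _ = wilcoxon_rank_sum(y, x)
            assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_matches_full_enumeration_for_tiny_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            u, p = wilcoxon_rank_sum(x, y)
            u_ref, p_ref = _enumerated_rank_sum(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_exact_and_approximate_agree_on_significance(self):
        # documented property: same side of 0.05 in >= 95% of instances
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(3)
        agree = 0
        trials = 200
        for _ in range(trials):
            n1, n2 = rng.integers(4, 16), rng.integers(4, 16)
            shift = rng.uniform(0, 1.5)
            x = rng.normal(size=n1)
            y = rng.normal(shift, 1, size=n2)
            p_exact = mannwhitneyu(x, y, method="exact").pvalue
            p_approx = mannwhitneyu(x, y, method="asymptotic").pvalue
            agree += (p_exact < 0.05) == (p_approx < 0.05)
        assert agree / trials >= 0.95


class TestFoldChange:
    def test_tenfold(self):
        assert median_log10_fold_change([10, 10, 10], [1, 1, 1]) == pytest.approx(1.0)

    def test_identity(self):
        x = [1.0, 2.0, 5.0]
        assert median_log10_fold_change(x, x) == 0.0

    def test_cohort_style_medians(self):
        # medians 240 and 3.78 -> log10(63.49...)
        assert median_log10_fold_change([240.0], [3.78]) == pytest.approx(
            1.80276, abs=1e-4)

    def test_degenerate_medians_flagged(self):
        assert math.isinf(median_log10_fold_change([1.0], [0.0]))
        assert math.isnan(median_log10_fold_change([0.0], [0.0]))
        assert median_log10_fold_change([0.0], [1.0]) == -math.inf


class TestAgeTrend:
    def test_perfect_monotone(self):
        rho, _ = age_trend([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = age_trend([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_example_with_exact_p(self):
        rho, p = age_trend([2, 8, 14, 18], [80, 60, 30, 10])
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 24)    # 2 of 4! permutations at |rho|=1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(2, 19, size=12)
        freqs = rng.uniform(0, 100, size=12)
        rho1, p1 = age_trend(ages, freqs)
        rho2, p2 = age_trend(np.exp(ages / 5), freqs ** 3)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_vector_flagged(self):
        rho, p = age_trend([1, 2, 3], [7, 7, 7])
        assert math.isnan(rho) and math.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            age_trend([1, 2], [3, 4])


class TestCompareGroups:
    def _values(self):
        return pd.DataFrame({
            "donor_id": [f"d{i}" for i in range(8)],
            "group": ["A"] * 4 + ["B"] * 4,
            "value": [1.0, 2.0, 3.0, 4.0, 10.0, 20.0, 30.0, 40.0],
        })

    def test_identical_groups_null_result(self):
        values = self._values()
        values["value"] = 1.0
        out = compare_groups(values, "f", [("A", "B")])
        assert out.loc[0, "p"] == 1.0
        assert out.loc[0, "log10_fc"] == 0.0
        assert out.loc[0, "stars"] == "ns"

    def test_swapped_pair_symmetry(self):
        out = compare_groups(self._values(), "f", [("A", "B"), ("B", "A")])
        assert out.loc[0, "p"] == pytest.approx(out.loc[1, "p"])
        assert out.loc[0, "log10_fc"] == pytest.approx(-out.loc[1, "log10_fc"])
        assert out.loc[0, "U"] + out.loc[1, "U"] == 16

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="C"):
            compare_groups(self._values(), "f", [("A", "C")])

    def test_bh_column_optional(self):
        out = compare_groups(self._values(), "f", [("A", "B")], bh=True)
        assert "p_bh" in out.columns
        assert out.loc[0, "p_bh"] >= out.loc[0, "p"]

    def test_star_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(4e-4) == "***"
        assert significance_stars(4e-5) == "****"
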