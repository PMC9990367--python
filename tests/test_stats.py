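import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from fretflux.stats import (
    GroupSample,
    kruskal_wallis,
    mann_whitney_u,
    posthoc_vs_reference,
    significance_stars,
    summarize_cohort,
)


def permutation_mw_p(a, b):
    """Independent oracle: exact two-sided Mann-Whitney p by full
    enumeration of all C(n+m, n) group assignments."""
    pooled = list(a) + list(b)
    n = len(a)

    def u_of(idx):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = sum(1 for x in grp for y in rest if x > y) + 0.5 * sum(
            1 for x in grp for y in rest if x == y
        )
        return min(u, len(grp) * len(rest) - u)

    observed = u_of(tuple(range(n)))
    us = [u_of(idx) for idx in combinations(range(len(pooled)), n)]
    return sum(1 for u in us if u <= observed + 1e-12) / len(us)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_u(GroupSample("a", (1, 2, 3)), GroupSample("b", (4, 5, 6)))
        assert res.statistic == 0
        assert res.p == pytest.approx(0.1)  # 2 / C(6,3)
        assert "exact" in res.method

    def test_identical_samples_give_p_one(self):
        res = mann_whitney_u(GroupSample("a", (5, 5, 5, 5)), GroupSample("b", (5, 5, 5, 5)))
        assert res.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSample("b", ())

    @pytest.mark.parametrize(
        "a,b",
        [
            ((1, 2, 3), (4, 5, 6)),
            ((1.5, 2.5), (0.5, 3.5, 4.5)),
            ((10, 1, 7, 3), (2, 8, 5)),
            ((1, 4), (2, 3, 5, 6, 7)),
            ((9, 2, 6, 11, 3), (1, 5, 8, 10, 12)),
        ],
    )
    def test_exact_p_matches_permutation_oracle(self, a, b):
        res = mann_whitney_u(GroupSample("a", a), GroupSample("b", b))
        assert res.p == pytest.approx(permutation_mw_p(a, b), abs=1e-12)

    def test_exact_and_asymptotic_close_for_small_tie_free_samples(self):
        rng = np.random.default_rng(8)
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            a = tuple(rng.normal(size=6))
            b = tuple(rng.normal(size=7))
            exact = mann_whitney_u(GroupSample("a", a), GroupSample("b", b)).p
            approx = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            assert abs(exact - approx) < 0.02

    def test_order_invariance_within_groups(self):
        a, b = (3.0, 1.0, 2.0), (6.0, 4.0, 5.0)
        r1 = mann_whitney_u(GroupSample("a", a), GroupSample("b", b))
        r2 = mann_whitney_u(GroupSample("a", a[::-1]), GroupSample("b", b[::-1]))
        assert r1.p == r2.p and r1.statistic == r2.statistic


class TestKruskalWallis:
    def test_identical_groups_give_h_zero_p_one(self):
        g = GroupSample("x", (1.0, 1.0, 1.0))
        res = kruskal_wallis([g, GroupSample("y", g.values), GroupSample("z", g.values)])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_h_matches_rank_sum_formula(self):
        """Brute-force oracle: H = 12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2
        with no ties."""
        groups = [
            GroupSample("a", (1.0, 2.0)),
            GroupSample("b", (3.0, 4.0)),
            GroupSample("c", (5.0, 6.0)),
        ]
        res = kruskal_wallis(groups)
        n_tot = 6
        mean_ranks = [1.5, 3.5, 5.5]
        h = 12.0 / (n_tot * (n_tot + 1)) * sum(
            2 * (r - (n_tot + 1) / 2) ** 2 for r in mean_ranks
        )
        assert res.statistic == pytest.approx(h)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            kruskal_wallis(
                [GroupSample("a", (1.0,)), GroupSample("b", (1, 2)), GroupSample("c", (3, 4))]
            )

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            kruskal_wallis([GroupSample("a", (1, 2)), GroupSample("b", (3, 4))])


class TestPosthoc:
    def test_identical_groups_all_adjusted_p_one(self):
        vals = (1.0, 2.0, 3.0, 4.0)
        groups = [GroupSample(n, vals) for n in ("a", "b", "c")]
        for res in posthoc_vs_reference(groups, "a"):
            assert res.adjusted_p == 1.0

    def test_adjusted_p_at_least_raw_p(self):
        rng = np.random.default_rng(12)
        groups = [GroupSample(n, tuple(rng.normal(m, 1, 8))) for n, m in
                  (("a", 0.0), ("b", 1.0), ("c", 2.0))]
        for res in posthoc_vs_reference(groups, "a"):
            assert res.adjusted_p >= res.p

    def test_missing_reference_rejected(self):
        groups = [GroupSample(n, (1.0, 2.0, 3.0)) for n in ("a", "b", "c")]
        with pytest.raises(ValueError, match="reference"):
            posthoc_vs_reference(groups, "zzz")

    def test_dunnett_alternative_path(self):
        rng = np.random.default_rng(13)
        groups = [GroupSample(n, tuple(rng.normal(m, 1, 10))) for n, m in
                  (("ref", 0.0), ("hi", 3.0), ("lo", 0.1))]
        res = posthoc_vs_reference(groups, "ref", method="dunnett")
        by_name = {r.groups[0]: r for r in res}
        assert by_name["hi"].adjusted_p < 0.05
        assert by_name["lo"].adjusted_p > 0.05


class TestSummarizeCohort:
    def _table(self):
        return pd.DataFrame(
            {
                "group": ["c"] * 3 + ["k"] * 3,
                "mouse": ["c0", "c0", "c1", "k0", "k1", "k1"],
                "slope_dratio_per_min": [0.5, 0.6, 0.55, 0.9, 1.0, 0.95],
                "flags": [""] * 6,
            }
        )

    def test_counts(self):
        summary, comparisons = summarize_cohort(
            self._table(), readouts=("slope_dratio_per_min",)
        )
        assert len(summary) == 2
        assert len(comparisons) == 1
        assert comparisons.iloc[0]["p"] == pytest.approx(0.1)

    def test_all_flagged_traces_skip_comparison(self):
        df = self._table()
        df["flags"] = "low_r2"
        _, comparisons = summarize_cohort(df, readouts=("slope_dratio_per_min",))
        assert comparisons.iloc[0]["note"] == "no eligible traces"

    def test_mouse_aggregation_mode(self):
        summary, comparisons = summarize_cohort(
            self._table(), readouts=("slope_dratio_per_min",), unit="mouse"
        )
        # 2 mice in group c, 2 in group k
        assert tuple(comparisons.iloc[0][["group_a", "group_b"]]) == ("c", "k")

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            summarize_cohort(self._table(), reference="zzz")


def test_significance_star_thresholds():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.05) == "*"
    assert significance_stars(0.01) == "**"
    assert significance_stars(0.0005) == "***"
    assert significance_stars(1e-5) == "****"
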