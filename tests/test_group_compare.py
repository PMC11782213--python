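"""Rank statistics: exact enumeration, normal approximation, HL shifts,
omnibus tests, and the pathology-group comparison driver."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adcascade.group_compare import (
    bonferroni_adjust,
    chi_square_2x2,
    compare_by_pathology_group,
    hodges_lehmann_shift,
    kruskal_wallis,
    wilcoxon_rank_sum,
)
from adcascade.preprocess import build_analysis_table
from adcascade.synthetic_cohort import default_config, generate_cohort


class TestWilcoxonRankSum:
    def test_identical_samples_exact(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_exact(self):
        # 2 of the C(6,3)=20 assignments are at least as extreme
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.p_value == pytest.approx(0.1)

    def test_all_tied_degenerate(self):
        res = wilcoxon_rank_sum([5, 5, 5], [5, 5], mode="exact")
        assert res.p_value == 1.0 and res.degenerate

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        assert wilcoxon_rank_sum(x, y, mode="normal").p_value < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_mode_matches_scipy_asymptotic(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.4, 1.2, 25)
        mine = wilcoxon_rank_sum(x, y, mode="normal")
        ref = stats.mannwhitneyu(x, y, method="asymptotic")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_and_normal_agree_for_small_samples(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 1, 9)
        y = rng.normal(0.5, 1, 9)
        exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
        normal = wilcoxon_rank_sum(x, y, mode="normal").p_value
        assert abs(exact - normal) < 0.02


class TestHodgesLehmann:
    def test_hand_example(self):
        est, lo, hi = hodges_lehmann_shift([1, 2, 3], [3, 4, 5])
        assert est == pytest.approx(-2.0)
        assert lo <= est <= hi

    @given(
        x=st.lists(st.floats(-50, 50, allow_nan=False), min_size=3, max_size=8),
        c=st.floats(-20, 20, allow_nan=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_shift_equivariance(self, x, c):
        """HL(x + c, x) recovers the pure shift c exactly."""
        est, _, _ = hodges_lehmann_shift([v + c for v in x], x)
        assert est == pytest.approx(c, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_inversion_ci_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 7)
        y = rng.normal(1, 1, 6)
        est, lo, hi = hodges_lehmann_shift(x, y, ci_level=0.95, method="inversion")
        # oracle: enumerate every group assignment of the pooled ranks to
        # build the exact null CDF of U, then index the ordered differences
        n_a, n_b = len(x), len(y)
        pooled = np.arange(n_a + n_b, dtype=float)
        us = []
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            ranks = stats.rankdata(pooled)
            us.append(sum(ranks[list(idx)]) - n_a * (n_a + 1) / 2)
        values, counts = np.unique(us, return_counts=True)
        cdf = np.cumsum(counts) / len(us)
        ok = values[cdf <= 0.025 + 1e-12]
        k = int(ok[-1]) if len(ok) else -1
        diffs = np.sort(np.subtract.outer(x, y).ravel())
        assert (lo, hi) == (pytest.approx(diffs[k]), pytest.approx(diffs[len(diffs) - k - 1]))

    def test_bootstrap_ci_seeded_and_covers_estimate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2, 1, 40)
        y = rng.normal(0, 1, 35)
        r1 = hodges_lehmann_shift(x, y, method="bootstrap", seed=5)
        r2 = hodges_lehmann_shift(x, y, method="bootstrap", seed=5)
        assert r1 == r2
        est, lo, hi = r1
        assert lo <= est <= hi


class TestKruskalWallis:
    def test_hand_ranked_formula(self):
        # ranks 1..9 split into thirds: H = 12/90 * (12^2/... ) - 30 = 7.2
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.degrees_of_freedom == 2

    def test_degenerate_identical(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
        assert res.p_value == 1.0 and res.degenerate

    def test_two_groups_agree_with_wilcoxon_normal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.3, 1, 50)
        kw = kruskal_wallis([x, y]).p_value
        wr = wilcoxon_rank_sum(x, y, mode="normal").p_value
        assert abs(kw - wr) < 0.01

    def test_null_p_uniform(self):
        rng = np.random.default_rng(0)
        ps = [
            kruskal_wallis([rng.normal(size=50) for _ in range(3)]).p_value
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.01], family_size=3) == [pytest.approx(0.03)]
        assert bonferroni_adjust([0.5, 0.9]) == [1.0, 1.0]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_never_below_raw(self, ps):
        adjusted = bonferroni_adjust(ps)
        assert all(a >= p for a, p in zip(adjusted, ps))


class TestChiSquare:
    def test_independence(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_sex_by_group_hand_value(self):
        # expected counts E_ij = row_i * col_j / N; value from the
        # expected-count formula computed by hand
        res = chi_square_2x2([[33, 9], [157, 191]], correction=False)
        assert res.statistic == pytest.approx(16.790753824215717)
        assert res.p_value < 0.001

    def test_doubling_cells_doubles_statistic(self):
        t = np.array([[12, 7], [9, 20]])
        s1 = chi_square_2x2(t).statistic
        s2 = chi_square_2x2(2 * t).statistic
        assert s2 == pytest.approx(2 * s1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestCompareByPathologyGroup:
    def test_pair_count_is_combinatorial(self, default_cohort):
        cohort, _ = default_cohort
        at = build_analysis_table(cohort, ["at_group", "gfap"])
        report = compare_by_pathology_group(at, "gfap")
        usable = 4 - len(report.skipped)
        assert len(report.pairwise) == usable * (usable - 1) // 2
        assert report.family_size == len(report.pairwise)
        for comp in report.pairwise:
            assert comp.adjusted_p >= comp.raw_p
            assert comp.hl_ci_low <= comp.hl_shift <= comp.hl_ci_high

    def test_null_cohort_rarely_significant(self):
        from adcascade.synthetic_cohort import null_config

        hits = 0
        for seed in range(12):
            cohort, _ = generate_cohort(null_config(seed=seed, n_ds=150, n_controls=50))
            # assign arbitrary A/T groups by age quartile so all four exist
            cohort = cohort.copy()
            at = build_analysis_table(cohort, ["gfap"], exclude_discordant=False)
            data = at.data
            q = data["age"].rank(pct=True)
            data.loc[:, "at_group"] = np.select(
                [q < 0.25, q < 0.5, q < 0.75], ["control", "A-/T-", "A+/T-"], "A+/T+"
            )
            report = compare_by_pathology_group(at, "gfap")
            hits += any(c.adjusted_p < 0.05 for c in report.pairwise)
        assert hits <= 3

    def test_small_group_skipped_and_logged(self, default_cohort):
        cohort, _ = default_cohort
        at = build_analysis_table(cohort, ["at_group", "gfap"])
        import pandas as pd

        data = at.data[at.data["at_group"] != "A+/T-"]
        single = at.data[at.data["at_group"] == "A+/T-"].head(1)
        at.data = pd.concat([data, single], ignore_index=True)
        report = compare_by_pathology_group(at, "gfap")
        assert any(s["group"] == "A+/T-" for s in report.skipped)
        assert len(report.pairwise) == 3
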