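"""Cohort statistics: normality, Kruskal–Wallis, Pearson, CV, power, trajectories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxymet.stats import (
    coefficient_of_variation,
    kruskal_wallis_pairwise,
    normality_screen,
    pearson_corr,
    sample_size_power,
    trajectory_divergence,
)


class TestNormalityScreen:
    def test_uniform_draws_rejected_at_large_n(self, rng):
        groups = {"u": rng.uniform(0, 1, 500), "n": rng.normal(0, 1, 500)}
        screen = normality_screen(groups)
        assert screen.p_values["u"] < 0.05
        assert screen.recommendation == "nonparametric"

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            normality_screen({"a": [1.0, 2.0]})

    def test_constant_group_reported_degenerate(self):
        screen = normality_screen({"a": [5.0, 5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0, 2.5]})
        assert screen.degenerate["a"] and np.isnan(screen.p_values["a"])


class TestKruskalWallis:
    def test_hand_computed_h_for_two_rank_separated_groups(self):
        comp = kruskal_wallis_pairwise({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        # ranks 1..6 split cleanly: H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7
        assert comp.statistic == pytest.approx(12 / 42 * (12 + 75) - 21, abs=1e-9)
        assert comp.statistic == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups_null_result(self):
        same = [2.0, 2.0, 2.0]
        comp = kruskal_wallis_pairwise({"a": same, "b": same, "c": same})
        assert comp.statistic == 0.0 and comp.omnibus_p == 1.0
        assert all(p.bonferroni_p == 1.0 for p in comp.pairwise)

    def test_well_separated_groups_all_pairwise_significant(self, rng):
        groups = {
            "a": rng.normal(0, 1, 14),
            "b": rng.normal(8, 1, 14),
            "c": rng.normal(16, 1, 14),
        }
        comp = kruskal_wallis_pairwise(groups)
        assert len(comp.pairwise) == 3
        assert all(p.bonferroni_p < 0.05 for p in comp.pairwise)

    def test_bonferroni_is_raw_times_pairs_capped(self, rng):
        groups = {g: rng.normal(i, 1, 10) for i, g in enumerate("abc")}
        comp = kruskal_wallis_pairwise(groups)
        for p in comp.pairwise:
            assert p.bonferroni_p == pytest.approx(min(1.0, p.raw_p * 3), rel=1e-12)
            assert p.bonferroni_p >= p.raw_p

    def test_dunn_posthoc_variant_runs(self, rng):
        groups = {g: rng.normal(i * 3, 1, 12) for i, g in enumerate("abc")}
        comp = kruskal_wallis_pairwise(groups, posthoc="dunn")
        assert len(comp.pairwise) == 3
        assert comp.pairwise[0].raw_p <= 1.0

    def test_summaries_carry_cv(self, rng):
        groups = {"a": rng.normal(100, 10, 20), "b": rng.normal(50, 5, 20)}
        comp = kruskal_wallis_pairwise(groups)
        for s in comp.summaries:
            assert s.cv_pct == pytest.approx(100 * s.sd / s.mean, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_pairwise({"a": [1.0, 2.0], "b": []})

    @given(power=st.sampled_from([1.0, 3.0]), scale=st.floats(0.5, 4.0))
    def test_h_invariant_under_monotone_transform(self, power, scale):
        rng = np.random.default_rng(7)
        groups = {g: np.abs(rng.normal(i + 1, 1, 10)) + 0.1 for i, g in enumerate("abc")}
        h0 = kruskal_wallis_pairwise(groups).statistic
        transformed = {g: scale * v**power for g, v in groups.items()}
        h1 = kruskal_wallis_pairwise(transformed).statistic
        assert h1 == pytest.approx(h0, rel=1e-12)


class TestPearson:
    def test_perfect_positive(self):
        assert pearson_corr([1, 2, 3, 4], [2, 4, 6, 8]).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_corr([1, 2, 3], [-1, -2, -3]).r == pytest.approx(-1.0)

    def test_hand_computed_moderate_correlation(self):
        res = pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)
        assert res.n == 4

    def test_matches_brute_force_covariance_oracle(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(size=8)
            r = pearson_corr(x, y).r
            oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert r == pytest.approx(oracle, abs=1e-12)

    def test_missing_pairs_dropped(self):
        res = pearson_corr([1, 2, 3, np.nan, 5], [2, 4, 6, 8, np.nan])
        assert res.n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([7.0, 7.0, 7.0]) == 0.0

    def test_analytic_check_from_mean_and_sd(self):
        # two points at mean +/- sd/sqrt(2) have sample SD exactly sd
        mean, sd = 63.8, 14.8
        values = [mean - sd / np.sqrt(2), mean + sd / np.sqrt(2)]
        assert coefficient_of_variation(values) == pytest.approx(100 * sd / mean, rel=1e-12)
        assert coefficient_of_variation(values) == pytest.approx(23.2, abs=0.05)

    @given(k=st.floats(0.1, 50.0))
    def test_scale_invariance(self, k):
        v = np.random.default_rng(11).normal(50, 5, 30)
        assert coefficient_of_variation(k * v) == pytest.approx(
            coefficient_of_variation(v), rel=1e-9
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestSampleSizePower:
    def test_unit_effect_at_80_percent_power(self):
        # 2 * (1.96 + 0.8416)^2 = 15.7 -> 16
        assert sample_size_power(delta=10.0, sd=10.0, alpha=0.05, power=0.80) == 16

    def test_perfusion_design_value(self):
        # 20-unit difference, SD ~7.5, alpha 0.05, power 95 % -> n = 4
        assert sample_size_power(delta=20.0, sd=7.5, alpha=0.05, power=0.95) == 4

    def test_doubling_delta_quarters_n(self):
        n1 = sample_size_power(delta=5.0, sd=10.0, power=0.80)
        n4 = sample_size_power(delta=10.0, sd=10.0, power=0.80)
        assert n1 == pytest.approx(4 * n4, abs=3)  # ceiling effects only

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            sample_size_power(delta=0.0, sd=10.0)


def frame(rows: dict, n_animals: int) -> pd.DataFrame:
    return pd.DataFrame(
        {f"m{i}": pd.Series(rows) for i in range(n_animals)}
    )


class TestTrajectoryDivergence:
    def test_identical_trajectories_never_diverge(self):
        days = {d: 1.0 for d in range(18)}
        res = trajectory_divergence(frame(days, 10), frame(days, 10))
        assert res.first_significant_day is None

    def test_step_trajectory_diverges_on_step_day(self, rng):
        days = np.arange(18)
        eae = pd.DataFrame(
            {f"e{i}": np.where(days >= 12, 8.0, 0.0) + rng.normal(0, 0.5, 18)
             for i in range(13)}, index=days,
        )
        cfa = pd.DataFrame(
            {f"c{i}": rng.normal(0, 0.5, 18) for i in range(14)}, index=days,
        )
        res = trajectory_divergence(eae, cfa)
        assert res.first_significant_day == 12

    def test_attrition_recorded_in_per_day_counts(self, rng):
        days = np.arange(5)
        a = pd.DataFrame({"x": [0, 0, 1, np.nan, np.nan], "y": [0, 0, 1, 1, 1]}, index=days)
        b = pd.DataFrame({"u": np.zeros(5), "v": np.zeros(5)}, index=days)
        res = trajectory_divergence(a, b)
        assert res.n_per_day[3] == (1, 2)

    def test_single_shared_day_rejected(self):
        a = pd.DataFrame({"x": [1.0]}, index=[3])
        b = pd.DataFrame({"y": [1.0]}, index=[3])
        with pytest.raises(ValueError):
            trajectory_divergence(a, b)

    def test_rm_anova_contract_runs(self, rng):
        days = np.arange(6)
        a = pd.DataFrame({f"a{i}": days * 1.0 + rng.normal(0, 0.2, 6) for i in range(6)}, index=days)
        b = pd.DataFrame({f"b{i}": rng.normal(0, 0.2, 6) for i in range(6)}, index=days)
        res = trajectory_divergence(a, b, method="rm_anova")
        assert res.first_significant_day is not None
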