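import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from solepipe.growthstats import (
    DegenerateVarianceError,
    analyze_cohort,
    paired_ttest,
    student_t_sf2,
    summarize_group,
    twosample_ttest,
)
from solepipe.synthscene import cohort_to_frame, generate_growth_cohort


class TestPairedTTest:
    def test_hand_computed_example(self):
        # d = {1, 0, 2}: mean 1, sd 1, t = 1/(1/sqrt(3)) = 1.7321, df = 2
        res = paired_ttest([1.0, 2.0, 3.0], [2.0, 2.0, 5.0])
        assert res.t_statistic == pytest.approx(math.sqrt(3), abs=1e-4)
        assert res.degrees_of_freedom == 2
        assert res.mean_difference == pytest.approx(1.0)
        # cross-check p against the reference implementation
        assert res.p_value == pytest.approx(
            float(sps.ttest_rel([2.0, 2.0, 5.0], [1.0, 2.0, 3.0]).pvalue), abs=1e-10
        )

    def test_constant_shift_is_degenerate(self):
        before = [1.0, 2.0, 5.0, 9.0]
        after = [4.0, 5.0, 8.0, 12.0]
        with pytest.raises(DegenerateVarianceError):
            paired_ttest(before, after)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_one_sample_test_of_differences(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(10.0, 2.0, size=12)
        d = rng.normal(0.5, 1.0, size=12)
        res = paired_ttest(x, x + d)
        ref = sps.ttest_1samp(d, 0.0)
        assert res.t_statistic == pytest.approx(float(ref.statistic), rel=1e-10)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-8)

    def test_power_on_synthetic_cohort_with_known_effect(self):
        """At the default effect size and noise, the paired test on the
        low-interaction group rejects in >= 95% of seeds."""
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            recs = [r for r in generate_growth_cohort(seed=seed) if r.group == "EXP"]
            res = paired_ttest(
                [r.weight_t0_kg for r in recs], [r.weight_t1_kg for r in recs]
            )
            rejections += res.p_value < 0.05
        assert rejections / n_seeds >= 0.95

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(2024)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            before = rng.normal(0.75, 0.1, size=15)
            after = before + rng.normal(0.0, 0.03, size=15)
            hits += paired_ttest(before, after).p_value < 0.05
        assert 0.03 <= hits / n_sim <= 0.07


class TestStudentTail:
    def test_agrees_with_reference_cdf_to_1e8(self):
        ts = np.linspace(-6.0, 6.0, 41)
        dfs = [1, 2, 3, 5, 10, 14, 29, 100]
        for df in dfs:
            for t in ts:
                assert student_t_sf2(float(t), df) == pytest.approx(
                    2.0 * float(sps.t.sf(abs(t), df)), abs=1e-8
                )


class TestTwoSampleTTest:
    def test_identical_groups_give_t0_p1(self):
        res = twosample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        res = twosample_ttest([11.0, 12.0, 13.0], [1.0, 2.0, 3.0])
        assert res.p_value < 0.01
        assert res.t_statistic > 0

    def test_welch_equals_pooled_for_balanced_equal_variance(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.5, 3.5, 4.5, 5.5]
        w = twosample_ttest(a, b, equal_variance=False)
        p = twosample_ttest(a, b, equal_variance=True)
        assert w.t_statistic == pytest.approx(p.t_statistic, rel=1e-12)
        assert w.degrees_of_freedom == pytest.approx(p.degrees_of_freedom, rel=1e-12)
        assert w.p_value == pytest.approx(p.p_value, rel=1e-12)

    def test_welch_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.5, 2.0, 14)
        res = twosample_ttest(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.t_statistic == pytest.approx(float(ref.statistic), rel=1e-10)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-8)


class TestGroupSummary:
    def test_eight_of_fifteen_gainers_is_53_33_percent(self):
        deltas = [0.1] * 8 + [-0.05] * 7
        s = summarize_group(deltas)
        assert s.gainer_percent == 53.33
        assert s.n == 15

    def test_all_positive_is_100_percent(self):
        s = summarize_group([0.05, 0.1, 0.2])
        assert s.gainer_percent == 100.0

    def test_sem_is_sd_over_sqrt_n_and_none_for_single(self):
        x = [1.0, 2.0, 3.0, 4.0]
        s = summarize_group(x)
        assert s.sem == pytest.approx(np.std(x, ddof=1) / 2.0)
        assert summarize_group([5.0]).sem is None
        with pytest.raises(ValueError):
            summarize_group([])


class TestAnalyzeCohort:
    def test_full_cohort_analysis_detects_group_difference(self):
        df = cohort_to_frame(generate_growth_cohort(seed=1))
        out = analyze_cohort(df)
        assert set(out["groups"]) == {"CTRL", "EXP"}
        exp = out["groups"]["EXP"]
        assert exp["paired_test"]["p_value"] < 0.05
        assert exp["increment_kg"]["n"] == 15
        cmp = out["increment_comparison"]
        assert cmp["groups"] == ["CTRL", "EXP"]
        # EXP gains more than CTRL at the default effects
        assert cmp["mean_difference"] < 0
        assert cmp["p_value"] < 0.05
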