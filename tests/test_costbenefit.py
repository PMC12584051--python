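"""Cost-benefit check: expected counts, worked scenario, sensitivity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aibilling.costbenefit import (
    AccuracyProfile,
    CostBenefitInputs,
    break_even_fee,
    expected_counts,
    one_way_sensitivity,
    run_check,
    staff_time_savings,
)

rates = st.floats(0.0, 1.0, allow_nan=False)


class TestExpectedCounts:
    @pytest.mark.parametrize(
        "profile, fn, fp",
        [
            (AccuracyProfile(sensitivity=0.85, specificity=0.90), 15.0, 90.0),
            (AccuracyProfile(sensitivity=0.90, specificity=0.93), 10.0, 63.0),
            (AccuracyProfile(sensitivity=1.0, specificity=1.0), 0.0, 0.0),
        ],
    )
    def test_closed_form(self, profile, fn, fp):
        counts = expected_counts(0.10, profile, 1000)
        assert counts.fn == pytest.approx(fn)
        assert counts.fp == pytest.approx(fp)

    @given(prevalence=rates, se=rates, sp=rates, n=st.integers(1, 10**6))
    @settings(max_examples=200, derandomize=True)
    def test_partitions_conserved(self, prevalence, se, sp, n):
        counts = expected_counts(
            prevalence, AccuracyProfile(sensitivity=se, specificity=sp), n
        )
        assert counts.tp + counts.fn == pytest.approx(prevalence * n)
        assert counts.fp + counts.tn == pytest.approx((1 - prevalence) * n)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            expected_counts(1.5, AccuracyProfile(sensitivity=0.9, specificity=0.9), 100)


class TestWorkedScenario:
    def test_baseline_read_out(self, baseline_inputs):
        """The default inputs reproduce the full illustrative read-out."""
        result = run_check(baseline_inputs)
        assert result.avoided_fn == pytest.approx(5.0)
        assert result.avoided_fp == pytest.approx(27.0)
        assert result.avoided_downstream_cost == pytest.approx(14050.0)
        assert result.ai_spend == pytest.approx(12000.0)
        assert result.net_payer_impact == pytest.approx(-2050.0)
        assert result.break_even_fee == pytest.approx(14.05)
        assert result.staff_hours_saved == pytest.approx(50.0)

    def test_no_accuracy_gain_means_pure_ai_cost(self, baseline_inputs):
        inputs = baseline_inputs.model_copy(update={"ai": baseline_inputs.soc})
        result = run_check(inputs)
        assert result.avoided_fn == result.avoided_fp == 0
        assert result.net_payer_impact == pytest.approx(result.ai_spend)
        assert break_even_fee(inputs) == pytest.approx(0.0)

    def test_free_ai_impact_equals_negated_avoided_cost(self, baseline_inputs):
        result = run_check(baseline_inputs.model_copy(update={"ai_fee": 0.0}))
        assert result.net_payer_impact == pytest.approx(
            -result.avoided_downstream_cost
        )

    def test_swapping_profiles_negates_avoided_counts(self, baseline_inputs):
        swapped = baseline_inputs.model_copy(
            update={"soc": baseline_inputs.ai, "ai": baseline_inputs.soc}
        )
        a, b = run_check(baseline_inputs), run_check(swapped)
        assert b.avoided_fn == pytest.approx(-a.avoided_fn)
        assert b.avoided_fp == pytest.approx(-a.avoided_fp)

    def test_per_1000_normalization(self, baseline_inputs):
        scaled = run_check(baseline_inputs.model_copy(update={"n": 5000}))
        per_1000 = scaled.per_1000()
        assert per_1000["avoided_fn"] == pytest.approx(5.0)
        assert per_1000["net_payer_impact"] == pytest.approx(-2050.0)
        assert per_1000["break_even_fee"] == pytest.approx(14.05)


class TestBreakEven:
    def test_net_impact_linear_in_fee_with_zero_at_break_even(self, baseline_inputs):
        fee_star = break_even_fee(baseline_inputs)
        at_zero = run_check(baseline_inputs.model_copy(update={"ai_fee": 0.0}))
        at_star = run_check(baseline_inputs.model_copy(update={"ai_fee": fee_star}))
        assert at_star.net_payer_impact == pytest.approx(0.0, abs=1e-9)
        # slope is exactly n
        above = run_check(
            baseline_inputs.model_copy(update={"ai_fee": fee_star + 1.0})
        )
        assert above.net_payer_impact - at_star.net_payer_impact == pytest.approx(
            baseline_inputs.n
        )
        assert at_zero.net_payer_impact == pytest.approx(-fee_star * baseline_inputs.n)

    def test_direct_division(self, baseline_inputs):
        doubled = baseline_inputs.model_copy(
            update={"cost_fn": 4000.0, "cost_fp": 300.0}
        )
        assert break_even_fee(doubled) == pytest.approx(28.10)


class TestStaffTime:
    @pytest.mark.parametrize(
        "minutes, n, hours", [(3, 1000, 50.0), (0, 1000, 0.0), (4.5, 200, 15.0)]
    )
    def test_conversion(self, minutes, n, hours):
        assert staff_time_savings(minutes, n) == pytest.approx(hours)

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValueError):
            staff_time_savings(-1, 100)


class TestOneWaySensitivity:
    def test_ai_fee_grid_hits_break_even_zero(self, baseline_inputs):
        table = one_way_sensitivity(baseline_inputs, "ai_fee", [12.0, 14.05, 16.0])
        assert list(table["net_payer_impact"]) == pytest.approx(
            [-2050.0, 0.0, 1950.0], abs=1e-8
        )

    def test_zero_fn_cost_removes_fn_contribution(self, baseline_inputs):
        table = one_way_sensitivity(baseline_inputs, "cost_fn", [0.0])
        # only the 27 avoided FPs at EUR 150 remain
        assert table["break_even_fee"][0] == pytest.approx(27 * 150 / 1000)

    def test_avoided_fn_linear_in_prevalence(self, baseline_inputs):
        grid = [0.0, 0.1, 0.2, 0.4]
        table = one_way_sensitivity(
            baseline_inputs, "prevalence", grid, extra_fields=["avoided_fn"]
        )
        # avoided FN = prevalence * n * (se_ai - se_soc) -- linear through 0
        slopes = [
            row.avoided_fn / row.value
            for row in table.itertuples()
            if row.value > 0
        ]
        assert slopes == pytest.approx([slopes[0]] * len(slopes))
        assert table["avoided_fn"][0] == pytest.approx(0.0)

    def test_accuracy_rates_addressable_by_dotted_name(self, baseline_inputs):
        table = one_way_sensitivity(baseline_inputs, "ai.sensitivity", [0.85, 0.95])
        assert table["break_even_fee"][0] < table["break_even_fee"][1]

    def test_unknown_parameter_and_empty_grid_rejected(self, baseline_inputs):
        with pytest.raises(ValueError, match="unknown parameter"):
            one_way_sensitivity(baseline_inputs, "discount_rate", [0.03])
        with pytest.raises(ValueError, match="non-empty"):
            one_way_sensitivity(baseline_inputs, "ai_fee", [])
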