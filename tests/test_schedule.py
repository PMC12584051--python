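"""Fee engine, regime presets, registry validation, table regeneration."""

from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aibilling.schedule import (
    BillingCode,
    FactorPolicyError,
    PointValueRegime,
    UnknownCodeError,
    compute_fee,
    get_regime,
    itemize_invoice,
    regenerate_table,
    tier_consistency_report,
    validate_registry,
)
from pydantic import ValidationError


class TestComputeFee:
    @pytest.mark.parametrize(
        "points, regime, factor, expected",
        [
            # statutory GOA point value reproduces the published euro amounts
            (280, "goa", 1.0, Decimal("16.32")),
            (2000, "goa", 1.0, Decimal("116.57")),
            (4400, "goa", 1.0, Decimal("256.46")),
            # EBM presets
            (100, "ebm-simplified", 1.0, Decimal("12.00")),
            (82, "ebm-2025", 1.0, Decimal("10.16")),
            # multiplier applied before cent rounding
            (280, "goa", 2.3, Decimal("37.54")),
        ],
    )
    def test_published_conversions(self, points, regime, factor, expected):
        assert compute_fee(points, get_regime(regime), factor) == expected

    @pytest.mark.parametrize("bad_points", [0, -5, 2.5, True])
    def test_rejects_non_positive_or_non_integer_points(self, bad_points, ebm_simplified):
        with pytest.raises(ValueError):
            compute_fee(bad_points, ebm_simplified)

    def test_factor_outside_regime_bounds_names_bound(self, goa):
        with pytest.raises(FactorPolicyError, match=r"3\.5"):
            compute_fee(100, goa, 4.0)
        with pytest.raises(FactorPolicyError, match=r"1\.0"):
            compute_fee(100, goa, 0.5)

    @given(points=st.integers(1, 10_000), k=st.integers(1, 20))
    @settings(max_examples=100, derandomize=True)
    def test_linearity_in_points_before_rounding(self, points, k, ebm_simplified):
        """fee(k*points) = k*fee(points) exactly when no cent rounding bites."""
        unit = Decimal(points) * ebm_simplified.euro_per_point
        assert compute_fee(k * points, ebm_simplified) == (Decimal(k) * unit).quantize(
            Decimal("0.01")
        )

    def test_base_fee_scales_with_point_value(self):
        doubled = PointValueRegime(name="double", euro_per_point=Decimal("0.24"))
        assert compute_fee(50, doubled) == 2 * compute_fee(50, get_regime("ebm-simplified"))


class TestInvoice:
    def test_base_invoice_line(self, registry, ebm_simplified):
        line = itemize_invoice("AI-202", registry, ebm_simplified)
        assert line.fee == Decimal("18.00")
        assert line.factor == 1.0
        assert line.regime == "ebm-simplified"

    def test_non_unit_factor_requires_justification(self, registry, ebm_simplified):
        with pytest.raises(ValueError, match="justification"):
            itemize_invoice("AI-101", registry, ebm_simplified, factor=1.5,
                            justification_note="")

    def test_justified_factor_recorded_on_line(self, registry, ebm_simplified):
        line = itemize_invoice(
            "AI-301", registry, ebm_simplified, factor=2.0,
            justification_note="repeat analysis, difficult trace",
        )
        assert line.fee == Decimal("24.00")
        assert line.justification_note == "repeat analysis, difficult trace"

    def test_factor_above_ai_cap_rejected(self, registry, goa):
        # the GOA band allows 2.3, but the AI policy caps invoices at 2.0
        with pytest.raises(FactorPolicyError, match="cap"):
            itemize_invoice("AI-101", registry, goa, factor=2.3,
                            justification_note="complex case")

    def test_unknown_code_rejected(self, registry, ebm_simplified):
        with pytest.raises(UnknownCodeError):
            itemize_invoice("AI-999", registry, ebm_simplified)


class TestRegistryValidation:
    def test_packaged_table_has_zero_violations(self, registry):
        assert validate_registry(registry) == []
        assert len(registry) == 5

    def test_duplicate_code_id_flagged(self, registry):
        violations = validate_registry(list(registry) + [registry[0]])
        assert [v.rule for v in violations] == ["unique_code_id"]
        assert violations[0].code_id == registry[0].code_id

    def test_prefix_level_mismatch_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="does not match"):
            BillingCode(
                code_id="AI-105", level="II", specialty="x", description="y", points=50
            )

    def test_report_is_order_independent_and_idempotent(self, registry):
        doubled = list(registry) + [registry[2]]
        first = validate_registry(doubled)
        second = validate_registry(list(reversed(doubled)))
        assert first == second == validate_registry(doubled)


class TestTableRegeneration:
    def test_reproduces_published_base_euro_column(self, registry, ebm_simplified):
        table = regenerate_table(registry, ebm_simplified)
        assert list(table["points"]) == [50, 60, 80, 150, 100]
        assert list(table["base_euro"]) == [
            Decimal("6.00"),
            Decimal("7.20"),
            Decimal("9.60"),
            Decimal("18.00"),
            Decimal("12.00"),
        ]

    def test_empty_registry_gives_empty_table(self, ebm_simplified):
        assert len(regenerate_table([], ebm_simplified)) == 0

    def test_base_euro_column_matches_fee_formula(self, registry, goa):
        table = regenerate_table(registry, goa)
        for _, row in table.iterrows():
            assert row["base_euro"] == compute_fee(int(row["points"]), goa, 1.0)


class TestTierConsistency:
    def test_packaged_off_tier_codes_flagged(self, registry):
        report = tier_consistency_report(registry)
        assert {r["code_id"] for r in report} == {"AI-102", "AI-201"}
        by_code = {r["code_id"]: r for r in report}
        assert by_code["AI-102"]["nearest_tier"] == 50
        assert by_code["AI-201"]["nearest_tier"] == 100

    def test_canonical_registry_produces_empty_report(self):
        codes = [
            BillingCode(code_id="AI-101", level="I", specialty="s",
                        description="d", points=50),
            BillingCode(code_id="AI-301", level="III", specialty="s",
                        description="d", points=150),
        ]
        assert tier_consistency_report(codes) == []
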