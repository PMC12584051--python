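"""Illustrative cost-benefit check for an AI diagnostic service.

The check compares expected misclassification counts under standard of care
(SoC) against the same pathway with AI support, prices the avoided false
negatives and false positives at flat per-event downstream costs, and nets
them against the per-case AI fee.  For a cohort of ``n`` cases with disease
prevalence ``p`` and a test with sensitivity ``se`` and specificity ``sp``:

    E[FN] = p * n * (1 - se)          E[FP] = (1 - p) * n * (1 - sp)

The payer-side result is

    net_payer_impact = ai_spend - avoided_downstream_cost

so a **negative** value is a payer saving.  The break-even AI fee is the
per-case fee at which AI spend exactly equals avoided downstream cost:
``avoided_downstream_cost / n``.  Provider impact is reported as staff time
saved (hours); it is not monetised by default.

Expected counts are kept as real numbers; rounding to whole cases is a
display concern.  This is a transparent desk check with a small, auditable
input set, not a full health-economic evaluation (no QALYs, discounting, or
cohort state modelling).
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "AccuracyProfile",
    "CostBenefitInputs",
    "ExpectedCounts",
    "CostBenefitResult",
    "expected_counts",
    "run_check",
    "break_even_fee",
    "staff_time_savings",
    "one_way_sensitivity",
    "SENSITIVITY_PARAMETERS",
]


class AccuracyProfile(BaseModel):
    """Sensitivity/specificity pair of one diagnostic pathway."""

    model_config = ConfigDict(frozen=True)

    sensitivity: float = Field(ge=0.0, le=1.0)
    specificity: float = Field(ge=0.0, le=1.0)


class CostBenefitInputs(BaseModel):
    """The minimal input set of the cost-benefit check.

    Defaults correspond to the published illustrative scenario: a
    high-volume test with 10% prevalence where AI raises sensitivity from
    0.85 to 0.90 and specificity from 0.90 to 0.93, a missed case costs
    EUR 2,000 downstream, a false alarm EUR 150, the AI fee is EUR 12 per
    case (a 100-point service at 0.12 EUR/point), and AI saves 3 staff
    minutes per case.  Results are evaluated per 1,000 cases.
    """

    model_config = ConfigDict(frozen=True)

    prevalence: float = Field(default=0.10, ge=0.0, le=1.0)
    soc: AccuracyProfile = AccuracyProfile(sensitivity=0.85, specificity=0.90)
    ai: AccuracyProfile = AccuracyProfile(sensitivity=0.90, specificity=0.93)
    cost_fn: float = Field(default=2000.0, ge=0.0)
    cost_fp: float = Field(default=150.0, ge=0.0)
    ai_fee: float = Field(default=12.0, ge=0.0)
    minutes_saved: float = Field(default=3.0, ge=0.0)
    n: int = Field(default=1000, ge=1)


class ExpectedCounts(BaseModel):
    """Expected confusion-matrix cell counts for one pathway."""

    model_config = ConfigDict(frozen=True)

    tp: float = Field(ge=0.0)
    fn: float = Field(ge=0.0)
    fp: float = Field(ge=0.0)
    tn: float = Field(ge=0.0)

    @property
    def n(self) -> float:
        return self.tp + self.fn + self.fp + self.tn


class CostBenefitResult(BaseModel):
    """Read-out of the cost-benefit check.

    Sign convention: ``net_payer_impact = ai_spend - avoided_downstream_cost``;
    positive means added payer cost, negative means a payer saving.
    """

    model_config = ConfigDict(frozen=True)

    n: int
    soc_counts: ExpectedCounts
    ai_counts: ExpectedCounts
    avoided_fn: float
    avoided_fp: float
    avoided_downstream_cost: float
    ai_spend: float
    net_payer_impact: float
    break_even_fee: float
    staff_hours_saved: float

    @model_validator(mode="after")
    def _check_identities(self) -> "CostBenefitResult":
        assert abs(
            self.net_payer_impact
            - (self.ai_spend - self.avoided_downstream_cost)
        ) < 1e-9 * max(1.0, abs(self.ai_spend))
        return self

    def per_1000(self) -> dict[str, float]:
        """The headline quantities normalized to a 1,000-case cohort."""
        scale = 1000.0 / self.n
        return {
            "avoided_fn": self.avoided_fn * scale,
            "avoided_fp": self.avoided_fp * scale,
            "avoided_downstream_cost": self.avoided_downstream_cost * scale,
            "ai_spend": self.ai_spend * scale,
            "net_payer_impact": self.net_payer_impact * scale,
            "break_even_fee": self.break_even_fee,
            "staff_hours_saved": self.staff_hours_saved * scale,
        }


def expected_counts(
    prevalence: float, profile: AccuracyProfile, n: int | float
) -> ExpectedCounts:
    """Closed-form expected TP/FN/FP/TN counts for a cohort of size n."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    diseased = prevalence * n
    healthy = (1.0 - prevalence) * n
    return ExpectedCounts(
        tp=diseased * profile.sensitivity,
        fn=diseased * (1.0 - profile.sensitivity),
        fp=healthy * (1.0 - profile.specificity),
        tn=healthy * profile.specificity,
    )


def break_even_fee(inputs: CostBenefitInputs) -> float:
    """Per-case AI fee at which avoided downstream costs equal AI spend.

    At or below this fee the payer view is cost-neutral or saving.
    """
    soc = expected_counts(inputs.prevalence, inputs.soc, inputs.n)
    ai = expected_counts(inputs.prevalence, inputs.ai, inputs.n)
    avoided = (soc.fn - ai.fn) * inputs.cost_fn + (soc.fp - ai.fp) * inputs.cost_fp
    return avoided / inputs.n


def staff_time_savings(minutes_saved: float, n: int) -> float:
    """Total staff hours saved over the cohort."""
    if minutes_saved < 0:
        raise ValueError("minutes_saved must be >= 0")
    return minutes_saved * n / 60.0


def run_check(inputs: CostBenefitInputs) -> CostBenefitResult:
    """Run the full cost-benefit check.

    Steps: expected misclassification counts under both pathways; avoided
    FN/FP; avoided downstream cost priced at flat per-event averages; AI
    spend (fee x n); net payer impact (spend minus avoided cost); the
    break-even fee; and staff time saved.
    """
    soc = expected_counts(inputs.prevalence, inputs.soc, inputs.n)
    ai = expected_counts(inputs.prevalence, inputs.ai, inputs.n)
    avoided_fn = soc.fn - ai.fn
    avoided_fp = soc.fp - ai.fp
    avoided_cost = avoided_fn * inputs.cost_fn + avoided_fp * inputs.cost_fp
    ai_spend = inputs.ai_fee * inputs.n
    return CostBenefitResult(
        n=inputs.n,
        soc_counts=soc,
        ai_counts=ai,
        avoided_fn=avoided_fn,
        avoided_fp=avoided_fp,
        avoided_downstream_cost=avoided_cost,
        ai_spend=ai_spend,
        net_payer_impact=ai_spend - avoided_cost,
        break_even_fee=avoided_cost / inputs.n,
        staff_hours_saved=staff_time_savings(inputs.minutes_saved, inputs.n),
    )


#: Input fields a one-way sensitivity analysis may vary.  Accuracy rates use
#: dotted names addressing the nested profiles.
SENSITIVITY_PARAMETERS = (
    "prevalence",
    "cost_fn",
    "cost_fp",
    "ai_fee",
    "minutes_saved",
    "n",
    "soc.sensitivity",
    "soc.specificity",
    "ai.sensitivity",
    "ai.specificity",
)


def _with_parameter(
    inputs: CostBenefitInputs, parameter: str, value: float
) -> CostBenefitInputs:
    if "." in parameter:
        profile_name, rate_name = parameter.split(".", 1)
        profile: AccuracyProfile = getattr(inputs, profile_name)
        new_profile = profile.model_copy(update={rate_name: value})
        return inputs.model_copy(update={profile_name: new_profile})
    if parameter == "n":
        value = int(value)
    return inputs.model_copy(update={parameter: value})


def one_way_sensitivity(
    inputs: CostBenefitInputs,
    parameter: str,
    grid: Sequence[float],
    extra_fields: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Vary one input over a grid, holding all others at baseline.

    Returns a DataFrame with one row per grid value and columns ``value``,
    ``net_payer_impact`` and ``break_even_fee`` (plus any extra result
    fields requested).  Supports the transparent, auditable style of the
    check: every row is a full re-run of :func:`run_check`.
    """
    if parameter not in SENSITIVITY_PARAMETERS:
        raise ValueError(
            f"unknown parameter {parameter!r}; one of {SENSITIVITY_PARAMETERS}"
        )
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    extra = list(extra_fields or [])
    rows = []
    for value in grid:
        result = run_check(_with_parameter(inputs, parameter, value))
        row = {
            "value": value,
            "net_payer_impact": result.net_payer_impact,
            "break_even_fee": result.break_even_fee,
        }
        for field in extra:
            row[field] = getattr(result, field)
        rows.append(row)
    return pd.DataFrame(rows)
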