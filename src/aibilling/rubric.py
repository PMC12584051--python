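"""Four-dimension scoring rubric for AI diagnostic decision support services.

An AI service (a diagnostic decision support system, DDSS) is rated 1-5 on
four qualitative dimensions:

* **data_complexity** -- complexity and diversity of the input data
  (1 = single, low-variance data source; 5 = multi-modal, high-resolution
  data across diverse sites and populations).
* **disease_complexity** -- intrinsic difficulty of the medical condition
  (1 = common, well-delimited condition; 5 = rare or multifactorial with a
  broad differential).
* **question_complexity** -- scope of the clinical question the AI answers
  (1 = narrow binary detection; 5 = open-ended reasoning such as
  differential diagnosis or next-step guidance).
* **ai_involvement** -- share of the diagnostic work done by the AI
  (1 = assistive pre-interpretation/triage; 5 = near-autonomous diagnostic
  report with minimal real-time human input).

The unweighted arithmetic mean of the four ratings, rounded to the nearest
integer, maps onto one of three canonical point tiers:

=============  ===========  =================================
rounded mean   tier points  tier label
=============  ===========  =================================
1 or 2         50           assistive
3              100          augmentative
4 or 5         150          high-complexity augmentative
                            or autonomous
=============  ===========  =================================

Because the rounded average is a coarse statistic, a tier assignment also
carries a *stability* flag: whether perturbing any single dimension by one
point (clipped to the 1-5 range) leaves the tier unchanged.  Stable
assignments are robust to one-rater disagreement on one dimension.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from enum import Enum
from fractions import Fraction
from typing import Iterator, Literal

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "DIMENSIONS",
    "DIMENSION_ANCHORS",
    "ScoreVector",
    "TierAssignment",
    "TierLabel",
    "Level",
    "LevelSuggestion",
    "RoundingRule",
    "validate_scores",
    "round_mean",
    "tier_for_rounded_mean",
    "assign_tier",
    "perturbation_stability",
    "perturbation_trace",
    "suggest_level",
]

#: Dimension field names in canonical order.
DIMENSIONS = (
    "data_complexity",
    "disease_complexity",
    "question_complexity",
    "ai_involvement",
)

#: Documentation anchors for the 1 and 5 endpoints of each dimension.
#: These guide human raters; they are never enforced computationally.
DIMENSION_ANCHORS: dict[str, dict[int, str]] = {
    "data_complexity": {
        1: "single, low-variance data source",
        5: "multi-modal/high-resolution data across diverse sites/populations",
    },
    "disease_complexity": {
        1: "common, well-delimited condition",
        5: "rare/multifactorial with broad differential",
    },
    "question_complexity": {
        1: "narrow/binary detection",
        5: "open-ended reasoning (differential diagnosis, next-step guidance)",
    },
    "ai_involvement": {
        1: "assistive pre-interpretation/triage",
        5: "near-autonomous diagnostic report with minimal real-time human input",
    },
}

RoundingRule = Literal["half_up", "half_even"]


class TierLabel(str, Enum):
    """Qualitative label attached to each canonical point tier."""

    assistive = "assistive"
    augmentative = "augmentative"
    high_complexity_or_autonomous = "high_complexity_or_autonomous"


class Level(str, Enum):
    """AI contribution level: assistive (I), augmentative (II), autonomous (III)."""

    I = "I"
    II = "II"
    III = "III"


class ScoreVector(BaseModel):
    """The four 1-5 dimension ratings of one AI service."""

    model_config = ConfigDict(frozen=True, strict=True)

    data_complexity: int = Field(ge=1, le=5)
    disease_complexity: int = Field(ge=1, le=5)
    question_complexity: int = Field(ge=1, le=5)
    ai_involvement: int = Field(ge=1, le=5)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return tuple(getattr(self, d) for d in DIMENSIONS)  # type: ignore[return-value]

    @classmethod
    def from_tuple(cls, values: tuple[int, int, int, int]) -> "ScoreVector":
        return cls(**dict(zip(DIMENSIONS, values)))

    def mean(self) -> Fraction:
        """Unweighted arithmetic mean of the four scores, kept exact."""
        return Fraction(sum(self.as_tuple()), len(DIMENSIONS))


class TierAssignment(BaseModel):
    """Canonical point tier assigned from the rounded mean score."""

    model_config = ConfigDict(frozen=True)

    mean_score: float = Field(ge=1.0, le=5.0)
    rounded_mean: int = Field(ge=1, le=5)
    tier_points: Literal[50, 100, 150]
    tier_label: TierLabel
    stable_under_unit_perturbation: bool


class LevelSuggestion(BaseModel):
    """Advisory contribution-level suggestion derived from the involvement score.

    The suggestion never overrides a registry entry: published code levels
    are authoritative.
    """

    model_config = ConfigDict(frozen=True)

    level: Level


_TIER_BY_ROUNDED_MEAN: dict[int, tuple[int, TierLabel]] = {
    1: (50, TierLabel.assistive),
    2: (50, TierLabel.assistive),
    3: (100, TierLabel.augmentative),
    4: (150, TierLabel.high_complexity_or_autonomous),
    5: (150, TierLabel.high_complexity_or_autonomous),
}


def validate_scores(vector: ScoreVector | dict | tuple) -> ScoreVector:
    """Validate a score vector, returning it unchanged when valid.

    Accepts a :class:`ScoreVector`, a mapping of dimension names, or a
    4-tuple in canonical dimension order.  Raises a pydantic
    ``ValidationError`` naming the offending dimension for out-of-range or
    non-integer values.
    """
    if isinstance(vector, ScoreVector):
        return vector
    if isinstance(vector, dict):
        return ScoreVector(**vector)
    return ScoreVector.from_tuple(tuple(vector))


def round_mean(mean: Fraction, rounding: RoundingRule = "half_up") -> int:
    """Round a mean score to the nearest integer.

    ``half_up`` rounds exact halves away from zero (2.5 -> 3); ``half_even``
    rounds them to the nearest even integer (banker's rounding).  Means of
    four 1-5 integers are multiples of 1/4, so only .5 fractions are
    affected by the choice.
    """
    mode = ROUND_HALF_UP if rounding == "half_up" else ROUND_HALF_EVEN
    exact = Decimal(mean.numerator) / Decimal(mean.denominator)
    return int(exact.quantize(Decimal("1"), rounding=mode))


def tier_for_rounded_mean(rounded_mean: int) -> tuple[int, TierLabel]:
    """Canonical (tier_points, label) for a rounded mean in 1..5."""
    try:
        return _TIER_BY_ROUNDED_MEAN[rounded_mean]
    except KeyError:
        raise ValueError(f"rounded mean {rounded_mean} outside 1..5") from None


def _perturbations(vector: ScoreVector) -> Iterator[tuple[str, int, ScoreVector]]:
    """All single-dimension +-1 perturbations, clipped to [1, 5]."""
    values = vector.as_tuple()
    for i, dim in enumerate(DIMENSIONS):
        for delta in (-1, +1):
            perturbed = list(values)
            perturbed[i] = min(5, max(1, perturbed[i] + delta))
            yield dim, delta, ScoreVector.from_tuple(tuple(perturbed))


def perturbation_trace(
    vector: ScoreVector, rounding: RoundingRule = "half_up"
) -> list[dict]:
    """Per-perturbation record of the +-1 stability check.

    Returns one entry per (dimension, delta) pair with the perturbed score
    (after clipping to [1, 5]), whether clipping occurred, and the tier the
    perturbed vector maps to.  Useful for audit output; the boolean summary
    is :func:`perturbation_stability`.
    """
    vector = validate_scores(vector)
    base_tier, _ = tier_for_rounded_mean(round_mean(vector.mean(), rounding))
    trace = []
    for dim, delta, perturbed in _perturbations(vector):
        tier, _ = tier_for_rounded_mean(round_mean(perturbed.mean(), rounding))
        trace.append(
            {
                "dimension": dim,
                "delta": delta,
                "perturbed_score": getattr(perturbed, dim),
                "clipped": getattr(perturbed, dim) == getattr(vector, dim),
                "tier_points": tier,
                "tier_changed": tier != base_tier,
            }
        )
    return trace


def perturbation_stability(
    vector: ScoreVector, rounding: RoundingRule = "half_up"
) -> bool:
    """True iff no single-dimension +-1 perturbation changes the tier."""
    return not any(step["tier_changed"] for step in perturbation_trace(vector, rounding))


def assign_tier(
    vector: ScoreVector | dict | tuple, rounding: RoundingRule = "half_up"
) -> TierAssignment:
    """Assign the canonical point tier for a score vector.

    Computes the unweighted mean of the four dimension scores, rounds it
    (``half_up`` by default), maps the rounded mean through the canonical
    tier table, and runs the +-1 perturbation stability check.
    """
    vector = validate_scores(vector)
    mean = vector.mean()
    rounded = round_mean(mean, rounding)
    points, label = tier_for_rounded_mean(rounded)
    return TierAssignment(
        mean_score=float(mean),
        rounded_mean=rounded,
        tier_points=points,
        tier_label=label,
        stable_under_unit_perturbation=perturbation_stability(vector, rounding),
    )


def suggest_level(vector: ScoreVector | dict | tuple) -> LevelSuggestion:
    """Advisory AI contribution level from the involvement score alone.

    Involvement 1-2 suggests Level I (assistive), 3-4 Level II
    (augmentative), and 5 Level III (autonomous).  Level III is only ever
    suggested at the maximum involvement score; a published registry entry
    always takes precedence over this suggestion.
    """
    vector = validate_scores(vector)
    involvement = vector.ai_involvement
    if involvement <= 2:
        level = Level.I
    elif involvement <= 4:
        level = Level.II
    else:
        level = Level.III
    return LevelSuggestion(level=level)
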