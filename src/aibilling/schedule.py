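"""Billing-code registry, point-value regimes, and the fee formula.

A reimbursement fee for an AI diagnostic service is computed as

    fee = points x point value x factor

where *points* come from a published code registry, the *point value* is a
regime-specific euro-per-point conversion, and *factor* is a case-complexity
multiplier visible on the invoice.  Three regime presets ship with the
package:

* ``goa``            -- German private fee schedule (GOA): statutory point
                        value 0.0582873 EUR/point, multipliers 1.0-3.5
                        (typical 2.3).
* ``ebm-simplified`` -- statutory-insurance orientation value rounded to
                        0.12 EUR/point, the value used throughout the
                        published AI code table.
* ``ebm-2025``       -- the 2025 orientation value 0.123934 EUR/point
                        (reproduces the printed 10.16 EUR for an 82-point
                        chest X-ray interpretation).

Money is held as :class:`decimal.Decimal`; cent rounding (half-up) happens
once, at the final fee.  Intermediate products are exact.

Factor policy: under the default AI billing policy the multiplier is capped
at 2.0 and any factor other than 1.0 requires a written justification that
is recorded on the fee line.
"""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .rubric import Level

__all__ = [
    "CANONICAL_TIERS",
    "DEFAULT_AI_FACTOR_CAP",
    "BillingCode",
    "PointValueRegime",
    "FeeLine",
    "RegistryViolation",
    "FactorPolicyError",
    "UnknownCodeError",
    "REGIME_PRESETS",
    "get_regime",
    "packaged_registry",
    "compute_fee",
    "itemize_invoice",
    "validate_registry",
    "regenerate_table",
    "tier_consistency_report",
]

#: The fixed canonical point tiers of the scoring rubric.
CANONICAL_TIERS = (50, 100, 150)

#: Maximum multiplier allowed for AI codes without an explicit policy override.
DEFAULT_AI_FACTOR_CAP = 2.0

_CODE_PATTERN = re.compile(r"^AI-([123])\d{2}$")
_LEVEL_DIGIT = {"1": Level.I, "2": Level.II, "3": Level.III}
_CENT = Decimal("0.01")


class FactorPolicyError(ValueError):
    """Raised when a fee multiplier violates regime bounds or the AI policy."""


class UnknownCodeError(KeyError):
    """Raised when a billing code id is not present in the registry."""


class BillingCode(BaseModel):
    """One entry of the AI billing-code registry.

    Code ids follow the pattern ``AI-Lxx`` where ``L`` is the contribution
    level digit (1 = assistive, 2 = augmentative, 3 = autonomous); the digit
    must agree with the ``level`` field.
    """

    model_config = ConfigDict(frozen=True)

    code_id: str
    level: Level
    specialty: str
    description: str
    points: int = Field(gt=0)

    @field_validator("code_id")
    @classmethod
    def _check_pattern(cls, v: str) -> str:
        if not _CODE_PATTERN.match(v):
            raise ValueError(
                f"code_id {v!r} does not match 'AI-' + level digit + two digits"
            )
        return v

    @model_validator(mode="after")
    def _check_prefix_level(self) -> "BillingCode":
        digit = self.code_id[3]
        if _LEVEL_DIGIT[digit] != self.level:
            raise ValueError(
                f"code_id {self.code_id} prefix digit {digit} does not match "
                f"level {self.level.value}"
            )
        return self


class PointValueRegime(BaseModel):
    """A named euro-per-point conversion with a multiplier policy."""

    model_config = ConfigDict(frozen=True)

    name: str
    euro_per_point: Decimal = Field(gt=0)
    factor_min: float = 1.0
    factor_max: float = 1.0
    typical_factor: float = 1.0

    @model_validator(mode="after")
    def _check_factor_order(self) -> "PointValueRegime":
        if not (self.factor_min <= self.typical_factor <= self.factor_max):
            raise ValueError(
                f"regime {self.name}: require factor_min <= typical_factor "
                f"<= factor_max, got {self.factor_min}/{self.typical_factor}"
                f"/{self.factor_max}"
            )
        return self


class FeeLine(BaseModel):
    """One itemized invoice line: code, multiplier, and the resulting fee.

    The multiplier (factor) is always recorded explicitly so that any
    deviation from the base fee is publicly visible on the invoice; a
    non-unit factor must carry a justification note.
    """

    model_config = ConfigDict(frozen=True)

    code_id: str
    points: int = Field(gt=0)
    regime: str
    factor: float
    fee: Decimal
    justification_note: Optional[str] = None

    @model_validator(mode="after")
    def _check_justification(self) -> "FeeLine":
        if self.factor != 1.0 and not (self.justification_note or "").strip():
            raise ValueError(
                f"factor {self.factor} != 1.0 requires a justification note"
            )
        return self


class RegistryViolation(BaseModel):
    """A single rule violation found while validating a registry."""

    model_config = ConfigDict(frozen=True)

    code_id: str
    rule: str
    message: str


#: Regime presets.  The GOA point value is the statutory 0.0582873 EUR
#: (the commonly quoted "about 0.058" is a rounding of it); only the exact
#: statutory value reproduces the published GOA euro amounts.
REGIME_PRESETS: dict[str, PointValueRegime] = {
    regime.name: regime
    for regime in (
        PointValueRegime(
            name="goa",
            euro_per_point=Decimal("0.0582873"),
            factor_min=1.0,
            factor_max=3.5,
            typical_factor=2.3,
        ),
        PointValueRegime(
            name="ebm-simplified",
            euro_per_point=Decimal("0.12"),
            factor_min=1.0,
            factor_max=DEFAULT_AI_FACTOR_CAP,
            typical_factor=1.0,
        ),
        PointValueRegime(
            name="ebm-2025",
            euro_per_point=Decimal("0.123934"),
            factor_min=1.0,
            factor_max=DEFAULT_AI_FACTOR_CAP,
            typical_factor=1.0,
        ),
    )
}


def get_regime(name: str) -> PointValueRegime:
    """Look up a preset regime by name."""
    try:
        return REGIME_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown regime {name!r}; presets: {sorted(REGIME_PRESETS)}"
        ) from None


def packaged_registry() -> list[BillingCode]:
    """The five-code AI billing table shipped with the package."""
    from . import io_  # local import to avoid a cycle

    with resources.as_file(
        resources.files("aibilling.data") / "ai_codes.csv"
    ) as path:
        return io_.read_code_table(path)


def compute_fee(
    points: int, regime: PointValueRegime, factor: float = 1.0
) -> Decimal:
    """Fee = points x euro-per-point x factor, rounded half-up to cents.

    The factor must lie within the regime's [factor_min, factor_max] band.
    """
    if not isinstance(points, int) or isinstance(points, bool) or points <= 0:
        raise ValueError(f"points must be a positive integer, got {points!r}")
    if not (regime.factor_min <= factor <= regime.factor_max):
        raise FactorPolicyError(
            f"factor {factor} outside regime {regime.name!r} bounds "
            f"[{regime.factor_min}, {regime.factor_max}]"
        )
    exact = Decimal(points) * regime.euro_per_point * Decimal(str(factor))
    return exact.quantize(_CENT, rounding=ROUND_HALF_UP)


def _find_code(registry: Sequence[BillingCode], code_id: str) -> BillingCode:
    for code in registry:
        if code.code_id == code_id:
            return code
    raise UnknownCodeError(f"code {code_id!r} not found in registry")


def itemize_invoice(
    code_id: str,
    registry: Sequence[BillingCode],
    regime: PointValueRegime,
    factor: float = 1.0,
    justification_note: Optional[str] = None,
    ai_factor_cap: float = DEFAULT_AI_FACTOR_CAP,
) -> FeeLine:
    """Produce one auditable invoice line for a registered AI code.

    Enforces the transparency rules of the AI billing policy: the factor is
    recorded on the line; a factor other than 1.0 requires a non-empty
    justification note; and factors above ``ai_factor_cap`` (2.0 by
    default) are rejected even when the regime's own band is wider.
    """
    code = _find_code(registry, code_id)
    if factor > ai_factor_cap:
        raise FactorPolicyError(
            f"factor {factor} exceeds the AI policy cap of {ai_factor_cap}"
        )
    if factor != 1.0 and not (justification_note or "").strip():
        raise ValueError(
            f"factor {factor} != 1.0 requires a justification note "
            f"(code {code_id})"
        )
    fee = compute_fee(code.points, regime, factor)
    return FeeLine(
        code_id=code.code_id,
        points=code.points,
        regime=regime.name,
        factor=factor,
        fee=fee,
        justification_note=justification_note,
    )


def validate_registry(registry: Iterable[BillingCode]) -> list[RegistryViolation]:
    """Check registry-wide consistency rules; empty list means valid.

    Per-code rules (positive points, code pattern, prefix/level agreement)
    are enforced at construction time by :class:`BillingCode`; this check
    re-verifies them for codes built before a rule change and adds the
    cross-code uniqueness rule.  The report is independent of code order.
    """
    violations: list[RegistryViolation] = []
    seen: dict[str, int] = {}
    for code in registry:
        seen[code.code_id] = seen.get(code.code_id, 0) + 1
        digit = code.code_id[3] if len(code.code_id) > 3 else ""
        if _LEVEL_DIGIT.get(digit) != code.level:
            violations.append(
                RegistryViolation(
                    code_id=code.code_id,
                    rule="prefix_level",
                    message=f"prefix digit {digit!r} does not match level "
                    f"{code.level.value}",
                )
            )
        if code.points <= 0:
            violations.append(
                RegistryViolation(
                    code_id=code.code_id,
                    rule="positive_points",
                    message=f"points must be positive, got {code.points}",
                )
            )
    for code_id, count in sorted(seen.items()):
        if count > 1:
            violations.append(
                RegistryViolation(
                    code_id=code_id,
                    rule="unique_code_id",
                    message=f"code id appears {count} times",
                )
            )
    return violations


def regenerate_table(
    registry: Sequence[BillingCode], regime: PointValueRegime
) -> pd.DataFrame:
    """Rebuild the public billing table with base (factor 1.0) euro fees.

    Columns: ``code_id, level, specialty, description, points, base_euro``.
    The base-euro column equals ``compute_fee(points, regime, 1.0)`` for
    every row.
    """
    rows = [
        {
            "code_id": code.code_id,
            "level": code.level.value,
            "specialty": code.specialty,
            "description": code.description,
            "points": code.points,
            "base_euro": compute_fee(code.points, regime, 1.0),
        }
        for code in registry
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "code_id",
            "level",
            "specialty",
            "description",
            "points",
            "base_euro",
        ],
    )


def tier_consistency_report(
    registry: Sequence[BillingCode],
) -> list[dict]:
    """Flag codes whose point values sit outside the canonical tiers.

    The rubric assigns tiers from the fixed set {50, 100, 150}, but the
    published registry may deviate (anchoring a code to an existing
    comparator, for instance).  Registry values are authoritative; flagged
    codes are annotated as deliberate, registry-authoritative deviations
    together with the nearest canonical tier.
    """
    report = []
    for code in registry:
        if code.points not in CANONICAL_TIERS:
            nearest = min(CANONICAL_TIERS, key=lambda t: abs(t - code.points))
            report.append(
                {
                    "code_id": code.code_id,
                    "points": code.points,
                    "nearest_tier": nearest,
                    "note": "registry-authoritative deviation from canonical tiers",
                }
            )
    return report
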