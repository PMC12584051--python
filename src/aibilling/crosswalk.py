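"""Translating the point schedule into RVU and capitation payment systems.

The point scale is currency-neutral: only the *ratios* between services are
fixed.  Two standard translations are supported.

**RVU fee-for-service** (e.g. US Medicare RBRVS).  Points map linearly into
relative value units through an anchor-calibrated slope kappa:

    RVU = kappa * points            payment = RVU * CF

where CF is the local dollar-per-RVU conversion factor.  Kappa is chosen so
that one or more AI services align with established valuations (a 100-point
autonomous screening anchored to an existing autonomous-AI procedure code,
for instance).  With a single anchor kappa is the exact ratio rvu/points;
with several anchors it is the least-squares slope through the origin (RVU
must vanish at zero points), and per-anchor residuals are reported.

**Capitation** (e.g. per-member-per-month add-ons).  A service used at rate
``u`` per eligible member per year, in a care pathway covering a fraction
``rho`` of members, adds

    PMPM = rho * u * points * point_value / 12

to the monthly capitation rate.

An RVU may optionally be split into work / practice-expense / malpractice
components; the split fractions are user-supplied and must sum to 1 (no
default split is assumed).  Outputs carry a currency tag; no exchange-rate
conversion is performed.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "CrosswalkAnchor",
    "KappaCalibration",
    "CapitationInputs",
    "calibrate_kappa",
    "map_payment",
    "split_rvu",
    "pmpm",
    "quality_linked_bonus",
]


class CrosswalkAnchor(BaseModel):
    """One points-to-RVU anchor.

    Supply either the RVU directly or a (payment, conversion_factor) pair,
    from which the implied RVU is payment / conversion_factor.
    """

    model_config = ConfigDict(frozen=True)

    label: str = ""
    points: int = Field(gt=0)
    rvu: Optional[float] = Field(default=None, gt=0)
    payment: Optional[float] = Field(default=None, gt=0)
    conversion_factor: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_one_form(self) -> "CrosswalkAnchor":
        has_rvu = self.rvu is not None
        has_pair = self.payment is not None and self.conversion_factor is not None
        partial_pair = (self.payment is None) != (self.conversion_factor is None)
        if partial_pair:
            raise ValueError(
                "payment and conversion_factor must be supplied together"
            )
        if has_rvu == has_pair:
            raise ValueError(
                "supply exactly one of rvu or (payment, conversion_factor)"
            )
        return self

    @property
    def implied_rvu(self) -> float:
        if self.rvu is not None:
            return self.rvu
        return self.payment / self.conversion_factor  # type: ignore[operator]


class KappaCalibration(BaseModel):
    """Fitted RVU-per-point slope and per-anchor residuals."""

    model_config = ConfigDict(frozen=True)

    kappa: float = Field(gt=0)
    #: implied_rvu - kappa * points, per anchor (fit order preserved)
    residuals: tuple[float, ...]
    anchor_labels: tuple[str, ...] = ()


class CapitationInputs(BaseModel):
    """Inputs of the per-member-per-month capitation add-on."""

    model_config = ConfigDict(frozen=True)

    rho: float = Field(ge=0.0, le=1.0, description="pathway prevalence")
    u: float = Field(ge=0.0, description="expected uses per eligible member-year")
    points: int = Field(gt=0)
    euro_per_point: float = Field(gt=0)


def calibrate_kappa(anchors: Sequence[CrosswalkAnchor]) -> KappaCalibration:
    """Fit kappa (RVU per point) from one or more anchors.

    A single anchor gives kappa = rvu / points exactly (zero residual).
    Several anchors give the ordinary-least-squares slope through the
    origin, kappa = sum(points * rvu) / sum(points^2), with per-anchor
    residuals ``implied_rvu - kappa * points``.
    """
    if len(anchors) == 0:
        raise ValueError("at least one anchor is required")
    rvus = [a.implied_rvu for a in anchors]
    if any(r <= 0 for r in rvus):
        raise ValueError("every anchor must imply a positive RVU")
    pts = [a.points for a in anchors]
    kappa = sum(p * r for p, r in zip(pts, rvus)) / sum(p * p for p in pts)
    residuals = tuple(r - kappa * p for p, r in zip(pts, rvus))
    return KappaCalibration(
        kappa=kappa,
        residuals=residuals,
        anchor_labels=tuple(a.label for a in anchors),
    )


def map_payment(points: int, kappa: float, conversion_factor: float) -> float:
    """Payment = (kappa * points) * CF, in the conversion factor's currency."""
    if kappa <= 0 or conversion_factor <= 0:
        raise ValueError("kappa and conversion_factor must be positive")
    if points < 0:
        raise ValueError("points must be non-negative")
    return kappa * points * conversion_factor


def split_rvu(rvu: float, fractions: dict[str, float]) -> dict[str, float]:
    """Split a total RVU into named components (work/PE/malpractice).

    ``fractions`` must sum to 1 (within 1e-9); no default split is assumed
    because the allocation depends on the level of AI involvement and is a
    policy choice.
    """
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"component fractions must sum to 1, got {total}")
    return {name: rvu * frac for name, frac in fractions.items()}


def pmpm(inputs: CapitationInputs) -> float:
    """Per-member-per-month add-on: rho * u * points * point_value / 12."""
    return inputs.rho * inputs.u * inputs.points * inputs.euro_per_point / 12.0


def quality_linked_bonus(*args, **kwargs):
    """Extension hook for quality-linked capitation bonuses.

    Bonuses keyed to verifiable outcome thresholds (e.g. avoided false
    negatives per 1,000 cases) are a recognised design direction, but no
    formula is standardised; this hook exists so integrations have a stable
    name to override.
    """
    raise NotImplementedError(
        "quality-linked bonuses are an extension point; no standard formula "
        "is defined"
    )
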