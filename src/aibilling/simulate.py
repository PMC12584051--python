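"""Monte-Carlo cohort and synthetic registry generation.

The cost-benefit check uses closed-form expected counts; this module
verifies them by simulation.  Each case draws a disease status
``Bernoulli(prevalence)``; given the status, each pathway (standard of care
and AI) returns a positive result with probability equal to its sensitivity
(diseased) or one minus its specificity (non-diseased).  The two pathways
are drawn independently given disease status by default: only marginal
accuracies are specified, and between-pathway correlation changes the
variance of paired comparisons but not any expectation.  An optional
``correlation`` parameter (Gaussian-copula on the latent uniforms) is
provided for variance studies.

All randomness flows through one seeded ``numpy.random.Generator``, so a
fixed seed reproduces cohorts and registries bit-for-bit.

The module also generates synthetic billing-code registries for exercising
the schedule machinery at sizes beyond the packaged five-code table.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.stats import norm

from .costbenefit import AccuracyProfile, ExpectedCounts
from .rubric import Level
from .schedule import CANONICAL_TIERS, BillingCode

__all__ = [
    "CohortParams",
    "CaseRecord",
    "simulate_cohort",
    "empirical_counts",
    "generate_registry_fixture",
]

COHORT_COLUMNS = ("diseased", "soc_positive", "ai_positive")


class CohortParams(BaseModel):
    """Parameters of one simulated diagnostic cohort."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=1)
    prevalence: float = Field(ge=0.0, le=1.0)
    soc: AccuracyProfile
    ai: AccuracyProfile
    seed: int
    #: Gaussian-copula correlation between the two pathways' test draws,
    #: conditional on disease status.  0 = independent (default).
    correlation: float = Field(default=0.0, ge=-1.0, le=1.0)


class CaseRecord(NamedTuple):
    """One simulated case: disease status and both test results."""

    diseased: bool
    soc_positive: bool
    ai_positive: bool


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a cohort; returns a boolean DataFrame, one row per case.

    Columns: ``diseased, soc_positive, ai_positive``.  Iterate
    ``df.itertuples(index=False, name="CaseRecord")`` for per-case records.
    """
    rng = np.random.default_rng(params.seed)
    diseased = rng.random(params.n) < params.prevalence

    # P(positive | status) per pathway
    p_soc = np.where(diseased, params.soc.sensitivity, 1.0 - params.soc.specificity)
    p_ai = np.where(diseased, params.ai.sensitivity, 1.0 - params.ai.specificity)

    if params.correlation == 0.0:
        soc_positive = rng.random(params.n) < p_soc
        ai_positive = rng.random(params.n) < p_ai
    else:
        # Correlated uniforms via a Gaussian copula; marginals unchanged.
        rho = params.correlation
        z1 = rng.standard_normal(params.n)
        z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(params.n)
        soc_positive = norm.cdf(z1) < p_soc
        ai_positive = norm.cdf(z2) < p_ai

    return pd.DataFrame(
        {
            "diseased": diseased,
            "soc_positive": soc_positive,
            "ai_positive": ai_positive,
        }
    )


def empirical_counts(cohort: pd.DataFrame) -> dict[str, ExpectedCounts]:
    """Tabulate the confusion matrix of each pathway from a simulated cohort.

    Returns ``{"soc": counts, "ai": counts}``; each pathway's four cells
    sum to the cohort size.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    diseased = cohort["diseased"].to_numpy(dtype=bool)
    out = {}
    for arm, col in (("soc", "soc_positive"), ("ai", "ai_positive")):
        positive = cohort[col].to_numpy(dtype=bool)
        out[arm] = ExpectedCounts(
            tp=float(np.sum(diseased & positive)),
            fn=float(np.sum(diseased & ~positive)),
            fp=float(np.sum(~diseased & positive)),
            tn=float(np.sum(~diseased & ~positive)),
        )
    return out


_SPECIALTIES = (
    "Radiology-X-ray",
    "Ultrasound imaging",
    "Laboratory diagnostics",
    "Pathology-Histology",
    "Cardiology-ECG",
    "Dermatology imaging",
    "Ophthalmology-Fundus",
)

_LEVEL_DESCRIPTIONS = {
    Level.I: "Assistive AI pre-interpretation (synthetic fixture code)",
    Level.II: "Augmentative AI review support (synthetic fixture code)",
    Level.III: "Autonomous AI reporting (synthetic fixture code)",
}


def generate_registry_fixture(
    k: int, seed: int, rng: Optional[np.random.Generator] = None
) -> list[BillingCode]:
    """Generate ``k`` synthetic, mutually consistent billing codes.

    Codes cycle through the three contribution levels (so any fixture with
    k >= 3 spans all levels) and draw points from the canonical tiers; code
    numbers are unique within each level.  The output always passes
    registry validation with zero violations.  Intended as test scaffolding,
    not as a proposed schedule.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 300:
        raise ValueError("at most 300 codes (100 two-digit suffixes per level)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    levels = [Level.I, Level.II, Level.III]
    counters = {Level.I: 0, Level.II: 0, Level.III: 0}
    codes = []
    for i in range(k):
        level = levels[i % 3]
        suffix = counters[level]
        counters[level] += 1
        digit = {"I": "1", "II": "2", "III": "3"}[level.value]
        points = int(rng.choice(CANONICAL_TIERS))
        specialty = str(rng.choice(_SPECIALTIES))
        codes.append(
            BillingCode(
                code_id=f"AI-{digit}{suffix:02d}",
                level=level,
                specialty=specialty,
                description=_LEVEL_DESCRIPTIONS[level],
                points=points,
            )
        )
    return codes
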