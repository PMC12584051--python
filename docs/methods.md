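# Methods

## The model

`aibilling` prices AI diagnostic decision support along a chain of four
small, auditable models. Nothing in the chain is statistical estimation;
every step is a documented deterministic mapping, which is the point: fee
schedules must be reproducible by all parties from published inputs.

### Scoring rubric and canonical tiers

An AI service is rated by a human evaluator on four dimensions, each on an
integer 1–5 scale with documented endpoint anchors (carried in
`rubric.DIMENSION_ANCHORS`): data complexity/diversity, disease complexity,
clinical-question complexity, and degree of AI involvement. The tier score
is the **unweighted** arithmetic mean of the four ratings — the rubric
deliberately avoids weights, which would invite gaming and are hard to
justify across specialties. The rounded mean maps to a fixed tier set:

| rounded mean | tier | label |
|---|---|---|
| 1–2 | 50 points | assistive |
| 3 | 100 points | augmentative |
| 4–5 | 150 points | high-complexity augmentative or autonomous |

A small fixed tier set (rather than paying the continuous score directly)
trades resolution for predictability and resistance to upcoding.

**Rounding.** Means of four integers are multiples of 0.25, so the only
ambiguous cases are exact halves (x.5). The default rule is round half away
from zero (2.5 → 3), chosen because it is deterministic, simple to state in
a fee schedule, and treats the half-point as evidence of the higher
complexity band. `half_even` (banker's rounding) is available as a config
option for schedules that prefer bias-free rounding; the choice only
matters for mean scores of exactly 2.5 or 3.5 (a 4.5 mean stays in the
150-point tier under both rules).

**Stability check.** A tier assignment is flagged *stable* when perturbing
any single dimension by ±1 (clipped to [1, 5]; clipping is reported in the
perturbation trace) leaves the tier unchanged. This models one-rater
disagreement on one dimension. Clipping at the scale ends is the natural
choice: a score of 5 cannot meaningfully be "rated one higher". Unstable
assignments are not rejected — the flag is advisory input to a human
schedule committee.

**Level suggestion.** AI involvement 1–2 suggests contribution Level I
(assistive, `AI-1xx` codes), 3–4 Level II (augmentative, `AI-2xx`), and 5
Level III (autonomous, `AI-3xx`). The mapping is advisory plumbing: the
published registry's level is always authoritative, because levels encode
regulatory posture (e.g. oversight requirements), not just the involvement
score. Level III is only ever suggested at the maximum involvement score.

### Fee engine

`fee = points × point value × factor`, with money held as exact decimals
and half-up rounding to cents applied once, at the final fee. The factor
multiplies the unrounded product; rounding earlier could shift a fee by a
cent at some multipliers, and which order a real schedule intends is a
policy detail — the chosen order is documented here and fixed.

Regime presets:

| regime | €/point | factors | note |
|---|---|---|---|
| `goa` | 0.0582873 | 1.0–3.5, typical 2.3 | the statutory point value; the commonly quoted "≈0.058" is a rounding of it and does not reproduce published euro amounts |
| `ebm-simplified` | 0.12 | 1.0–2.0 | the rounded orientation value used in the published AI code table |
| `ebm-2025` | 0.123934 | 1.0–2.0 | 2025 orientation value (82 points → €10.16) |

Invoice itemization enforces the transparency policy: the factor is always
recorded on the fee line, any factor ≠ 1.0 requires a non-empty written
justification, and AI invoices are capped at 2.0× by default even where the
legacy regime band is wider (the cap is a parameter, but overrides are the
caller's explicit, visible choice). Registry validation checks code-id
uniqueness, the prefix/level agreement (`AI-1xx` ⇔ Level I, etc.), and
positive points; it is report-based, idempotent, and order-independent.

Registry points are authoritative over rubric tiers. The packaged table
deliberately contains two off-tier codes (60 and 80 points) anchored to
existing comparator valuations; `tier_consistency_report` flags them as
registry-authoritative deviations rather than errors.

### Cost–benefit check

For a cohort of `n` cases with prevalence `p` and a test with sensitivity
`se` / specificity `sp`:

    E[FN] = p·n·(1−se)        E[FP] = (1−p)·n·(1−sp)

Avoided downstream cost = ΔFN·cost_FN + ΔFP·cost_FP with flat per-event
averages (no discounting or risk adjustment — downstream costs enter as the
transparent averages a payer would put in a desk check). The sign
convention is

    net_payer_impact = ai_spend − avoided_downstream_cost

so negative values are payer savings; every report states the convention.
The break-even fee is `avoided_downstream_cost / n`, the unique zero of the
net impact, which is linear in the AI fee with slope `n`. Expected counts
are kept as reals; rounding to whole cases is display-only. Provider impact
is reported as staff hours saved (minutes × n / 60), not monetised by
default — a wage rate would add an assumption the check does not need.

Default inputs (a representative high-volume scenario): prevalence 0.10,
SoC accuracy 0.85/0.90, with-AI 0.90/0.93, €2,000 per false negative, €150
per false positive, €12 AI fee per case, 3 staff minutes saved per case,
n = 1,000. These defaults give avoided FN 5, avoided FP 27, net payer
impact −€2,050, break-even €14.05, 50 staff hours. Results are also
normalised per 1,000 cases regardless of the requested `n`.

This is explicitly **not** a health-economic evaluation: no QALYs,
discounting, utilisation feedback, or cohort state transitions.

### Crosswalks

RVU mapping is linear through the origin: `RVU = κ·points`. With one anchor
κ is the exact ratio; with several, the ordinary-least-squares slope
through the origin, `κ = Σ(pᵢrᵢ)/Σ(pᵢ²)`, because an RVU must vanish at
zero points (an intercept would break the ratio-preservation property that
motivates the point scale). Per-anchor residuals are reported; no residual
acceptance threshold is imposed — anchor conflict is a policy judgement.
Volume-weighting of anchors is possible by repeating anchors; a dedicated
weight field was considered and left out until a use case defines its
semantics. An RVU may be split into work/practice-expense/malpractice
components only with user-supplied fractions summing to 1; no default split
is invented.

Capitation: `PMPM = ρ·u·points·point_value/12`, where ρ is the fraction of
members in the care pathway and `u` the expected uses per eligible
member-year. Quality-linked bonuses are a named `NotImplementedError` hook:
no standard formula exists yet.

Outputs carry a currency tag; there is no FX conversion.

## Synthetic data

`simulate_cohort` draws disease status `Bernoulli(p)` per case and, given
status, positive results per pathway with probability `se` (diseased) or
`1−sp` (healthy). Both pathways are drawn **independently given disease
status** by default: the check only specifies marginal accuracies, and
correlation between pathways affects the variance of paired comparisons but
no expectation — and the fee and break-even computations depend on
expectations only. A Gaussian-copula `correlation` parameter is provided
for variance studies. All randomness flows through one seeded
`numpy.random.Generator`; a fixed seed reproduces cohorts bit-for-bit.

What the simulation does *not* emulate: real cohorts have case-mix
heterogeneity (per-case prevalence and accuracy), clustered sampling,
verification bias, and cost distributions rather than flat averages.
Passing Monte-Carlo tests therefore shows the closed forms are implemented
correctly, not that the closed forms describe any particular clinical
pathway. Test cohorts use n = 10⁵ (2×10⁵ for the paired-difference check),
where 3-standard-error bands are tight enough to catch a swapped rate while
the whole suite stays in a few seconds.

`generate_registry_fixture` builds synthetic registries cycling through the
three levels with canonical-tier points; it exists to exercise the schedule
machinery at sizes beyond the packaged five-code table and always satisfies
every registry invariant.

## Numerical choices

- Money: `decimal.Decimal` end to end; cent rounding half-up once, at the
  final fee; JSON serialises money as strings so reports round-trip
  cent-exactly.
- Mean rounding: exact rational mean (`fractions.Fraction`) quantised with
  `decimal` — no binary-float half-point artefacts.
- κ calibration: closed form; numerically trivial at realistic anchor
  counts (cross-checked in tests against `numpy.linalg.lstsq` and a grid
  search).
- Degenerate inputs: zero-point fees are rejected as a precondition (the
  formula is linear, so the limit is €0.00); empty cohorts and empty anchor
  lists raise; prevalence 0 or 1 and perfect accuracy are valid and exact.

## Known limitations

- The rubric scores are human judgements; the package validates and maps
  them but cannot derive them from device documentation.
- The packaged registry is a five-code illustrative excerpt, not a legal
  fee schedule; the GOÄ/EBM presets cover only the point values, not the
  catalogues.
- The cost–benefit check is a desk-scale screening tool (see above).
- Published per-code dimension ratings behind the packaged table are not
  available, so tier stability for those specific services can only be
  tested on hypothetical score vectors.
- One published EBM comparator (a 534-point service quoted at €66.20) is
  inconsistent with the point value implied by the other published
  comparator (534 × 0.123934 = €66.18); it is not used as a reference
  value anywhere in the package.
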