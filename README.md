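# aibilling

Point-based reimbursement modelling for AI diagnostic decision support
systems (DDSS).

AI tools that triage chest X-rays, pre-read ECGs, or flag suspicious regions
on pathology slides deliver measurable clinical value, but most fee
schedules have no code to bill them under. `aibilling` implements a
structured way to close that gap, for health economists, payers, and
developers of diagnostic AI who need to price such services inside existing
billing systems (the German GOÄ/EBM point schedules, US RVU fee-for-service,
or capitation):

1. **Scoring rubric** — an AI service is rated 1–5 on four dimensions
   (data complexity/diversity, disease complexity, clinical-question
   complexity, degree of AI involvement). The unweighted mean, rounded,
   maps to a canonical point tier: rounded mean 1–2 → **50 points**
   (assistive), 3 → **100** (augmentative), 4–5 → **150** (high-complexity
   augmentative or autonomous), with a ±1 perturbation-stability check.
2. **Fee engine** — a billing-code registry (codes `AI-1xx`/`AI-2xx`/`AI-3xx`
   for assistive/augmentative/autonomous services) and the fee formula

   ```
   fee = points × point value × factor
   ```

   with regime presets (GOÄ statutory 0.0582873 €/pt with 1.0–3.5×
   multipliers; EBM orientation values 0.12 and 0.123934 €/pt), invoice
   itemization with mandatory factor justification, and registry validation.
3. **Cost–benefit check** — expected false negatives/positives under
   standard of care vs. AI (`E[FN] = p·n·(1−se)`, `E[FP] = (1−p)·n·(1−sp)`),
   avoided downstream costs, net payer impact, break-even AI fee, and staff
   time saved; plus one-way sensitivity analysis.
4. **Crosswalks** — anchor-calibrated mapping into RVU systems
   (`RVU = κ·points`, `payment = RVU × CF`) and capitation add-ons
   (`PMPM = ρ·u·points·point value / 12`).
5. **Simulation** — seeded Monte-Carlo cohorts that verify the closed-form
   expected counts, and synthetic registry generation.

## Worked example

Score an autonomous ECG interpretation service and price it:

```bash
$ aibilling score --data 3 --disease 3 --question 3 --involvement 3
{
  "mean": 3.0,
  "rounded": 3,
  "stable": true,
  "suggested_level": "II",
  "tier_label": "augmentative",
  "tier_points": 100
}

$ aibilling fee --code AI-301 --regime ebm-simplified --factor 1.0
{
  "code_id": "AI-301",
  "fee_eur": "12.00",
  "points": 100,
  ...
}
```

A mean dimension score of 3.0 puts the service in the 100-point tier, and
the tier is stable: no single-rater ±1 disagreement on one dimension would
change it. At the simplified EBM orientation value of 0.12 €/point the
100-point code AI-301 bills €12.00 per case.

Is €12 per case worth paying? Run the cost–benefit check for a pathway with
10% prevalence where AI lifts sensitivity 0.85→0.90 and specificity
0.90→0.93, a missed case costs €2,000 downstream and a false alarm €150:

```bash
$ aibilling cba --prevalence 0.10 --soc-se 0.85 --soc-sp 0.90 \
    --ai-se 0.90 --ai-sp 0.93 --cost-fn 2000 --cost-fp 150 \
    --ai-fee 12 --minutes-saved 3 --n 1000
```

Per 1,000 cases the AI avoids 5 false negatives and 27 false positives,
worth €14,050 in avoided downstream costs against €12,000 in AI fees: a net
payer impact of **−€2,050** (negative = payer saving). The break-even AI fee
is **€14.05** per case — at or below it the payer is cost-neutral or saving —
and providers save 50 staff hours (3,000 minutes).

The same 100-point service maps into an RVU system by anchoring to an
established valuation (e.g. a $45 payment at a $30 conversion factor
implies 1.5 RVU, so κ = 0.015 RVU/point):

```bash
$ aibilling crosswalk rvu --anchor-points 100 --anchor-rvu 1.5 --points 150 --cf 30
# -> 150 points = 2.25 RVU = $67.50; service ratios are preserved
$ aibilling crosswalk pmpm --rho 0.1 --u 1 --points 100 --point-value 0.12
# -> €0.10 per member per month
```

Every invoice-producing command records the multiplier and its
justification, and logs an audit record (inputs, code version, output
digest) to standard error.

## Layout

| Module                  | Contents |
| ----------------------- | -------- |
| `aibilling.rubric`      | score vectors, tier assignment, stability check |
| `aibilling.schedule`    | billing codes, regimes, fee formula, validation |
| `aibilling.costbenefit` | expected counts, net payer impact, break-even |
| `aibilling.crosswalk`   | κ calibration, RVU payments, PMPM |
| `aibilling.simulate`    | Monte-Carlo cohorts, synthetic registries |
| `aibilling.io_` / `cli` | code-table and report I/O, config, audit, CLI |

See `docs/methods.md` for the model description, parameter defaults, and
known limitations.
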