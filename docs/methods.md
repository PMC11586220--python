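# Methods

This note documents the statistical model, the synthetic data generator,
numerical choices, and the limits of what the test suite demonstrates.

## Counting model

The analysis unit is the **deduplicated case** (one safety report), never
the drug–event row. FAERS publishes a report as one row per
(caseid, version); follow-ups share the caseid with a higher version.
Deduplication keeps, per caseid, the highest version, breaking ties by the
numerically larger primaryid (compared zero-padded). Dedup is idempotent
and conserves counts: raw rows = kept + removed-as-duplicate +
outside-window.

A case joins a drug group's cohort iff at least one of its drug mentions
normalizes into the group *and* carries the primary-suspect role code
(`PS`; the role filter is a parameter). Drug-name normalization is exact
matching after case folding, whitespace trimming and removal of one
trailing parenthetical (strength) suffix — no fuzzy matching, by design:
spelling variants in real FAERS need a curated synonym list anyway, and
silent fuzzy hits are worse than logged misses.

The comparator for every statistic is **cohort-excluded**: `c` and `d`
count cases whose primary suspect is any other drug. Age units
(YR/DEC/MON/WK/DY/HR) are converted to years; ages above 120 years are
treated as missing. Cumulative dose is `dose_amt ×` administration days
(inclusive therapy date span) when both are present, else the reported
cumulative field, else missing.

## Disproportionality statistics

Definitions are the variants standard in FAERS mining; all operate on
`(a, b, c, d)` with `N = a+b+c+d` and, for MGPS, the independence
expectation `E = (a+b)(a+c)/N`.

- **ROR** `ad/bc`, Woolf log-scale 95% CI. `a = 0` short-circuits to
  ROR 0 with an undefined CI (never a signal). If any of `b, c, d` is 0
  the Haldane–Anscombe +0.5 is added to all four cells and the result is
  flagged `continuity_corrected` — applying it to `d = 0` as well keeps
  the log-variance finite in that (pathological) corner.
- **PRR** with the same correction path when `c = 0`; χ² uses the Yates
  continuity term capped at `|ad − bc|` so it can never go negative.
- **BCPNN** closed-form posterior moments of the information component
  with the standard constants (`γ₁₁ = 1`, `α₁ = β₁ = 1`, `α = β = 2` and
  data-dependent `γ`). Tests verify the two analytic limits: IC ≈ 0 under
  independence (|IC| < 0.02 bits at N ≈ 10⁶) and IC → log₂ RR for large
  counts (within 0.01 bits at a = 10⁵). IC is *not* monotone in `a` for
  dense tables (the observed/expected ratio `aN/((a+b)(a+c))` turns over
  once roughly `a² > bc`), so the monotonicity property is asserted only
  in the sparse regime relevant to signal detection.
- **MGPS**. The prior is a two-component gamma mixture on the relative
  reporting rate; marginally each count is negative-binomial. The five
  hyperparameters are fitted by maximizing the marginal likelihood over
  all `a ≥ 1` cells of the database (zero cells are excluded — their
  enumeration over all drug×PT pairs is unbounded), optimizing
  `(log α₁, log β₁, log α₂, log β₂, logit p)` with L-BFGS-B from the
  DuMouchel start `(0.2, 0.1, 2, 4, 1/3)`. Non-convergence, an all-zero
  count vector, or fewer than 50 usable cells falls back to the start
  values with `converged=False`. EBGM is the posterior geometric mean
  `exp(E[ln λ])` of the resulting two-component gamma mixture posterior;
  EB05 solves the mixture CDF at 0.05 with Brent root-finding bracketed
  by the component quantiles, to 1e-9 relative on λ.

Thresholds are applied exactly as conventional, with inclusive `≥` for
PRR/χ²/a and strict `>` for the CI lower bounds and IC−2SD; the
combination policy (`all` of four, default, vs `any`) is a configuration
switch. Strong conditions use IC as the cross-drug "signal strength"
metric by default (EBGM selectable); condition D compares only drugs with
a positive signal for the same PT and is vacuously true when there are
none. Top-k ranking orders by case count `a` descending, ties by IC
descending then PT name.

## Synthetic generator

The generator emulates the *structure* of the FAERS quarterly extract for
a four-drug narcolepsy catalog (pitolisant, sodium oxybate, solriamfetol,
modafinil with their brand names) and a 21-PT toy MedDRA catalog spanning
six SOCs. Default demographics mirror a mostly adult, majority-female,
US-dominated reporting population: sex F/M/unknown = 0.665/0.285/0.05,
age strata child/adult/elderly = 0.04/0.78/0.18 with 30% missing age,
consumers the dominant reporters, receipt years uniform over 2019–2023.
Event probabilities are per-PT backgrounds (0.03–0.15, ≈1.5 events per
case) multiplied by a planted relative risk ρ for configured
(drug, event) pairs, keyed off the case's primary-suspect drug. One case
in five lists a secondary (non-PS) drug; 10% of cases are re-emitted as a
second version to exercise dedup. All draws flow from one root seed
through fixed per-table streams, so generation is byte-deterministic and
adding a table leaves the others unchanged.

Cases may draw zero events (≈20% at defaults); they are emitted in DEMO
and dropped at ingest, exactly as a report with no reaction rows would
be. Because event draws are independent Bernoullis, the reporting odds
ratio implied by the scheme has a closed form (`scheme_true_ror`)
conditioning on that retention; recovery tests check CI coverage of this
value. Note it exceeds ρ (e.g. 16.0 for ρ = 10 on a 0.04 background):
the odds ratio conditions on the event's complement and on retention.

What the generator does **not** emulate — and passing tests therefore do
not demonstrate — includes verbatim free-text drug names and MedDRA coding
noise, correlated events within a report, reporting trends over time,
cross-case (fuzzy) duplicates, and country-specific reporting dynamics.
Real-FAERS headline inventories cannot be reproduced without the real
extract, and the published IC/EBGM values of any given study depend on
unstated smoothing constants; agreement with them is out of scope.

## Problem sizes used by the validation suites

Chosen as the package's own test conditions: oracle equivalence on 1,000
random non-degenerate tables (cells uniform 1–500) at 1e-10 relative;
EBGM/EB05 against a 10⁷-draw Monte-Carlo posterior sample within 1% on a
25-table random subset (the closed form is identical per table, so the
subset exercises the full code path at Monte-Carlo precision); MGPS
recovery from 10⁵ self-simulated cells with `E ~ U(0.1, 20)` within 15%
relative; end-to-end recovery on 20 seeds × 50,000 cases with one planted
ρ = 10 pair (flagging by all four methods in ≥ 95% of seeds, ROR CI
coverage of the scheme-true value in ≥ 90%), and a 5-seed null arm
requiring the four-way signal rate among `a ≥ 3` pairs to stay below 5%.
`scripts/acceptance.py` re-runs the same computations at 10 planted and 3
null seeds.

## Rounding and table conventions

Summary proportions are percentages rounded half-up to 2 decimals; the
female/male ratio half-up to 1 decimal; quartiles use linear interpolation
between order statistics. Outcome proportions divide by the number of
outcome *records* (a case with two outcome codes contributes twice), not
the cohort size — this is the convention under which published outcome
columns are internally consistent. Dose summaries use the cohort's modal
unit; values in other units are excluded and counted. Yearly report
proportions are always emitted over the cohort total.

## Known limitations

- Exact-match drug normalization misses misspellings and compound
  products (logged, not guessed).
- MGPS is single-item: no drug–drug interaction terms despite the
  method's full name; no duplicate-aware statistical correction.
- The mixture likelihood is multimodal in principle; the fit is anchored
  at the DuMouchel start and may return a label-swapped or boundary
  optimum on data far from that prior (the `converged` flag and the
  likelihood-improvement test guard the pipeline's use).
- The MedDRA map is user-supplied; only PT/HLGT/SOC levels are modelled
  (no LLT/HLT/SMQ).
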