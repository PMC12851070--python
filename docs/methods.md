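# Methods

## Problem and model

The package identifies prevalent patients with short bowel
syndrome–associated intestinal failure (SBS-IF) in adjudicated
medical/pharmacy claims, where no specific diagnosis code exists for most
of the study era. Identification is a deterministic conjunction of
temporal rules over a patient's claim history (sustained parenteral
support plus prior malabsorption and surgical/congenital evidence), and
prevalence is a direct stratum-rate extrapolation: annual cohort counts
divided by enrollment-eligible database denominators per (age group ×
gender) cell, multiplied by census populations in the same cells. Nothing
is estimated statistically; every output is reproducible arithmetic over
the inputs, which is why results objects carry exact counts rather than
uncertainty intervals (and why none are reported).

## Rule parameters

All rule parameters live on `CohortDefinition`, with the shipped presets:

| parameter | default | meaning |
|---|---|---|
| `nutrition_categories` | {PN, IV_HYDRATION} | claim categories counting as parenteral support; `alternative_1` restricts to {PN} |
| `min_initial_nutrition_claims` | 1 | distinct-day nutrition claims needed since lookback |
| `chronic_gap_days` | 183 | "six months apart" as an unambiguous day count; 180/182 selectable |
| `continuous_min_claims_per_month` / `continuous_min_spacing_days` | 2 / 5 | per calendar month, after greedy thinning (below) |
| `continuous_min_months` | 6 | length of the qualifying consecutive-month run |
| `continuous_window` | `calendar_year` | run must fall inside the assessment year; `rolling_6_months` lets it straddle year boundaries |
| `require_malabsorption` | True (False in both alternatives) | malabsorption diagnosis strictly before the first nutrition claim |
| `enrollment_years_after_index` | 2 | index year + 2 subsequent years of continuous coverage |
| `global_window` | 2018-01-01 … 2021-12-31 | additional study-wide continuous-coverage requirement |
| `min_age_years` | 3 | exclusion below this age at Jan 1 of the assessment year |
| `lookback_start` | 2016-01-01 | earliest claim date considered |
| `allow_same_day_before` | False | whether same-day temporal ties satisfy "before" |

## Numerical and convention choices

* **Dates and intervals.** Claims carry service dates only; all dates are
  calendar dates and all intervals are closed on both ends. Enrollment
  spans are normalized by coalescing overlaps and gaps ≤ `grace_days`
  (default 0: strict continuity; the merge is idempotent and, at zero
  grace, coverage-preserving).
* **"Six months apart"** is 183 days between the earliest and latest
  nutrition claim dates.
* **The continuous rule** admits two readings — a qualifying run inside
  the assessment year versus a run merely intersecting it — and both are
  implemented as `continuous_window` modes; `calendar_year` is the
  default. Within a month, counted claims are greedily thinned on sorted
  distinct dates so that the counted set is pairwise ≥ 5 days apart;
  greedy earliest-first selection maximizes the counted subset under this
  constraint, giving patients the benefit of the doubt, and collapses
  same-day duplicate claims as a side effect.
* **"Before" is strict**: a malabsorption or evidence claim on the same
  day as the first nutrition claim does not qualify (configurable via
  `allow_same_day_before`).
* **Ages** are completed years: at Jan 1 of the assessment year for
  cohort eligibility, bands, and denominators; at the index date for
  `age_at_index`.
* **Annual cohorts are independent**: a patient may qualify in several
  years (annual point prevalence, not incidence).
* **Rule order** affects only the disposition waterfall; membership is the
  conjunction of independently evaluated rules, verified by a
  permutation property test.
* **Rounding** is half-up throughout (printed claims tables round halves
  up, unlike Python's banker's rounding): per-stratum projected counts are
  rounded before summation, with an unrounded total kept alongside;
  percentages are half-up integers.
* **Denominators**: a patient contributes to the year-*Y* denominator iff
  one normalized enrollment span covers Jan 1 (*Y*−3) … Dec 31 *Y* and
  their age/gender are known with age ≥ 3. Strata with zero denominator
  are omitted with a warning (an error if they contain cohort members).
* **Degenerate inputs**: empty databases yield empty cohorts and all-zero
  waterfalls; growth against a zero baseline is reported as absent;
  projection onto a census missing a nonzero-rate stratum raises an error
  naming the cell.
* **EN (enteral nutrition) claims never count toward eligibility**; they
  appear only in the nutrition-combination characterization rows.
* **Characterization window**: characteristics are assessed over the
  member's entire visible claim history by default, with an optional
  ±N-day window around the index date (`assessment_window_days`), since
  descriptive tabulations of comorbidity history are inherently
  window-ambiguous.

## Synthetic data: what it emulates, and what it does not

The generator plants three strata with per-patient random streams derived
from `(seed, ordinal)`, so databases are reproducible and insertion-stable:

* **True cases** follow the full trajectory — surgery (or congenital
  diagnosis) in November before the first qualifying year, malabsorption
  diagnosis a few weeks later, then PN supply claims every 12–14 days
  (matching 1–2-weekly home nutrition deliveries, and guaranteeing ≥ 2
  claims/month at ≥ 5-day spacing by construction) across each target
  year, with enrollment covering the index window, the global window, and
  every target year's 4-year denominator window. IV-hydration, enteral,
  comorbidity-group, and pharmacy-class claims are added at configurable
  per-patient presence rates (defaults 0.72 / 0.43 / 0.83–0.72 / 0.70–0.45,
  chosen to mirror the described 2021 cohort); gender and age-band mixes
  default to the same cohort's 66/34 gender split and
  30/29/30/10/1 band proportions.
* **Near-misses** violate exactly one named rule. Where a naive violation
  would cascade (e.g. removing nutrition claims also breaks the chronic
  rule), the trajectory is engineered so only the planted rule fails at
  evaluation time: the chronic violation uses six twice-monthly months
  whose overall span stays under 183 days, and the continuous violation
  uses monthly singletons across a full year. `repair_near_miss` flips the
  single planted feature and the result passes the primary definition — a
  tested minimality property. (`NUTRITION` near-misses bill the supply
  cadence as enteral nutrition, which necessarily also fails the
  downstream nutrition-dependent rules; the label records the planted
  violation.)
* **Background patients** carry junk codes from a vocabulary disjoint
  from every registry category, or — for a configurable confuser fraction
  — real rule codes in non-qualifying patterns (a lone PN claim, a
  3-month cadence, history without nutrition, enteral-only cadence).
  Optional claim-free "denominator filler" patients can be planted per
  (year, band, gender), enrolled exactly over that year's 4-year window.

The generator does **not** model realistic code frequencies, claim-line
detail (billed amounts, providers, adjustments), plan switching or
cross-plan linkage, disease onset/mortality dynamics, or calibrated
disease prevalence — planted cases are deliberately common so recovery is
measurable at small n. Passing tests therefore demonstrate that the
algorithm implements its temporal logic exactly (sensitivity and
specificity 1 against planted ground truth, agreement with an independent
brute-force checker), not that the rule set has any particular accuracy
against clinical reality, which would require chart-validated data.

## Design choices where the design was open

* The primary nutrition requirement is one PN-or-hydration claim
  (`min_initial_nutrition_claims=1`, as in the rule table); the parameter
  is exposed for users who prefer a two-claim initial requirement.
* Whether pharmacy claims may satisfy nutrition rules is left to the
  registry: classification is category-driven and claim-category-agnostic
  by default.
* The chronic rule is applied to all nutrition claims since lookback, not
  only those after the SBS evidence.
* The registry is required user configuration; shipped tests use a small
  fictitious vocabulary rather than asserting unpublished code lists.

## Problem sizes

The default synthetic database (50 true cases, 5 near-misses × 7 rules,
500 background; ~585 patients, ~10 000 claims over 2019–2021) is the
package's standard working scale: the full generate → cohort → project →
characterize pipeline over three definitions and three years completes in
a few seconds on one CPU, and the brute-force oracle comparisons use
≤ 200-patient databases across multiple seeds. Demographic-mix convergence
is checked at n = 2000 generated true cases (±3 percentage points).

## Known limitations

* Uninsured populations are outside the projection (claims capture the
  insured only); no adjustment is attempted.
* Census vintages are user-supplied; no particular series is bundled.
* Monthly logic uses calendar months; a "month" is never a rolling 30-day
  window.
* The engine holds the full database in memory; it targets desk-scale
  analyses and synthetic studies, not production claims warehouses.
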