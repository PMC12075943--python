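# Methods

## Data model and curation

The package reads the modern (post-2014) FAERS ASCII schema: six
`$`-delimited tables keyed by `primaryid` (one report version) and
`caseid` (the case shared by versions). Legacy quarters with different
column names are handled through a user-supplied column mapping rather
than auto-detection; schema archaeology is orthogonal to the statistics.
Files are read as UTF-8 with replacement of invalid bytes, since real
FAERS files contain stray bytes. The parser is total: a malformed line
(wrong field count, missing identifier, empty reaction term, unknown
role/outcome code) is counted and logged, never raised, and skip counters
always equal input lines minus parsed records.

**Dates.** FAERS dates are `YYYYMMDD` with truncated `YYYYMM`/`YYYY`
variants. Partial dates resolve to *absent* by default; an optional
first-of-period policy exists for users who accept the imputation. The
default avoids silently fabricating time-to-onset values.

**Deduplication.** Exact full-row duplicates are dropped first; then,
within each case, the version with the latest receipt date is kept. Ties
(equal or absent dates) keep the greatest `primaryid` — numerically when
both ids are numeric, lexicographically otherwise — which matches the
"latest version" intuition and makes the operation deterministic and
idempotent. Receipt date (not event date) drives the rule; this is
configurable at the call site by supplying a different column.

**Drug matching.** Query names (generic and trade) are normalized
(uppercase, trimmed, trailing punctuation stripped, whitespace collapsed)
and matched against both the verbatim drug name and the active-ingredient
field, requiring whole-string equality or whole-word containment. The
containment rule lets "KINERET" match "KINERET 100MG" without matching
"KINERETIN". Only records in the queried role (default: primary suspect)
count.

**Derived fields.** Reporter occupations collapse to health professional
(physician, pharmacist, registered nurse, other health-professional) vs
non-health professional (consumer, lawyer) vs unknown. Ages convert to
years (decade×10, month/12, week/52, day/365.25, hour/8766) and bin into
left-closed strata [0,18), [18,40), [40,60), [60,80), [80,∞) — the only
convention under which the published strata are contiguous and
non-overlapping; an exact 40th birthday falls in "40–60". Time to onset
is event date minus the *earliest* therapy start among the matched drug's
records (the conservative exposure date), binned [0,30), [30,180),
[180,360), [360,540), [540,∞); negative or incomputable spans are
unknown.

## Disproportionality analysis

The counting unit is the **reaction record** (each PT occurrence), not
the report: a corpus of ~7.5k reports carrying ~29k events tabulates 29k
records, which is the convention under which published report/event
totals cohere. Events of non-target reports are attributed to the
report's first primary-suspect drug; reports without one fall into an
"UNSPECIFIED" background bucket. For a target drug, all corpus terms are
tabulated (including a = 0) before the minimum-count gate, so the gate —
not a silent join — removes rare pairs.

The four statistics use the canonical literature forms (Wald-CI ROR,
Evans PRR with χ², DuMouchel's MGPS, BCPNN IC):

- Zero cells make ROR/PRR/χ² undefined (reported as NaN, never flagged).
  No Haldane 0.5 correction is applied by default: the n ≥ 3 gate makes
  a = 0 pairs irrelevant, and corrections would silently change the
  published formulas.
- χ² uses the Yates continuity correction by default (common in PRR
  practice); the uncorrected Pearson form is a flag away. Both match
  `scipy.stats.chi2_contingency` to 1e−10 in the tests.
- **MGPS.** The marginal likelihood of the counts under
  `λ ~ P·Gamma(α₁,β₁) + (1−P)·Gamma(α₂,β₂)` is a two-component
  negative-binomial mixture. It is maximized with L-BFGS-B over
  log-transformed shapes/rates and a logit-transformed weight, from the
  fixed documented start (α₁=0.2, β₁=0.1, α₂=2, β₂=4, P=1/3), with up to
  20 seeded random restarts on convergence failure (failure raises,
  carrying the best-so-far parameters). No data squashing: corpora here
  are desk-scale (10³–10⁴ pairs) and the exact likelihood is cheap.
- **EBGM.** The posterior is `Q·Gamma(α₁+a, β₁+E) + (1−Q)·Gamma(α₂+a,
  β₂+E)` with Q the posterior component weight computed in log space.
  `E[ln λ]` is closed-form via the digamma function; EBGM05 (and the
  2.5% quantile for IC025) come from monotone root-finding on the
  mixture CDF, bracketed by the component quantiles, to
  |F − q| ≤ 1e−8. Roundoff that puts a bracket endpoint on the wrong
  side is healed by widening the bracket, never by loosening the
  tolerance.
- **IC.** The default "MGPS-linked" mode defines IC = log₂ EBGM and
  IC025 = log₂ of the posterior 2.5% quantile; published five-statistic
  tables satisfy IC = log₂(EBGM) to rounding in every row we checked, and
  their printed IC025 sits slightly below log₂(EBGM05), consistent with a
  2.5% quantile. The closed-form variant
  IC = log₂((a+½)/(E+½)), IC025 = IC − 3.3(a+½)^−½ − 2(a+½)^−³ᐟ²
  is provided for comparability with studies that use it; neither mode is
  asserted to be the one behind any particular published table.

**Signal criteria** default to the conventional thresholds (ROR: n ≥ 3
and CI lower bound > 1; PRR: PRR ≥ 2, χ² ≥ 4, n ≥ 3; BCPNN: IC025 > 0;
MGPS: EBGM05 > 2) combined conjunctively ("all-four"). A consequence
worth knowing: when the true relative rate is 2, EBGM shrinks toward 2
from below, so EBGM05 > 2 is unattainable no matter the sample size — the
all-four rule is deliberately conservative and modest real signals
surface through the CI-based criteria first.

**Subgroups.** Strata always partition the corpus (explicit "unknown"
strata). A "death report" is any report with ≥ 1 death outcome record,
regardless of other outcomes. Coadministration means any non-primary-
suspect record matching a user-supplied list. Within-stratum
disproportionality keeps the full-corpus comparator (c/d) by default —
the stratum changes the exposed cell, not the background — with a flag to
restrict the comparator to the stratum. Age-distribution matrices count
records, not reports (flag available).

**Summary tables.** Percentages are 100·count/denominator rounded
half-up at two decimals. The age/sex/reporter/country/route blocks use
deduplicated target reports as denominator; outcomes use outcome records
(a report can carry several); time-to-onset uses its own block total.
These are the only conventions under which the published percentage
columns are arithmetically self-consistent. Published country percentages
are *not* consistent with any visible denominator, so the country block
exposes its denominator in the output instead of asserting one.

## Synthetic corpora

The generator emulates FAERS structure so the whole pipeline is testable
without any download: one primary-suspect drug from a 20-drug vocabulary
(marginals ≈ 2–7%), 0–3 concomitants from a 10-drug pool, reactions drawn
per report as 1 + Poisson(2) truncated at 10 terms — giving ≈ 3 records
per report, near the records-to-reports ratio of large published corpora
— from a Zipf-weighted background multinomial over the ~85 toy-dictionary
PTs (head ≈ 9%, tail ≈ 0.3%). Demographics follow configurable mixtures
(60% female, five age strata, consumer-dominated occupations, US-dominated
countries); missingness rates default to 30% for age and event date, 5%
for sex and occupation, matching the heavy incompleteness of spontaneous
reports. Outcome codes appear on 60% of reports. A configurable fraction
of cases (default 5%) is emitted twice with a later receipt date and one
extra reaction — only mutable fields change, so deduplication correctness
is observable. All draws derive from per-aspect generators spawned from a
single seed; a config is byte-reproducible.

Planted associations multiply one PT's probability by ρ inside one drug's
reports (optionally restricted to an age group or to reports carrying a
given concomitant) with renormalization, and are recorded as ground
truth. Two systematic effects are worth noting when scoring recovery:
renormalization slightly depresses non-planted terms in boosted reports,
and the target's own boosted records inflate the event's corpus-wide
share, so `a/E` (hence EBGM) sits below ρ by roughly a factor
`1 + w(ρ−1)` where w is the target's record share, while ROR/PRR
(whose comparator excludes the target) sit slightly above ρ. Recovery
tests therefore keep the planted drug's share near 2%.

What the generator does **not** emulate: real drug ontologies and name
misspellings, reporting-delay dynamics, correlated event syndromes,
duplicate reports from different manufacturers, or pharmacological
plausibility. Passing tests show the pipeline recovers what was planted
under the stated reporting model, not that real FAERS curation issues
(probabilistic duplicates, LLT→PT coding noise) are solved.

## Problem sizes and test design

Unit and property tests run on hand-built six-case fixtures and
scipy-verified random tables. End-to-end calibration and power use
20,000-report corpora: the null corpus checks that ≤ 5% of count-eligible
pairs are flagged under the all-four rule (observed: 0 of ~1,700), and 20
seeded replicates with a planted ρ = 5 pair at expected count ≈ 50 check
≥ 95% detection (observed: 20 of 20). MGPS recovery simulates 5,000
(a, E) pairs from a known Gamma(2, 2) prior and requires the implied
prior mean within 10% of 1. These sizes keep the full suite and the
acceptance script each within a few minutes on one CPU while leaving the
binomial tolerances comfortably non-degenerate.

## Known limitations

- The MGPS fit is a 5-parameter nonconvex likelihood; with very few pairs
  (< 50) the mixture can collapse to near-degenerate solutions. The fit
  is intended for corpus-scale pair sets.
- Only the case-version deduplication rule is implemented; probabilistic
  record linkage across manufacturers is out of scope.
- The shipped PT→SOC dictionary is a toy covering the generator's
  vocabulary; real MedDRA is licensed and must be user-supplied.
- Multi-level MedDRA (HLT/HLGT), legacy pre-2014 schema auto-detection,
  and temporal/sequential signal detection are out of scope.
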