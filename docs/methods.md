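# Methods

## Counting model

The unit of analysis is the *event record*: one (report, distinct PT)
pair.  A report listing the same PT twice contributes one record; a
report with three PTs contributes three.  This matches how public SRS
front-ends tally "AEs" (a drug can have 1,235 reports but 2,245 AEs), and
it is the unit under which the reconstructable published rows are
internally consistent.  `unit="report"` is available as an alternative:
each report then counts at most once per cell, with b and d counting
reports *without* the event.

Exposure is defined at report level (the report lists the target drug in
an allowed role); the comparator is every other report.  For SOC-level
events a record counts if its PT maps to the SOC under the user-supplied
two-column PT→SOC table (MedDRA itself is licensed and is not shipped;
an unmapped PT reaching a screen is an error, not a silent drop).

Aggregated pseudo-reports carry an integer `weight ≥ 1` and every
counting path sums weights.  This lets a published table with d in the
tens of millions be replayed as four rows (`replay_counts`).

## Statistics

All five methods are closed-form functions of (a, b, c, d); the exact
formulas are in the README.  Numerical notes:

- **Zero cells.** ROR needs all four cells; PRR needs a and c.  The
  default is an undefined (NaN) statistic carrying a reason code — an
  undefined statistic never flags.  A Haldane–Anscombe +0.5 correction on
  all cells is available behind `continuity_correction=True`.  Screens
  with the default a ≥ 3 floor never produce zero-a tables.
- **BCPNN.** The one-layer model with Dirichlet priors
  γ₁₁ = α₁ = β₁ = 1, α = β = 2 and the joint prior parameter
  γ = γ₁₁(N+α)(N+β)/[(a+b+α₁)(a+c+β₁)], which centres the prior IC at
  zero.  These canonical values reproduce the printed credibility bounds
  of the reference rows (e.g. 7.36 for the strongest row).  The reported
  `ic` is the raw log₂ relative reporting ratio (what reference tables
  print as "IC"); the flag uses E(IC) − 2√V(IC) ("IC025").
- **EBGM.** Implemented exactly as the reference analysis defines it:
  the crude relative reporting ratio aN/((a+b)(a+c)) with a lognormal
  interval sharing the ROR's standard error.  This is *not* the
  gamma–Poisson mixture MGPS; no EM fit is performed.  Consequently
  IC = log₂(EBGM) holds to machine precision, and EBGM05 =
  EBGM·(ROR_lo/ROR).
- **Monotonicity caveat.** ROR and PRR are strictly increasing in a with
  b, c, d fixed.  IC/EBGM are not in general — incrementing a also
  inflates both margins of aN/((a+b)(a+c)) — but are in the rare-event
  regime (b ≫ a, c ≥ a) that screening operates in; the property suite
  asserts exactly that.
- **Presentation rounding** is half-up to 2 decimals at serialization
  only; all comparisons and flags use full precision.  z = 1.96 by
  default, configurable.

## Published-row reconstruction

A signal-table row printing (a, the exposure's total event records, ROR,
χ²) determines its 2×2 table: b is the total minus a, the ROR fixes
d/c = ROR·b/a, and χ² is strictly monotone in the remaining scale, so a
Brent root solve recovers c (cells then rounded to integers).
`reconstruct_table_from_stats` implements this; the acceptance script
uses it to recompute the printed interval bounds from scratch.

## Screening and rules

A PT is a *positive signal* under a configurable boolean rule over the
five method flags; the default `ror & prr` is the most conservative
reading of "combined application of ROR and PRR".  Rows are ranked by
ROR (ties: a descending, PT ascending), mirroring published tables.  No
multiple-testing correction is applied (the screens it mirrors apply
none); the number of PTs tested is always reported so users can judge
multiplicity.  Concordance tabulates, for every subset of the five
methods, the PTs flagged by at least and by exactly that subset.

## Deduplication

Two rules, applied in order: (1) for reports sharing an id, keep the
highest case version, ties to the latest receipt date; (2) reports with
distinct ids but identical (sex, age, drug-name set, PT set, receipt
date) collapse to the lexicographically smallest id.  The operation is
idempotent and never increases the count.  No probabilistic linkage is
attempted.

## Strata and time to onset

Age groups are `<18`, `[18, 45)`, `[45, 65)`, `≥65` (so age 44.9 falls
in 18–44); reports with the stratifying field unknown are excluded from
that stratified screen but kept overall.  Both exposure and comparator
are restricted to the stratum before tables are built.  A secondary
`sex_contrast` view compares female vs male event shares *within* the
exposure's own reports, reusing the odds-ratio machinery.

Time to onset is onset date minus the earliest therapy start of the
matching drug entries, per report; negative differences are implausible
and are excluded but counted.  Unknown timing propagates — never imputed.
The median is the lower median; bins are 0–30, 31–60, 61–90, 91–180,
181–360, >360 days.  The per-sex cumulative curves are plain empirical
CDFs over known-TTO reports: spontaneous reports carry no risk set, so no
censoring-adjusted estimator is attempted.

## Co-administration screens

Partners are ranked by the number of reports containing both drugs.  A
combination screen treats reports with base+partner as the exposure and
everything else (including base-alone) as the comparator, and
cross-checks each flagged PT against the base-alone screen to mark
combination-specific signals.  No observed-vs-expected interaction
contrast is computed; the composite-exposure 2×2 is the whole model.

## Synthetic data generator

The generator emulates a public SRS extract, not any real database: a
Zipf-weighted background of comparator drugs and PTs, a target drug with
a configurable report count, and multiplicative signal injection — the
target draws PT i with probability ∝ p_i·RR_i, renormalized.  Defaults
follow the reporting profile of the motivating anti-CD20 cohort:

| parameter | default | meaning |
|---|---|---|
| `n_background_records` | 200,000 | comparator event records |
| `n_target_reports` | 1,235 | target-drug reports |
| `extra_reactions_mean` | 0.8 | reactions per report = 1 + Poisson |
| `sex_female_fraction` | 0.751 | female:male ≈ 3.02:1 among known |
| `missing_age_fraction` | 0.497 | ~half of reports lack age |
| `serious_fraction` | 0.183 | serious reports |
| `onset_median_days` | 5 | geometric onset-day model |
| `missing_tto_fraction` | 0.4211 | reports with unknown timing |
| `duplicate_fraction` | 0.02 | injected exact duplicates |

Each report is one AE episode: all its reactions share one onset day
drawn from the geometric model of its first PT (parameterized by its
median, p = 1 − 2^(−1/(m+1))), so the configured median is the
report-level TTO median.  Region mix is Americas-dominant; partner drugs
are co-administered independently with stated probabilities; signals can
be restricted to a sex, an age group, or a partner drug.  All randomness
flows from a single seeded `numpy` generator — identical configs produce
byte-identical stores.  The manifest records true RRs, expected counts,
and the contingency cells realized in the deduplicated store.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: reporting dynamics over calendar time (Weber
effect, stimulated reporting), drug–drug and event–event correlation
beyond co-administration flags, free-text drug-name noise beyond the
synonym table, near-duplicate (non-identical) reports, and confounding by
indication.  With ~50 % missing age the content space is coarse enough
that a few *organic* exact duplicates arise alongside the injected ones —
as in real extracts; dedup removes both.

Two identifiability caveats the test fixtures respect: the injected RR is
the estimand of ROR/EBGM only when the injected PT is rare in the
background (renormalization bias is 1 + p·(RR−1)) and the target's
records are a small fraction of the database (otherwise its own
enrichment inflates the comparator rate).  Test and acceptance databases
use 3×10⁴–10⁵ background records with expected signal counts set by the
conditions under test (expected a ≥ 5 for null calibration, ≥ 30 for
parameter recovery) — scaled-down but structurally faithful stand-ins
for the 10⁶–10⁷-record real systems.

## Pipeline and outputs

`run_pipeline` chains read → dedup → select → overall screen → strata →
TTO → DDI, writing TSV/JSON artifacts plus a run manifest with report
counts at every stage and a config digest; identical inputs give
byte-identical outputs.  The CLI is a thin layer over these functions.

## Known limitations

- Disproportionality quantifies reporting association, not risk or
  causality; no background-incidence denominator exists.
- The EBGM here is the crude ratio the reference analysis defines, so it
  lacks MGPS shrinkage; at small a it is anti-conservative relative to a
  true gamma–Poisson fit (the BCPNN bound provides the shrunk view).
- The exact-content dedup rule misses near-duplicates (same case,
  slightly different field values).
- FAERS-ASCII ingestion covers DEMO/DRUG/REAC/THER/OUTC essentials and
  tolerates extra columns, but not every quarterly-file quirk.
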