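# Methods

## Data model and counting conventions

The unit of analysis is the deduplicated safety report. A case (stable
`case_id`) may be submitted in several versions (`report_id`); deduplication
keeps the version with the latest receipt date, breaking date ties by the
lexicographically greatest report id. This is the conventional
case-versioning rule for FAERS-style extracts; the upstream "remove
duplicates" functions of query tools are not specified precisely enough to
mirror, so the rule here is fixed, deterministic and idempotent.

A report *has the drug* iff the drug name (case-insensitive, with optional
synonyms for brand/generic collapsing) appears with the primary-suspect
role code; other roles (secondary suspect, concomitant, interacting) never
place a report in the drug row, and a drug listed under several roles in
one report counts once. A report *has the event* iff the PT appears in its
validated PT list; within-report multiplicity is ignored. Consequently
a+b+c+d equals the population size identically for every pair built from
the same report set — a conservation law the tests assert against a naive
double-loop recount.

The comparator population is "all other drugs" within the supplied report
set. The `comparator` option decides whether reports that lose every event
term during PT validation stay in the background population (`all`) or are
dropped (`cleaned`, the default). The pipeline runs the primary-suspect
filter to define the drug's report subset for descriptive summaries, but
contingency tables are always built over the full population, because the
c and d cells count other drugs' reports.

## Detector formulas

With T = a+b+c+d and the shared standard error
s = √(1/a + 1/b + 1/c + 1/d):

| method | point value | interval |
|---|---|---|
| ROR | ad/bc | exp(ln ROR ± 1.96 s) |
| PRR | a(c+d)/(c(a+b)) | exp(ln PRR ± 1.96 s); χ² = (ad−bc)²T/((a+b)(c+d)(a+c)(b+d)) |
| BCPNN | IC = log₂(aT/((a+c)(a+b))) | IC025 = exp(ln IC − 1.96 s) |
| MGPS | EBGM = aT/((a+c)(a+b)) | EBGM05 = exp(ln EBGM − 1.64 s) |

Three conventions deserve emphasis.

**EBGM is the unshrunk observed/expected ratio.** Sources in this
literature sometimes typeset the EBGM denominator ambiguously
("(a+c)/(a+b)"); the only reading consistent with published signal tables
is aT/((a+c)(a+b)), which makes EBGM = 2^IC an exact algebraic identity.
The package computes the ratio once and derives both statistics from it.
True multi-item gamma-Poisson shrinkage (a fitted two-component gamma
prior) is deliberately not implemented: the published tables this package
mirrors are the unshrunk ratio, and a shrinkage EBGM would not satisfy the
2^IC identity those tables exhibit. χ² uses no Yates correction.

**IC025 and EBGM05 are multiplicative intervals on the point value.**
IC025 = IC·exp(−1.96 s) applies the log-scale interval factor to the IC
point value itself (note: ln of IC, not IC minus a multiple of its
standard deviation). This matches how the published tables were computed —
e.g. a row with IC 3.48 and ROR CI 14.60–16.04 gives
s = ln(16.04/14.60)/3.92 = 0.0240 and 3.48·e^(−1.96·0.0240) = 3.32,
exactly the printed IC025, and the same s reproduces the printed EBGM05
10.70 from EBGM 11.13 via the 1.64 multiplier. Two consequences follow:
IC025 is undefined when IC ≤ 0, and IC025 > 0 whenever IC > 0, so the
BCPNN significance gate ("IC > 0 and IC025 > 0") reduces to the sign of
IC. The conventional additive interval IC − 1.96·s/ln 2 is available via
`bcpnn_additive_interval=True` (default off).

**Zero cells leave statistics undefined, never raise.** Undefined
statistics are flagged, treated as nonsignificant, and printed as NA. An
optional Haldane–Anscombe correction (+0.5 to every cell) can be enabled;
it is off by default because the N ≥ 3 gate already screens almost every
pair a zero cell would affect, and `n` always reports the raw a cell.

## Significance and intensity

Gates (each also requires n = a ≥ 3): ROR lower bound > 1; PRR lower bound
> 1 and PRR ≥ 2 and χ² ≥ 4; IC > 0 and IC025 > 0; EBGM05 > 2. Published
criteria vary on whether the MGPS gate tests EBGM or EBGM05 and whether its
report threshold is N > 0; this package tests the lower bound EBGM05 > 2
with the global N ≥ 3 gate, the stricter and internally consistent choice.
A pair is *combined-positive* only when all four gates pass — the
conjunction trades sensitivity for a very low false-positive rate (see
calibration below).

Intensity bands (open below, closed above): ROR and PRR on the point value
— (2,10] weak, (10,50] medium, >50 strong; BCPNN on IC025 — (0,1.5] weak,
(1.5,3] medium, >3 strong; MGPS on EBGM05 — (2,10] weak, (10,30] medium,
>30 strong. Nonsignificant methods grade `none`, as do values at or below
the lowest edge. Full precision is kept internally; rounding (half-up, two
decimals) happens only in presentation tables.

## Pipeline, exclusions and summaries

Stage order: read → deduplicate → primary-suspect filter → PT validation →
tables → statistics → significance/intensity → invalid-signal exclusion →
SOC aggregation → ranking → novelty flagging → descriptive summary. Every
stage records inflow, removals by category, and outflow; the tests assert
conservation on synthetic runs.

Significant signals whose PT names the treated disease (e.g. "Disease
progression"), a disease outcome (e.g. "Death"), a non-reference term
(e.g. "Investigation") or an unspecified event (e.g. "Oncologic
complication") are statistically disproportionate but uninformative about
drug harm; they are tagged with their category and removed from the
positive set. The four term lists are user configuration — the shipped
defaults cover the canonical examples for a breast-cancer indication and
must be extended per study. Exclusion accounting is reported both in PT
records and in signal reports (the sum of n), the latter being the unit of
flow-diagram totals.

SOC aggregation sums n over positive PT signals per system organ class and
expresses each SOC as a share of the positive total. Ranking offers
`frequency` (n descending, ties by ROR then PT) and `strength` (ROR
descending by default, ties by n then PT; the strength metric is
configurable to IC025 because ROR-based strength ordering, while the
convention in the mirrored tables, is sensitive to tiny-count pairs).
Novelty flags PTs absent (case-insensitively) from a user-supplied label PT
list.

Descriptive summaries count sex, age bands (<18, 18–64, ≥65 — lower bounds
inclusive — plus not-specified), reporter regions and countries (built-in
country→region map, overridable; unmapped countries log a warning and count
as not specified), top indications, receipt years and the six outcome
classes. All percentages use the full report total as denominator and round
half-up to two decimals, so not-specified levels are part of every
partition; outcome percentages can exceed 100 in sum because a report may
carry several outcome classes.

## Synthetic report generator

The generator emulates the seven data classes of a spontaneous report
(demographics, drug information, indication, reaction terms, outcomes,
therapy/dose, provenance) at a desk scale. Defaults describe a scaled-down
breast-cancer pharmacovigilance population: sex 77.9% female / 3.4% male /
18.7% not specified; age normal(56, 13) with 43% missing; a dominant
indication (50% "Breast cancer") plus an unknown-indication level (23%);
US-dominant countries; outcome-class rates death 13.8%, hospitalisation
28.8%, life-threatening 3.1%, disability 1.4%, required intervention 0.1%,
other 36.7%, none 16.1%; receipt years 2007–2024; dose mostly 1250 mg/day
with 30% missing. The default population is 20 drugs × 50 PTs with the
drug of interest holding a 20% primary-suspect share and PT background
probabilities on a geometric gradient (0.002–0.1); the mean zero-truncated
PT count per report is 3.

Planted signals act on the odds scale: a planted PT enters each report by
an independent Bernoulli draw whose odds are multiplied by λ when the
report's primary suspect is the planted drug, so the population ROR equals
λ exactly and recovery targets are analytic. Planted PTs are excluded from
the categorical background pool (their only entry route is the Bernoulli
overlay); all other PTs fill the report via a zero-truncated Poisson count
(rate solved so the truncated mean matches `events_per_report`) and
categorical draws, guaranteeing at least one event term per report.
Duplicate case versions differ only in report id and an earlier receipt
date, isolating the deduplication rule. Identical configurations (including
seed) yield identical outputs.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: correlated drug co-prescription and
drug–drug interaction structure, correlated multi-PT syndromes, reporting
trends over time, notoriety and stimulated-reporting bias, country- or
reporter-specific coding habits, and free-text drug-name noise beyond
case differences.

## Calibration results and their configuration

Two simulation studies back the detector implementation (both run in the
test suite and in `scripts/acceptance.py`):

- **Recovery**: 100 replicates of the default population with one planted
  pair at λ = 10 and background probability 0.01 (expected a ≈ 90). The
  pair must be combined-positive in ≥ 95 replicates and the realised 95%
  ROR interval must cover λ in ≥ 93; the mean realised ROR recovers λ
  within 10%.
- **Null calibration**: 100 all-null 20-drug × 50-PT grids of 2,000 cases;
  every (drug, PT) pair with a ≥ 3 is screened. ROR, PRR, MGPS and the
  combined rule must each flag < 10% of pairs. The BCPNN rate is evaluated
  with the additive IC interval, because under the default multiplicative
  IC025 the gate reduces to the sign of IC and flags ≈ 50% of null pairs
  *by construction* — that degenerate rate is reported alongside
  (`bcpnn_printed`) for transparency but is an analytic property of the
  printed formula, not a calibration failure. In practice the conjunction
  rule absorbs this: the combined false-positive rate stays ≈ 0.2%.

Problem sizes (5,000-case recovery replicates, 2,000-case null grids, 100
replicates each) were chosen as the smallest populations at which the
expected a cell clears the asymptotic regime of the interval formulas
(expected a ≈ 90 and ≈ 6–60 per common pair respectively).

## Naranjo scoring

The ten canonical questions with the published weights (shipped as YAML;
maximum 13, minimum −4) and the fixed category cut-offs: ≥ 9 definite, 5–8
probable, 1–4 possible, ≤ 0 doubtful. Some sources label the top category
"highly probable or definite"; it is a single category here. Unknown
responses score 0 under the default table. Dual-rater workflows are
supported only to the extent of scoring two answer sets and flagging
category disagreements; consensus resolution is a human process and out of
scope.

## Numerical and degenerate-input choices

- Probability vectors must sum to 1 within 1e-9; violations are
  configuration errors, as are planted pairs absent from vocabularies.
- The ZTP rate is solved by Brent's method on [1e-9, mean+10].
- The monotonicity of IC/EBGM in a holds only while a² < bc (a small
  against both margins — the mining regime); ROR and PRR are strictly
  monotone everywhere. Tests reflect this.
- Empty report sets, absent drugs and header-only files yield empty
  results, never errors; malformed input rows are rejected row-wise with
  reasons rather than aborting a read.
- Ranking uses a stable mergesort with fully specified tie-breaks, and
  dictionary iteration orders are insertion-deterministic, so identical
  inputs produce byte-identical outputs.

## Known limitations

Disproportionality on spontaneous reports cannot estimate incidence or
establish causation; the package screens and ranks hypotheses. No
stratified or adjusted tables (age/sex stratification), no dose–response
modelling (spontaneous data carry no exposure denominator), no RxNorm drug
normalisation, no parsing of raw quarterly FAERS distributions, and no
shrinkage-based EBGM (above). MedDRA content is licensed and must be
supplied by the user.
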