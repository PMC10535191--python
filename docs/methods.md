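# Methods

## Phenotype calling and activity scoring

A diplotype is an unordered pair of star alleles, each with a copy number
(`*1x2` denotes a duplicated `*1`). Calling uses only the pair of allele
*function* categories, taken from a CSV table
(`star_allele, function[, activity]`):

| function pair | raw phenotype |
|---|---|
| no_function + no_function | poor |
| any no_function or decreased allele, short of two no_function | intermediate |
| normal + normal | normal |
| normal + increased | rapid |
| increased + increased | ultrarapid |

Rapid and ultrarapid are collapsed to **fast** for analysis, reflecting
their comparable pharmacokinetics. Alleles of unknown function yield
*indeterminate*; alleles absent from the table yield *not_available*;
both are excluded from analysis cohorts rather than raising. The
decreased-function rows of the table above are a deliberate convention
(CPIC-style, conservative): any reduced-capacity allele short of total
loss is grouped as intermediate, including decreased + increased. Copy
number does not enter the categorical call.

The activity score is `Σ activity(allele) × copy number` with default
per-allele values no_function 0, decreased 0.5, normal 1, increased 2 —
each within the conventional [0, 2] per-allele range, and doubling both
copy numbers doubles the score. The shipped CYP2C19 table (`*1` normal;
`*2`–`*8` no function; `*9` decreased; `*17` increased) is a stand-in for
a full curated assignment and is user-overridable, including per-allele
activity overrides. One consequence of the default values: `*2/*17`
(intermediate) scores 2.0, the same as `*1/*1` (normal), so the score is
monotone in phenotype only across the canonical diplotypes
(`*2/*2` 0 < `*1/*2` 1 < `*1/*1` 2 < `*1/*17` 3 < `*17/*17` 4).

## Record handling

Prescription tables follow the UK primary-care export layout
(`eid, data_provider, issue_date, read_2, bnf_code, dmd_code, drug_name,
quantity`); clinical events follow `eid, data_provider, event_dt, read_2,
read_3`. Dates are day-first or ISO ("auto" tries day-first then ISO per
element). Placeholder dates — years ≤ 1901 or ≥ 2037, the UK-Biobank
sentinel convention — are dropped and counted, never raised, as are rows
with no code or name at all.

Drug classification resolves each prescription to one of six classes
(three index SSRIs, other antidepressant, antipsychotic, other) with
precedence dm+d > BNF exact > BNF chapter prefix > read v2 > name
pattern. Name patterns are word-bounded case-insensitive regexes, so
"Escitalopram" never matches the citalopram pattern. Same-day duplicate
issues of the same agent are collapsed before any outcome work: repeat
lines would inflate count-based duration arbitrarily.

The shipped side-effect code list
(`uku_side_effect_codes_synthetic.csv`) is a small synthetic stand-in of
25 plausible read v2 / CTV3 codes for common psychotropic adverse
effects; the real curated list is study data that cannot be
redistributed. The pipeline treats any such list purely as data.

## Outcome definitions

All outcomes are derived per person × index SSRI from the deduplicated
timeline; binary statuses are case / control / excluded.

**Prescription windows.** Maximal runs of index issues with consecutive
gaps strictly under `gap_days` (default 90); a gap of exactly 90 starts a
new window.

**Switching.** The switch candidate is the first other-antidepressant
issue on or after the first index issue; ties on the same day count as
day-difference 0. A case at window *w* ∈ {30, 60, 90} requires the
candidate at most *w* days after the preceding index issue and at most
`tol(w)` index issues (1/1/2) in the 30 days before and the 30 days after
the switch date. The tolerance interval is a fixed 30 days
(`tolerance_window`) rather than *w* itself: tying it to *w* would make
ordinary monthly prescribing fail the 60-day tolerance for every
switcher, and would break the monotonicity a stricter window should have
(case at 30 ⇒ case at 60). Both the interval and the thresholds are
configurable. Controls need at least 3 index issues and no
other-antidepressant issue at any point from the first index issue on
(a strict reading of "no previous switch"); everyone else is excluded.

**Discontinuation.** Definition 1: exactly one index issue ever and no
antidepressant of any agent after it. Definition 2: the person's only
prescription window spans under 56 days (8 weeks, strict) and no
antidepressant follows its last issue. "Stoppage" is unbounded in time,
so both definitions additionally require `lookahead_days` (default 180)
of observed record beyond the last index issue — otherwise the person is
excluded as right-censored. Controls are the switching controls. When a
short-window stream also satisfies the control rule (three issues inside
eight weeks), case takes precedence.

**Duration.** Count of deduplicated index issues, and total weeks
`Σ (last − first)/7` over prescription windows (a single-prescription
window contributes 0). All persons with at least one index issue
contribute to duration models, regardless of case/control membership in
other outcomes.

**Side effects.** A listed clinical-event code in `(first_rx, first_rx +
w]` for *w* ∈ {30, 60} whose exact code does not also occur in the 30
days up to and including `first_rx` (a same-code prior event marks a
pre-existing condition, not a side effect; a *different* listed code
prior does not block). Requires the record to cover the whole
look-back/look-forward interval, else excluded.

**Antipsychotic overlap.** Any antipsychotic issue inside the inclusive
first-to-last index envelope; used as a model covariate.

## Association models

Binary outcomes: maximum-likelihood logistic regression. Durations: OLS
on `ln(duration + 1)`; the +1 offset handles single-prescription persons
with zero weeks. Predictor: phenotype as a categorical with normal
metabolisers as reference, or the activity score as a continuous term.
Covariates (default): age at first index prescription (years), sex,
genotyping batch (unordered factor) and antipsychotic overlap — the
four-covariate set matches the fitted models' description; a
methods-only set is a parameter away. Inference is two-sided Wald
(CI = estimate ± 1.96·SE on the link scale, OR = exp(estimate)). Raw
p-values are reported throughout; `run_all` adds a Bonferroni
significance flag at α/4 (four outcome families) alongside, never
replacing them. Degenerate fits — no cases, no controls, perfect
separation, non-convergence, zero-variance response — return flagged,
inestimable results rather than raising; separation is flagged
heuristically (non-finite or huge SE / |coefficient| > 15) on top of the
optimizer's own exceptions.

## Synthetic cohorts

The generator's defaults are the study conditions: phenotype frequencies
2.7 / 26.0 / 39.6 / 31.6 % (fast split 85.1 / 14.9 into rapid and
ultrarapid, i.e. 26.9 / 4.7 points), 66.2% female, age ~ N(55.2, 8.1²),
two genotyping batches, 80% broad-depression prevalence, per-SSRI
assignment probabilities proportional to the per-drug cohort sizes
(multi-SSRI persons allowed; their agents occupy disjoint calendar
segments ≥ 180 days apart), and a ~28-day inter-issue gap (monthly issue
convention).

Treatment intensity is latent log-normal: `ln(count+1) = μ_c +
shift_c(phenotype) + σ_c·u` with defaults μ_c = 2.5, σ_c = 1.1 (mean
count ≈ 22 and coefficient of variation ≈ 1.6, matching the printed
duration means and SDs), and `ln(weeks+1)` adds `ln 4` (weeks ≈ 4 ×
count), an independent log-normal gap jitter (SD 0.15) and its own
phenotype shift. Gaps are clipped to [3, 83] days so every stream forms a
single prescription window — derived weeks then equal the latent span
exactly, and count shifts propagate to weeks as they would in real
prescribing. Counts are capped at 300 and streams at a calendar horizon
(first issue 2000–2005, horizon ~2032) so extreme tails stay inside a
realistic records period.

Binary events are injected on the logistic scale, as per-phenotype odds
ratios (reference normal) or as a log-odds slope per activity-score unit
anchored at the normal-metaboliser score of 2.0. Switchers receive
another antidepressant 7–29 days after their final index issue, with the
delay floor raised so the second-to-last index issue stays outside the
30-day tolerance interval — the stream then expresses a clean switch at
all three windows. Side-effect cases receive a listed event 3–28 days
after first prescription with no same-code prior event; 2% of persons
additionally receive a same-code before/after pair, which must derive as
control (the prior-occurrence rule).

Discontinuation has two generation modes. With `disc_prob` unset
(default), abrupt stops emerge from the natural left tail of the
duration distribution — no separate process distorts the duration
latents, which keeps duration-effect simulations clean. With `disc_prob`
set, a latent per-person mixture forces cases onto short streams (1–3
issues, span < 8 weeks, nothing after) and keeps non-cases at ≥ 3 issues
spanning ≥ 60 days; this expresses a specified discontinuation odds
ratio exactly but deliberately overrides the duration latents for the
affected persons, so the two injection modes should not be combined in
one estimand. Record ends extend ≥ 180 days past the last activity
except for a configurable censored fraction (default 5%).

Nuisance realism: duplicate same-day issue lines (2%), four coding
styles for index prescriptions (name / dm+d / BNF / read v2), background
non-psychotropic prescriptions and non-listed clinical events,
antipsychotic co-prescriptions inside and outside the index envelope.
The truth table records every latent draw plus the status each stream
was constructed to express; on non-censored streams the outcome module
reproduces those statuses essentially exactly (the test bound is ≥ 99%).

What the generator does **not** emulate: dose information, tapering,
partial adherence, seasonal or provider effects, drug–drug interactions,
co-prescription of multiple antidepressants as augmentation, and
irregular real-world gap distributions. Passing recovery tests therefore
show that the derivation and models are correct and calibrated under the
stated generative assumptions — not that the outcome definitions capture
clinical reality.

Determinism: one global seed with per-person substreams keyed by
(seed, person index); identical configurations give byte-identical
bundles, and person *i*'s records do not change when only `n_persons`
grows.

## Numerical and design choices

* Integer day arithmetic throughout derivation; no time-of-day or
  time-zone handling.
* Summary-table percentages use decimal half-up rounding at one decimal,
  with the column total as the explicit denominator (category counts
  need not exhaust it).
* Null calibration of the adjusted logistic test is checked on the
  intermediate and fast contrasts (≥ 25 expected cases per cell at the
  test's cohort size); the poor contrast at reduced n has too few
  expected cases for the Wald approximation to be the object under test.
* Parameter-recovery checks assert that the injected truth lies inside
  the fit's own 95% CI — the natural frequentist contract for a single
  seeded replicate.
* The subgroup analysis filters outcome-table rows before fitting; it
  does not re-derive controls within the subgroup.
* `n_cases`/`n_controls` double as `n`/0 for linear fits.

## Known limitations

* The switch tolerance interval (fixed 30 days) is one reading of an
  under-specified rule; it is a config knob, and alternative readings
  change who counts as a 60/90-day case.
* The shipped allele table covers the common CYP2C19 alleles only;
  cohorts with structural variants or rare alleles will see many
  not_available exclusions unless the table is extended.
* Activity-score analyses drop unknown-function carriers silently (with
  a log line); no imputation is attempted.
* Duration models include all prescribed persons; if duration is only
  meaningful among treatment completers, filter the outcome table before
  fitting.
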