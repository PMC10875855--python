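# Methods

## The scoring model

Both indices are additive 10-component scores over a single recall day.
A recall day is a list of eating occasions (EO); exactly one may be labelled
breakfast. Nutrient amounts are absolute per consumed portion and sum
exactly (item → occasion → day), which the data model enforces at
construction time, so scoring never re-derives totals from densities.

Several adult criteria are *daily limits divided by the EO count*: the free
sugar, saturated fat, fibre and sodium thresholds all scale as `1/EO`. This
makes the EO count a first-class quantity: every recorded occasion counts,
including beverage-only ones, because the recall structure is the only
occasion definition available. Two consequences are worth knowing:

- increasing EO (intakes held fixed) tightens the three "less-than" criteria
  and loosens the fibre "greater-than" criterion — the property suite
  asserts these exact directions;
- zero intake trivially satisfies every "less-than" criterion, so a bare
  espresso breakfast still collects the sugar, fat and sodium points. This
  is a feature of the published scoring scheme, not an artifact.

Boundary handling follows the printed operators: strict `<` for sugar, fat
and sodium, strict `>` for fibre, `≥` for calcium. The two windows that are
printed without operators — the adult 15–25% and child 20–25% energy share,
and the child 200–300 mg calcium window — are closed at both ends.

Energy conversions use the Atwater factors 4 kcal/g (sugars) and 9 kcal/g
(fat), exposed as module constants.

The breakfast occasion is identified by its recall label; a clock-window
fallback was considered and rejected as a default because occasion labels
are authoritative in diary-based recalls, and two labelled breakfasts is
treated as a data error rather than merged (the `1/EO` thresholds assume
distinct occasions).

"Complete dietary data" is operationalized as: breakfast occasion present,
positive daily energy, and no unparseable nutrient cells (enforced at read
time). No energy-plausibility filter is applied. The selection cascade is
fixed-order — missing breakfast-regularity, then habitual skippers, then
incomplete recall days — with each participant counted under the first
matching reason; the filter is idempotent.

### Adult specifics

Calcium is judged against 20% of a life-stage reference intake. The
packaged table uses 1000 mg/day up to age 59 and 1200 mg/day from 60 for
both sexes, the conventional Italian adult reference values; it is a YAML
config validated for gap- and overlap-free coverage, so any national table
can be substituted. The combination point requires all three of
cereals/fruit-vegetables/dairy in the breakfast meal; a configuration
switch (`combination_rule="any2"`) exposes the looser two-of-three reading
without making it the default, since observed combination prevalences are
far too low for the looser rule.

### Child specifics

The MUFA:SFA criterion is population-relative: the cohort median of
breakfast ratios is computed once per run (two-pass scoring) and a child
scores the point only when strictly above it — ties at the median score
zero, which is why slightly fewer than half of a cohort can hold the point.
Degenerate ratios follow documented conventions: SFA = 0 with MUFA > 0 is
+inf (above any finite median); 0/0 is 0 (never above a positive median).
Both conventions are arguments. The median is over breakfast ratios of the
analyzed cohort (not whole-day ratios or an external reference); with
tie-free ratios exactly `⌊n/2⌋` children score the point, asserted exactly
in the acceptance suite. The "MUFA-rich fats" component is class presence
(olive/vegetable oil items), not a nutrient threshold, and the added-sugar
limit counts only the free sugar carried by simple-sugar-source items
(added sugar, jam, honey) — sugar inside biscuits does not count against it.

## Taxonomy

Food codes map to ~28 reporting groups which map to seven scoring classes;
both maps are a packaged YAML config and fully overridable. Deliberate edge
placements: fruit juice and nut spread are *not* fruit/vegetables; cocoa
drinks (milk-based) are dairy while cocoa/energy drinks are not; nuts are
fruit/vegetables. `water` and `mixed_dishes` are scoring-neutral plumbing
groups so that non-breakfast recall rows classify cleanly.

## Regression models

Model 1 adjusts for age group, sex and total daily energy (kcal/day,
untransformed); Model 2 adds area, residence, education, occupation,
marital status, smoking, sport, BMI category and five disease-history
flags (the child tier uses the reduced child covariate set). Age enters
grouped (20–40/41–65/>65; children 5–12/13–19) because that is how such
tables report it. Categorical covariates are treatment-coded against the
declared reference levels; psychosocial exposures are appended to the
Model 2 set one at a time, with subsetting available for structurally
inapplicable levels (e.g. non-workers in stress-at-work models).

Estimation is ordinary least squares for the continuous score and
multinomial logit (Newton, |Δloglik| < 1e-8, ≤100 iterations) for the
category, both via statsmodels; this module owns design construction and
table assembly. Confidence intervals are Wald (±1.96·SE, normal quantile)
everywhere, with multinomial CIs built on the log scale and exponentiated;
p-values are two-tailed normal. Rank-deficient designs fail loudly with the
collinear columns named; |log-odds| > 15 flags likely separation.
Complete-case analysis is the only missing-data policy: multiple imputation
is a survey-processing procedure outside this package's scope, and the
synthetic data are generated complete (a masking option can document the
gap).

## The synthetic cohort generator

The generator emulates the *structure* of an Italian telephone nutrition
survey, with defaults set to published marginal figures: ~7,673 adults /
~505 children; 2–6 occasions per day (truncated Poisson, mean 4.0); adult
breakfast consumption probabilities (milk 0.617, coffee 0.72, bread 0.441,
cakes/biscuits 0.387, added sugar 0.567, fruit 0.067, juice 0.038, yogurt
0.081, jam/honey 0.087) and child probabilities (milk 0.75, cakes 0.493,
bread 0.188, cereals 0.097, coffee 0.188, cocoa/energy drinks 0.168, juice
0.079, fruit 0.045, added sugar 0.301); covariate category frequencies from
the corresponding descriptive tables. Where a needed value is unpublished
it was chosen once as field-realistic: adult tea 0.20 and breakfast cereals
0.05; child jam/honey 0.05, yogurt 0.081, olive oil 0.028 and butter 0.022
(the last two chosen so the MUFA:SFA criterion splits the cohort
non-trivially, matching the ~2.8% MUFA-fat and ~2.2% butter prevalences of
such cohorts). Portions are lognormal per group; nutrients come from a
fixture composition table with reference-book-typical densities — it is a
synthetic stand-in, never a truth claim about any real food database.
Non-breakfast occasions are filled with a generic mixed dish so daily
energy lands in 1,400–3,200 kcal. A participant whose consumption draws
all fail receives a water-only breakfast (~1% of adults): the files then
pass the exclusion cascade untouched and no configured prevalence is
biased.

Planted covariate effects act on consumption logits, not on the score:
postsecondary education +1.5 on fruit and +1.0 on breakfast cereals;
age > 65 +1.5 on fruit; high financial stress −1.5 on fruit and −1.0 on
milk. Acting mechanistically makes recovery an end-to-end test — the score
difference must *emerge* through taxonomy, scoring and regression. The
magnitudes are design choices: large enough that the sign of the induced
score difference is recoverable by the fully adjusted linear model at
n = 5,000 (the financial-stress effect includes the milk term because its
reference stratum holds only ~2% of participants, so a fruit-only shift
would drown in its standard error). The `planted_truth` ledger records
every effect and its expected direction for the recovery suite.

Configured probabilities are **baseline** (reference-stratum) rates: planted
shifts move the marginal prevalence of affected groups. Distributional
fidelity (empirical prevalence within 3 binomial SEs of the configured
value at n = 20,000) therefore holds, and is asserted, for a configuration
with no planted effects; under the defaults it holds for all unshifted
groups. Covariates are drawn independently of one another, which real
surveys violate (age–occupation, stress–occupation); this makes adjusted
estimates unconfounded by construction and is precisely why passing
recovery tests here says nothing about confounding control in real data.

## What the tests do and do not show

Problem sizes used: exhaustive 2^10 component-vector enumeration; regression
oracles at n = 500; null-OR calibration at n = 5,000 over 50 seeds; CI
coverage of a planted linear effect (β = 0.25, σ = 1.1) at n = 5,000 over
100 replicates (accepted band 90–99%); end-to-end sign recovery at
n = 5,000; simulator fidelity at n = 20,000; exclusion cascade at n = 10,000
with skip/missing rates 10.5%/1.1%. These validate the scoring algebra, the
two-pass median logic, the selection cascade and the estimation machinery
under known truth. They do not — and cannot — reproduce any real cohort's
score distribution: that would require the survey's food-composition data
and microdata, which are access-restricted, so published cohort figures are
context, not calibration targets.

## Known limitations

- Single-day recalls: the index measures the recorded day, not habitual
  breakfast quality; no usual-intake correction is attempted.
- The fixture composition table is deliberately coarse (one representative
  food per reporting group in the simulator).
- No survey weights, clustering or design effects.
- Child BMI categorisation beyond a configurable covariate column (e.g.
  age/sex-specific cut-offs) is out of scope; the covariate arrives
  pre-categorised.
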