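# Methods

This note records the models, rules, and numerical choices behind
`bevclass`, and what the synthetic-data tests do and do not demonstrate.

## Classification

### Strategy proxies

* **Strategy 1 (foodcode numbering).** True when the 8-digit code starts
  with the configured prefix (default `924`, carbonated soft drinks) *and*
  the description matches one of a small term set (default: *sugar free*,
  *reduced sugar*, *low calorie sweetener*, *no calorie sweetener*).  The
  description test is configurable because the published uses of this
  strategy never enumerate it precisely; the default mirrors the phrasing
  those analyses gesture at.
* **Strategy 2 (survey categories).** True when the foodcode's category is
  one of the diet-drink categories {7102, 7104, 7106}.
* **Strategy 3 (caloric density).** Four criteria: <40 kcal/8 fl oz
  (regulatory low-calorie), <5 kcal/8 fl oz (no-calorie), <6.7 kcal/8 fl oz,
  and <50 kcal/240 g.  All comparisons are strict `<`; boundary values are
  excluded.  The serving is fixed at 8 fl oz, whose mass is
  `8 × grams_per_floz`, so `kcal/8 fl oz = kcal/100 g × 8 × factor / 100`.
  The 240 g basis is mass-only: `kcal/240 g = kcal/100 g × 2.4`, never
  touching the fluid-ounce factor.  Energy can come from the database
  (FNDDS) or from manufacturer declarations; when brands under one code
  disagree, the foodcode-level manufacturer value is the minimum over known
  products (the most inclusive choice for low-calorie screening).  A missing
  energy value yields an explicit *unknown* result, never `False`.  Whether
  the 240 g criterion was originally applied to database or manufacturer
  energy is not documented; both sources are supported and the database is
  the default.
* **Strategy 4 (text search).** Whole-token matching over the normalized
  description: single-word terms match whole tokens only (so *diet* does not
  fire inside *dietary*), multiword terms match as contiguous token phrases,
  and hyphen/space/case variants are equivalent.  Uncontrolled substring
  matching is a documented failure mode of text-based classification, hence
  the token discipline.

### Ingredient-based reference classifier

Ingredient strings are normalized (lowercase, hyphens→spaces, punctuation
stripped, whitespace collapsed) and matched against an LCS lexicon
(aspartame, sucralose, acesulfame potassium/AceK, saccharin, neotame,
advantame, stevia/steviol glycosides, rebaudioside A/RebA/rebiana, monk
fruit/luo han guo) as token phrases.  Per (code, cycle):

* all known products list ≥1 LCS → **LCSB** (a product listing both sugar
  and an LCS counts as LCS-containing);
* some but not all → **MIXED**;
* none, but a caloric sweetener present (sugar lexicon: sugar, HFCS, corn
  syrup, sucrose, glucose, dextrose, fructose, maltose, honey, agave, cane
  juice, fruit-juice concentrate) → **SB**;
* no sweetener of either kind → **NONSWEETENED**.

Products whose contemporaneous ingredient list could not be located are
represented as *unknown* (not empty) and excluded from the tally, recorded
in provenance.  If only unknowns remain, the description can still decide —
but only through a deliberately narrow explicit-LCS term subset
(*low/no-calorie sweetener*, *sugar-free*, *diet*, *dietetic*, *artificial
sweetener*).  *Light*, *reduced sugar*, and *less sugar* are excluded from
that subset because worked-example brands carrying those words contain no
LCS; and when ingredient evidence contradicts an explicit description, the
ingredients win (the conflict is logged in provenance).  With no usable
evidence at all the classifier raises rather than guesses; a permissive
table-construction mode downgrades this to a warning and falls back to the
<40 kcal/8 fl oz density rule so the label map stays total.

The caloric-sweetener rule is how the package distinguishes SB from
NONSWEETENED without a schema flag: it is data-driven, but it does require
product rows for sugar-sweetened beverages to name their caloric sweetener.

### Packaged worked-example fixtures

The 17-foodcode fruit-juice-drink universe and the 14-product mixed-code
example are shipped as CSV fixtures.  LCS listings, category assignments,
and energy values are transcribed from the published tables; full ingredient
lists are not published, so product rows carry minimal reconstructed lists
(the listed LCS verbatim, plus a caloric sweetener where the manufacturer
energy indicates sugar).  Database energy is stored as kcal/100 g with a
30 g/fl oz conversion factor, rounded to four decimals such that the strict
`<` boundary behaviour of every printed value is preserved in floating
point (printed 50 kcal/240 g does not pass <50; printed 5 kcal/8 oz passes
<5).

## Recall pipeline

Volumes convert as `oz = grams / grams_per_floz` with each foodcode's own
factor (beverage densities span roughly 24–32 g/fl oz in recent cycles;
LCS-sweetened beverages are lighter than sugar-sweetened ones, so a shared
factor would bias volume comparisons).  Plain-water intake comes from the
dietary questionnaire variable at 29.6 g/fl oz; a discrepancy flag fires
when the questionnaire grams differ from the summed plain-water recall items
by more than 1 g (the surveys report such mismatches in ~3% of recalls but
no tolerance, so 1 g — effectively "any real disagreement" — is the
package's choice).  Unsweetened carbonated water is excluded from water by a
configurable code set.  Eligibility: age 2–17, reliable in-person recall, no
diabetes diagnosis; day-1 recall only.

Group assignment uses ≥ for "at least 4 oz" and < for "fewer than", exactly
as the group definitions are worded.  Participants meeting no criterion are
UNGROUPED and never enter outcome models; the analysis concerns exactly four
groups and is silent about the remainder.  Mixed-code volume is added to the
effective LCSB total under the mixed-as-LCSB scenario and to the effective
SB total under mixed-as-SB, which yields two structural monotonicities
(LCSB ∪ LCSB+SB membership can only grow, SB membership only shrink, when
mixed volume moves to the LCSB side).  Water-group invariance across
scenarios is *not* a theorem of the rule — a participant whose mixed volume
pushes exactly one effective class over 4 oz could enter or leave the water
group — but holds in the synthetic design because mixed volume is only drawn
for sweetened-beverage consumers; the tests assert it on generated data.

## Survey statistics

**Estimator.** Weighted least squares
`β̂ = (XᵀWX)⁻¹XᵀWy` with Taylor-linearization covariance: per-observation
scores `uᵢ = wᵢeᵢxᵢ` are totalled within PSU, and each stratum *h* with
*n_h* PSUs contributes `n_h/(n_h−1) Σ_j (z_hj − z̄_h)(z_hj − z̄_h)ᵀ` to the
middle matrix (with-replacement first-stage approximation).  Residual df is
`#PSUs − #strata`.  Lonely-PSU strata (a single PSU) contribute the squared
deviation of their total from the grand mean of all PSU totals with unit
factor — the "centered at the grand mean" convention, switchable to a hard
error.  Under one stratum with singleton PSUs this collapses to textbook WLS
with a centered sandwich (HC0 × n/(n−1)) covariance; multiplying all weights
by a constant changes nothing.  Singular designs raise an error naming the
aliased columns.  No installed Python library offers design-based survey
regression, so this layer is implemented from first principles and verified
against brute-force score-total oracles in the tests.

**Transform ladder.** Residual normality is operationalized as weighted
residual skewness |γ₁| < 0.5 (the source analysis states only that
non-normal residuals were transformed "until residuals achieved normality",
naming no test; skewness is the property power transforms actually repair).
The ladder is identity → √y → log y → −1/√y → −1/y, refitting at each rung
and accepting the first that passes; negative-reciprocal signs keep every
rung monotone increasing.  Rungs whose domain excludes observed outcomes are
rejected rather than shifted; if nothing passes, the rung with the smallest
|skewness| is used.

**Least-squares means.** LSM_g is the model prediction for group *g* at the
survey-weighted covariate profile: weighted means for continuous covariates
and weighted level proportions for categorical ones (the evaluation point is
not documented in the source analysis; the weighted-population profile is
the package's choice).  SEs follow by the delta method, `√(LᵀV̂L)`.  LSMs and
SEs are reported on the raw scale; pairwise comparisons use the
transformed-scale fit.

**Tukey–Kramer.** For each pair, `p_adj = P(Q_{k,df} > √2|t|)` with the
studentized-range distribution at the design df; at k = 2 this is exactly
the two-sided t-test.  Compact letters label the maximal cliques of the
non-significance graph at α = 0.05 (exhaustive search, fine for ≤ a handful
of groups).  The comparison family is one outcome-model fit, matching the
letter-per-row presentation of such analyses.  Degenerate contrasts (zero
SE) get p = 1 when the difference is also zero, else p = 0.

**Models.** Model 1: group + age + sex + race/ethnicity + income + physical
activity + BMI percentile; Model 2 adds total energy (energy itself is
therefore only a Model 1 outcome).  Rows with missing used columns are
dropped and counted.  When cycles are pooled, multi-cycle weights should be
rescaled by 1/#cycles before entering the pipeline; the estimator itself is
scale-invariant, so this matters only for population totals, which the
package does not produce.

## Sensitivity analysis

`run_scenario` is deterministic given inputs and configuration (no pipeline
stage draws random numbers).  The classification table is computed once and
shared; only group assignment and the downstream models differ between
scenarios.  `diff_scenarios` errors if the two results do not partition the
same eligible population or disagree on classification counts, and reports
per-group Δn, adjusted-significance flips at 0.05 (adjusted p-values only,
matching the letter-based presentation), and the largest absolute LSM shift
per outcome/model.

## Synthetic data

The generator emulates, per configuration: universe composition 30% LCSB /
58% SB / 4% mixed / 8% non-sweetened (after the 137/295/16 single-cycle
classification counts, with a non-sweetened remainder), apportioned by
largest remainder so configured fractions are met exactly; 1–3 brands per
code with mixed codes forced to carry disagreeing products; database energy
by class (LCSB 0–15, SB 60–160, mixed 60–140 kcal/8 oz) with manufacturer
values jittered by N(0, 3) and, with probability 0.1, resampled from the far
side of the 40 kcal boundary (stressing density-criterion misclassification
exactly as the discordant worked-example codes do); conversion factors
U[24, 32]; group propensities 0.15/0.08/0.61/0.11/0.05
(water/LCSB/SB/both/ungrouped, after the re-analysis group sizes); additive
outcome effects (energy baseline 1560 kcal; +160/+320/+490 for
LCSB/SB/both) with Gaussian noise and fixed covariate effects; a 15-strata ×
2-PSU design with lognormal weights; a 3% water-questionnaire mismatch rate;
5% ineligible participants.  Default population size is 1200 participants —
large enough for stable group sizes and fits while keeping full-pipeline
simulations cheap; statistical calibration tests use dedicated sizes (500
replicates of n = 400 for coverage, 1000 null simulations of n = 200 for
family-wise error, 100 universes of 30 codes × 150 participants for the
scenario properties).

Volumes are drawn in fluid ounces on the correct side of the 4 oz threshold
(≥4.5 or ≤3.5, keeping the strict boundary untouched by float round-trip),
then stored as grams through each code's factor.  Mixed-code volume
(0.5–6 oz) is drawn for 8% of sweetened-beverage consumers, which is what
makes the two scenarios disagree.  Truth bookkeeping records true code
classes, per-scenario true groups (recomputed by the generator's own
arithmetic from the drawn volumes), intended groups, and noiseless outcome
means, so recovery tests score the pipeline exactly.

What the generator does **not** emulate: realistic brand text, nutrient
correlations beyond a linear energy coupling, day-2 recalls, within-person
repeated measures, informative sampling (weights are independent of
outcomes), cluster-level random effects, or item nonresponse.  Passing tests
therefore demonstrate correctness of the algorithms and calibration of the
variance machinery under a clean design-based data-generating process — not
robustness to the messiness of real survey microdata.

## Known limitations

* The SB/NONSWEETENED distinction relies on caloric sweeteners being named
  in product ingredient rows; a sugar-sweetened product with an empty
  ingredient list would be labelled non-sweetened.
* Manufacturer energy at the foodcode level is the minimum over brands; no
  consumption-weighted aggregation is attempted.
* The lonely-PSU grand-mean convention can understate variance when lonely
  strata are systematically extreme.
* The letter display is exponential in the number of groups; it is intended
  for the four consumer groups, not general post-hoc use.
* Day-2 (phone) recalls, BMI-percentile computation, and correction of the
  known plain-water miscoding are out of scope; BMI percentile is consumed
  as a covariate, not derived.
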