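# Methods

## Scope and perspective

The package implements a trial-based economic evaluation from the societal
perspective over a 12-month horizon: intervention delivery costs, health
care costs valued with standardized Dutch unit prices, and patient time and
travel costs (friction-cost valued, entering only through the sensitivity
scenario). Costs and effects are not discounted, consistent with the short
horizon. Analyses follow the intention-to-treat principle: every
randomized participant is analyzed in their assigned arm, with missingness
handled by single imputation per outcome.

## Costing

Unit prices carry a price year and are indexed multiplicatively to the
2011 analysis year with consumer price indices (105.38 for 2009, 109.02
for 2011); indexing commutes with valuation since both are linear.
Medication is costed from the defined-daily-dose price: the drug amount is
discounted by the statutory pharmacist clawback, 6% VAT is added, and one
prescription charge applies per dispensed course. The clawback rate
(6.82%) and prescription charge (€6.00) are configuration defaults,
overridable per call — the concepts are standard in Dutch pharmaco-costing
but the applicable rates vary by year and contract.

Resource use is measured by 3-month retrospective recall at 6 weeks,
6 months and 12 months. Because the recall windows do not tile the year —
the 6-week window reaches back before randomization, and the later waves
are 4.5 and 6 months apart — each follow-up window's cost is weighted by
(gap since the previous wave) / (recall length 0.25 y): weights 0.46,
1.54 and 2.0 for the default wave layout, summing to 4.0 so that the
annual horizon is covered exactly once and pre-randomization use (the
baseline questionnaire) never enters annual totals. This weighting is the
package's own choice; any convention that covers the year without double
counting would be defensible, and the weights adapt automatically to other
wave layouts.

Intervention costs are fixed per arm: €57.70 (MTC), €7.70 (MT), €0 (UC)
in the primary scenario; €141.89 / €82.24 / €0 in the sensitivity
scenario, which folds the monetary value of participants' time and travel
(increments of €84.19 and €74.54) into the program costs.

## Imputation

Costs, EQ-5D items and the addiction score are imputed from the
participant's own adjacent waves: an interior gap whose two neighboring
waves are both observed takes the mean of the neighbors; otherwise the
last observation is carried forward, and leading gaps take the next
observation carried backward. EQ-5D item means are rounded back to levels
{1, 2, 3}; a .5 mean rounds toward the *more severe* level, a conservative
choice on utility that parallels the negative abstinence scenario (the
source analysis does not state a direction). Missing smoking status is
never interpolated: the negative scenario codes anyone lost to follow-up
as still smoking, so the imputation can only lower abstinence rates.

A series with no observation at all is flagged non-imputable; the
participant is excluded from the analyses needing that field but retained
wherever data exist — abstinence is always analyzable. This mirrors
per-outcome availability denominators rather than listwise deletion.

## Utilities and QALYs

EQ-5D-3L states are scored by a pluggable value set defined on all 243
states and anchored at 1.0 for full health (11111); the shipped Dutch
tariff is the additive three-level model with a constant decrement for any
departure from full health, per-dimension level decrements, and an extra
decrement when any dimension is at level 3 (worst state 33333 scores
−0.329). QALYs are the area under the utility–time curve. The default
integration is trapezoidal (linear interpolation between waves), the
standard trial-based convention; a rectangle rule (each interval valued at
its starting utility, i.e. duration × quality weight of the entered
state) is available as `auc_method: rectangle` for sensitivity. For
constant profiles both rules coincide with utility × horizon. Profiles
spanning other than one year are integrated as given with a warning.

## Uncertainty analysis

Bootstrap resampling is stratified by arm — participants are resampled
with replacement within their arm, preserving the randomized arm sizes —
because the design fixes those sizes and the published contrasts are
per-arm. Annual-cost confidence intervals use 5000 replicates and
equal-tailed percentile intervals (numpy linear-interpolation
percentiles); acceptability curves use 1000 replicates, both configurable.
At each willingness-to-pay value on the default grid (€0 to €100,000 in
€500 steps) the arm with the strictly highest net monetary benefit wins a
replicate; exact ties split the replicate equally among the tied arms,
which is unbiased for degenerate replicates and keeps the per-WTP
probabilities summing to one. The headline probability table is reported
at WTP €18,000. Effects are coded internally as probabilities in [0, 1];
the 1/2 survey coding maps to 0/1 and differences are unaffected.

All randomness flows from one root seed through named substreams
(simulation, missingness, cost bootstrap, CEAC bootstrap), so identical
configuration and seed reproduce identical artifacts bit for bit.

## The synthetic-trial generator

The generator emulates the study conditions the analysis assumes:

- **Arms and waves.** 163/132/119 participants (MTC/MT/UC), waves at 0,
  0.115 (6 weeks), 0.5 and 1.0 years.
- **Costs.** Per-category resource counts are negative binomial
  (variance = m + αm², default α = 4) with arm-specific mean euro spend
  per 3-month window taken from the arms' baseline cost profiles; euros
  are counts × indexed unit prices, giving right-skewed annual costs.
  A single dispersion parameter cannot reproduce the most extreme
  category-specific tails (hospital SDs an order of magnitude above the
  mean) while staying realistic for routine categories; arm-level
  contrasts, not extreme tail shape, are what the downstream tests rely
  on.
- **Utilities.** EQ-5D items are sampled from a one-factor Gaussian
  copula (ρ = 0.45 across dimensions, 60% of latent variance persistent
  across waves) with per-dimension marginal level probabilities chosen so
  that scored baseline utilities come out near mean 0.8, SD 0.2 under the
  Dutch tariff. Items — not utilities — are sampled, so the scoring path
  is exercised end to end. Other target means are reached by a latent
  location shift found by bisection; the SD is not independently tunable.
- **Abstinence.** Prolonged abstinence at 12 months is Bernoulli per arm
  (defaults 0.086/0.152/0.101) in the *complete* data; abstainers are
  also abstinent at 6 months (the prolonged definition), with transient
  early quitting among eventual non-abstainers. After 44% dropout and
  negative-scenario imputation the intention-to-treat rates are lower by
  roughly the retention factor — the true abstinence rate among dropouts
  is unobservable in any real trial, so the generator pins the complete-
  data rates rather than the post-imputation ones.
- **Dropout.** Monotone: a dropout's first missing wave is drawn from
  (0.4, 0.3, 0.3) over the three follow-up waves (per-wave retention is a
  free parameter; only 12-month retention is pinned), and everything from
  that wave on is missing; baseline is never missing. The dropout
  probability is logistic in age with slope −0.04 per year and an
  intercept solved by root-finding so the realized-age marginal rate
  equals the 0.442 target; completers are therefore older on average.

What the generator does **not** emulate: item-level (non-monotone)
nonresponse, correlation between dropout and outcomes beyond age,
seasonal or secular cost trends, and within-category price heterogeneity.
Passing tests therefore demonstrate that the pipeline recovers known
parameters under the assumed structure, not that these assumptions hold
in any particular real dataset.

## Numerical choices and degenerate inputs

- ICER undefined at ΔE = 0: the ratio is `None` and the classification
  follows the cost sign alone (equal costs and effects → `equivalent`).
  Ratio signs are not interpreted — quadrant labels carry direction, and
  (ΔC, ΔE) and (−ΔC, −ΔE) give the same ratio with flipped labels.
- Percentile CIs need ≥ 2 replicates; degenerate (constant) replicate
  sets give zero-width intervals.
- Euro amounts are kept at full precision internally; CSV artifacts round
  euros to 2 decimals and probabilities to 4 at write time only.
- Chi-square uses no continuity correction, matching the published
  statistics; zero margins raise rather than returning 0/0.
- One-way ANOVA with zero between- and within-group variance returns NaN
  (undefined), and infinity when only the within-variance vanishes.

## Known limitations and deliberate non-reproductions

The pairwise incremental probability for MTC vs UC printed in the source
analysis (−.02) is not reproducible from the published raw abstinence
counts, which give −.015 (→ −.01 at 2 decimals); the adjustment behind
the published "adjusted" costs and effects is unstated. The pipeline
computes unadjusted incrementals throughout and the acceptance suite
asserts the unadjusted value for that cell. For the same reason no
baseline-covariate adjustment is applied before the CEAC. Arm-level
annual cost tables and bootstrap probability tables from the original
participant-level data cannot be reproduced (the data are not deposited);
the synthetic pipeline reports its own computed analogues instead.
Problem sizes in the test suite are chosen for precision per unit time:
coverage checks use 500 simulated trials of 100 participants per arm with
1000 bootstrap replicates; parameter recovery uses 5000 participants per
arm.
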