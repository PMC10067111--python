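# Methods

## Model structure

A cohort of patients with driver-negative advanced/metastatic squamous
NSCLC starts in the progression-free state (PFS) on first-line therapy and
moves through first disease progression (FDP, second-line therapy), second
disease progression (SDP, third-line anlotinib), end-stage disease (best
supportive care) and death.  Each active treatment line also feeds a
single-cycle "discontinued therapy" tunnel: with the line's per-cycle
adverse-event discontinuation probability, a surviving, non-progressed
patient stops treatment, spends one cycle off drug at the current state's
utility (follow-up cost only, mortality per the governing OS curve), and
then moves to the next line's state.  Death is absorbing.  Cycle length is
21 days; the 20-year horizon spans 348 cycles; occupancy mass is conserved
to 1e-9 every cycle and the run aborts if it is not.

## Survival inputs and their time scale

Ten parametric curves drive the model: OS and PFS for first-line
sintilimab-GP and GP (ORIENT-12), second-line sintilimab (ORIENT-3) and
docetaxel, and third-line anlotinib (ALTER0303); nine are log-logistic
(S(t) = 1/(1 + θ·t^κ)) and the anlotinib pair Weibull
(S(t) = exp(−λ·t^γ)).  The parameter values carry no explicit unit, so the
package fixes it by checking the implied medians against the source trials:
on a "one unit = one 3-week cycle" scale the second-line sintilimab OS
median is 17.3 cycles = 11.9 months (trial: 11.79), docetaxel OS 8.4 months
(8.25), anlotinib OS 9.8 months (9.6) and anlotinib PFS 4.9 months (5.4);
a months scale misses these by ~45%.  The fixture therefore declares
`survival_time_unit: cycle`.  The survival module itself is unit-agnostic
and evaluates everything in log space, so transition probabilities remain
accurate in the deep tail.

## Clock and mortality conventions

The fitted inputs do not determine how a sequential model should index the
curves, so the engine implements three conventions (`ModelConfig.convention`):

* `sequential` — strict per-line semi-Markov: every curve on its own line's
  residence clock (reset at FDP/SDP entry); end-stage mortality continues
  the anlotinib OS on the line-3 clock.
* `stage-indexed` — every hazard on model time, the convention of
  stage-indexed probability tables in common decision-tree software.
* `anchored` (default) — after first progression, mortality in *every*
  downstream state follows the second-line OS curve on the
  time-since-second-line clock; PFS-derived progression-excess hazards
  (`max(0, tp_PFS − tp_OS)`, indexed on model time) partition the living
  into FDP / SDP / end-stage phases for cost and utility assignment.

The anchored default rests on two arguments.  Scientifically, the
second-line trial OS curves already integrate real-world downstream
treatment, so they are the best available estimate of survival after first
progression; routing both arms through the ALTER0303 anlotinib OS curve
instead (as `sequential` and `stage-indexed` do) erases the randomized
second-line OS difference between sintilimab and docetaxel that
distinguishes the strategies, and in this model flips the sign of the
incremental QALYs.  Empirically, only the anchored convention reproduces
the original analysis's reported occupancy pattern, in which the FDP state
accrues 0.49/1.01 QALYs — more person-time than the second-line *PFS*
curves alone can supply, so its FDP duration must have been governed by the
second-line OS curves.  The per-line conventions remain available and
tested.

Even under the anchored convention the reproduction is approximate: this
package obtains 1.29 vs 1.34 QALYs (reported: 1.37 vs 1.52) and
$13,679 vs $13,376 (reported: $12,203 vs $14,045), making the reserved
strategy dominant rather than costlier at ≈$12,700/QALY.  The residual gap
sits in the cost decomposition of the original report, whose per-state
entries are mutually inconsistent under any per-cycle costing we could
construct from the unit prices (its first-line-sintilimab PFS costs imply a
per-cycle outlay below the sintilimab price alone, while its GP-arm PFS
costs imply roughly twice the GP regimen cost).  The decision-relevant
conclusion — reserving sintilimab gains QALYs and is cost-effective at the
$35,663/QALY threshold — is reproduced by the default model.

## Costing and utilities

Unit drug prices are per Table-row dose at the reference patient (body
surface area 1.72 m², creatinine clearance 70 ml/min); per-m² components
scale with BSA and carboplatin with the Calvert dose
`AUC × (CrCl + 25)` (AUC 5).  The default regimens give one unit dose per
3-week cycle: sintilimab (flat $334.82) plus gemcitabine/cisplatin in line
1 with the chemotherapy backbone capped at six cycles (antibody continues
as maintenance), docetaxel or sintilimab alone in line 2, anlotinib
($665.97 per 168 mg cycle) in line 3.  Cisplatin is the default platinum;
carboplatin is fully supported but unused in the shipped regimens, so its
price is a deliberate no-op in sensitivity analysis.  Regimens are fully
configurable in the YAML fixture.

Active-treatment states also accrue routine follow-up ($55.60/cycle);
end-stage disease accrues BSC ($337.50/cycle).  The one-off grade-III/IV
adverse-event management cost of the first-line regimen is charged at model
entry, and the frequency-weighted AE disutility reduces the entry cycle's
utility.  Palliative care ($2,627.80/cycle) is charged for half a cycle at
each death transition — deaths occur mid-cycle on average — which matches
the original death-state cost (~$1,200 discounted); a full-cycle charge
would roughly double it.  Both the half-cycle fraction
(`death_cycle_fraction`) and an optional half-cycle correction for all
accrual (off by default, matching the original totals better) are
configuration flags.

QALYs accrue as occupancy × state utility × cycle-years, discounted by
(1.05)^(−k·cycle-years) at cycle k; tunnel states carry the utility of the
state the patient discontinued from and are folded into that state's row of
the reported decomposition.

## Pseudo-IPD reconstruction and fitting

`reconstruct_ipd` implements the standard reconstruction from digitized KM
coordinates plus a number-at-risk table: within each at-risk interval the
censor count is found by fixed-point iteration against the next interval's
at-risk figure, censor times are spread uniformly, and events at each
digitized step reproduce the published survival drop, with real-valued
allocations integerized by remainder-carrying rounding.  A reported total
event count constrains the final interval only when honouring it does not
degrade curve fidelity.  At n = 300 with six at-risk rows the round-trip
KM error is below 0.02 sup-norm at full digitization resolution; with only
~40 digitized points the error (~0.024) is dominated by the inter-click
survival gaps of the digitization itself, not the reconstruction.

Fitting maximizes the right-censored log-likelihood
Σ[δ·log f(t) + (1−δ)·log S(t)] per family with L-BFGS-B on log-transformed
parameters from three deterministic starts (the exponential rate has the
closed form events/total-time); model selection is by AIC, ties by BIC and
then family order.  The weibull/log-logistic routes are cross-checked
against lifelines' independent fitters in the test suite.  At n = 2000 the
generating parameters are recovered within 10% and AIC recovers the
generating family under ~20–25% censoring.

## Sensitivity analysis

Every input row except the survival parameters and (for PSA) the discount
rate carries a `ParameterSpec` with the published bounds: utilities at
their 95% CIs, costs/probabilities/patient characteristics at ±50%,
discount 0–8%.  One-way DSA re-runs both strategies at each bound; the
tornado table records both ICERs with dominance flags, and the summary
`max_icer` is taken over runs in trade-off quadrants (positive incremental
QALYs).  PSA assigns Beta to probabilities/utilities/disutilities, Gamma to
costs and Normal to BSA/CrCl, moment-matched so the mean equals the
baseline and the published range is read as a 95% interval
(sd = range/3.92); a Beta whose matched variance is infeasible has its sd
shrunk with a logged warning.  Survival parameters stay fixed in PSA as the
input table specifies.  With the base case cost-saving, the probability of
positive incremental net monetary benefit at $35,663/QALY comes out near
0.86 — higher than the original 67.6%, whose underlying dispersion
assumptions are not recoverable from the published inputs.

## Synthetic data

`simulate_trial` draws event times by inverse CDF (closed form for
exponential, Weibull, log-logistic and Gompertz; normal quantiles for
lognormal) with uniform and/or administrative censoring, seeded through
`numpy.random.default_rng`.  It emulates single-arm right-censored samples
from the fitted laws — not arm sizes, accrual, dropout patterns or interim
analyses of the source trials — so tests built on it validate the
reconstruction/fitting chain and the cohort engine, not trial-level
operating characteristics.

## Numerical choices and limitations

* Survivor functions are floored at exp(−745) and a conditional transition
  from a vanished state raises a degenerate-state error.
* Progression-excess hazards are clamped at zero when the death hazard
  exceeds the PFS-event hazard (late crossing of the fitted curves).
* Regimen cycle caps count cycles on the governing state clock; under the
  anchored convention the SDP clock is the line-2 clock, so a capped
  third-line component would be approximate (the shipped third-line regimen
  has no cap).
* Deterministic quantities are independent of the seed; PSA is reproducible
  byte-for-byte for a fixed seed.
* The model inherits the limitations of its inputs: indirect comparison of
  three single trials, utilities from external literature, aggregate AE
  costs/disutilities, and no treatment-waning or cure-fraction modelling.
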