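# sintcea

Markov cohort cost-effectiveness model for the timing of sintilimab — a
domestic Chinese anti-PD-1 antibody — in driver-negative advanced or
metastatic squamous non-small-cell lung cancer (sqNSCLC), from the Chinese
healthcare-system perspective.

Anti-PD-1/PD-L1 therapy works in both the first- and the second-line
setting, but re-use after progression is not recommended, so oncologists
must commit: give sintilimab up front with gemcitabine/platinum (GP)
chemotherapy, or give GP first and reserve sintilimab for second line?  The
package compares these two sequential strategies:

* **First-line sintilimab**: sintilimab + GP → docetaxel → anlotinib → BSC
* **Second-line sintilimab**: GP → sintilimab → anlotinib → BSC

## Model

A cohort Markov model with five main health states — progression-free
(PFS), first disease progression (FDP), second disease progression (SDP),
end-stage disease on best supportive care, and death — plus three
single-cycle "discontinued therapy" tunnel states fed by per-cycle
adverse-event discontinuation probabilities.  Cycle length is 3 weeks,
horizon 20 years (by then >99% of the cohort has died), and costs and QALYs
are discounted at 5% per year.

Transition probabilities come from parametric survival curves (log-logistic
and Weibull) fitted to the ORIENT-12, ORIENT-3 and ALTER0303 trials via the
standard chain of digitized Kaplan–Meier curves → pseudo individual-patient
data (Guyot reconstruction) → right-censored maximum likelihood → AIC
selection.  For a curve with survivor function *S(t)* the per-cycle
transition probability at state-clock *t* is

```
tp(t) = 1 − S(t + u) / S(t)
```

with cycle length *u*.  Progression and death compete:
`p(progression) = max(0, tp_PFS − tp_OS)`.  A strategy's cost per cycle
accumulates drug acquisition (dosing by body surface area and, for
carboplatin, the Calvert formula `dose = AUC × (CrCl + 25)`), routine
follow-up or BSC, one-off adverse-event management, and palliative care at
death; QALYs weight state occupancy by health-state utilities.  The
decision statistic is the incremental cost-effectiveness ratio
ICER = ΔCost/ΔQALY against a willingness-to-pay threshold of $35,663/QALY
(3× China's 2021 per-capita GDP).

One-way deterministic sensitivity analysis varies each input across its
published range; probabilistic sensitivity analysis draws all non-fixed
inputs jointly (Beta for probabilities/utilities, Gamma for costs, Normal
for patient characteristics) and reports a cost-effectiveness acceptability
curve.  See `docs/methods.md` for modelling conventions and their rationale
— in particular the time scale of the fitted curves and the clock/mortality
conventions, which the fitted inputs alone do not determine.

## Worked example

The complete base-case input set ships with the package, so the model runs
out of the box:

```sh
$ sintcea run --out out/
wrote 4 files to out/
  first_line_sintilimab: 1.286 QALYs, $13,679
  second_line_sintilimab: 1.338 QALYs, $13,376
  ICER (second vs first listed): dominant
```

Reserving sintilimab for second line yields 0.052 more QALYs; under this
package's costing conventions it is also slightly cheaper, i.e. dominant
(the original analysis reports it as costlier, with an ICER of ≈$12,700/QALY
— see `docs/methods.md` for the reconciliation).  Either way the strategy is
cost-effective at the $35,663/QALY threshold.  `out/summary_table.csv`
decomposes QALYs and costs by health state; `out/trace_*.csv` hold the
cycle-by-cycle state occupancy.

```sh
$ sintcea psa --out out/ --n 200 --seed 7
P(second strategy cost-effective at WTP $35,663) = 0.870 (200 draws, seed 7)
```

The library mirrors the CLI: `load_fixture()` →
`run_base_case()` / `run_dsa()` / `run_psa()` / `ceac()`, and the
reconstruction chain is available as `km_curve()` → `reconstruct_ipd()` →
`fit_parametric()` → `select_best()`.

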