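# Methods

## Model structure and assumptions

The model is a three-state partitioned-survival cohort model. State
membership at each cycle boundary comes directly from two survival curves:
NED occupancy equals recurrence-free survival, death equals one minus
overall survival, and recurrent/progressive disease (RPD) is the gap
between them. Patients never return from RPD to NED. Although the structure
is often described as a Markov model, deriving occupancy from the curves and
deriving it from per-cycle transition matrices are equivalent here; the
package exposes the matrix view (`to_transition_matrices`) as a derived
artifact and verifies the round trip to 1e-8. In that view NED outflow
splits between RPD and death, with cycle deaths drawn from RPD first and
only the remainder from NED — one of several conventions consistent with
the same trace; it is the one that keeps RPD→death maximal and never
produces negative flows when OS and RFS are consistent.

Cycle length equals the dosing interval of each strategy (2, 3 or 4 weeks;
weeks convert to months at 52/12). Occupancy is evaluated at cycle start
with no half-cycle correction: at 2–4-week cycles the correction is well
below the precision of everything else in the model. The lifetime horizon
runs to cohort age 100 (start age 50) or until less than 1e-6 of the cohort
remains alive.

Independently extrapolated RFS and OS curves can cross; when RFS exceeds
OS, NED is clipped to OS (RPD floored at zero) and a warning identifies the
affected cycles. The calibrated base case does this by construction in the
far tail (see Calibration below).

## Survival reconstruction and fitting

Digitized curves carry (time, survival) step points and a numbers-at-risk
table. At-risk counts at interval boundaries are interpolated linearly in
time, since published at-risk tables are sparse relative to digitized
points. Per interval, events and censorings solve the KM identity together
with the at-risk bookkeeping under uniform within-interval censoring. On
simulated arms (200 patients, three intervals) the reconstructed counts
track the simulator's true counts to about one patient.

Fitting maximizes the interval-censored likelihood: each event contributes
the log probability mass of its interval, each censoring the log survival
at the interval midpoint, and patients still at risk at the end of
follow-up the log survival there. This is deterministic — unlike
pseudo-individual-patient-data approaches there is no resampling step — and
agrees with direct maximum likelihood on the underlying individual data to
within digitization error (verified on simulated arms). Whether the original
spreadsheet implementation fitted by least squares on survival probabilities
or by likelihood is unknowable from the outside; likelihood was chosen
because it weights intervals by their information content and yields a
meaningful AIC.

Optimization uses Nelder-Mead on log-transformed parameters (location
untransformed for the log-normal), with a Powell polish on non-convergence.
AIC selects among exponential, Weibull, log-normal and log-logistic; ties
break toward fewer parameters, then family order. An override forces a
family — the pipeline default forces log-normal for both RFS and OS,
mirroring selection informed by visual assessment, with a logged warning if
it is not AIC-best.

Background mortality floors the extrapolation: on a monthly grid the
applied hazard is the maximum of the disease-model hazard and the
age-specific hazard `-ln(1 - qx)` from the life table. The maximum (rather
than the sum) guarantees modelled survival never exceeds general-population
survival without double-counting deaths already captured by trial OS.
Annual probabilities convert to per-cycle probabilities under a constant
hazard within the year. Both OS *and* RFS are floored: RFS events include
death from any cause, so the floor applies to it equally, and flooring both
reduces spurious curve crossing at high ages.

## Economic accounting

All accruals use state occupancy at cycle start times the cycle length.
Adjuvant drug acquisition and administration are charged per cycle to the
on-treatment fraction, which follows the RFS decrement up to the 12-month
duration cap. Scans (3-monthly to month 24, 6-monthly to month 60) are
charged per scheduled scan to everyone alive in the cycle containing it,
booked under the health-state components in proportion to occupancy.
Subsequent-treatment and best-supportive-care costs are charged once per
patient entering RPD, as an expected lump cost over the post-recurrence
mix — the near-constant best-supportive-care totals across published
columns are consistent with per-entrant costing, and no duration structure
for post-recurrence therapy is available. Weight-based drugs (ipilimumab,
3 mg/kg) are costed at the 78.4 kg cohort median weight.

Costs are discounted at 4.0 %/year, health effects at 1.5 %/year, with
discrete factors `(1 + r)^(-t)` applied at cycle start. Societal costs
(informal care, productivity, travel) are costs and therefore discounted at
the cost rate. Adverse-event costs and disutilities are out of scope, as is
any price-index adjustment: monetary inputs are assumed already expressed
at a single price year, recorded as config metadata.

## The calibrated base case

The original input tables are not available, so the fixture in
`synthetic_data` reconstructs a base case from published aggregates alone.
Everything below is a fitting procedure, not ground truth.

* **RFS curves.** Log-normal survival is solved exactly (2x2 linear system
  in mu and 1/sigma) through published 1- and 3-year recurrence-free rates:
  ICI 75 %/64 %, targeted therapy 88 %/58 %, routine surveillance 62 %/44 %.
* **OS curves.** One treated and one surveillance OS curve (the treated
  curve is shared by all three strategies, as the most mature trial's OS
  was used for all). Sigma is fixed at 0.8 and mu root-found so discounted
  total life years — which depend only on OS — equal the published totals
  (8.70 treated, 7.29 surveillance).
* **Unit costs.** Each published discounted cost component equals one unit
  cost times one discounted accrual from the trace (treated cycles,
  recurrence mass, state-years, visits), so unit costs are set to
  component / accrual. The accumulated pipeline then reproduces every
  published component to within EUR 1. Scan costs are folded into the
  calibrated state costs (they cannot be disaggregated from the published
  rows); productivity is calibrated as a flat rate per alive-year.
* **Utilities.** The published per-state QALY/LY ratios imply arm-specific
  utilities (treated NED ~0.87 vs surveillance ~0.77), so utilities are
  per-strategy: RPD utility is fixed at 0.72 (treated) / 0.68
  (surveillance) from those ratios and NED utility is solved against the
  published QALY totals.

Two published effects are *not* reproduced: the anchor-constrained
log-normal RFS tails are heavier than the original full-curve fits, so the
per-state NED/RPD life-year splits differ from the published splits even
though totals, QALYs, cost components and ICERs per QALY land on the
published values. ICERs per LY deviate by ~1.5 % because per-arm traces use
their own cycle discretization while both arms' published LY totals are
identical.

The synthetic Gompertz-Makeham life table (hazard `5e-4 + 3e-5 * 1.09^age`)
stands in for a national table; it reproduces the right order of magnitude
for adult background mortality (q50 ~0.003) but no cohort or sex structure.

## Sensitivity analysis

One-way analysis varies each registered parameter to its bounds (costs
±25 % of baseline, utilities over ±0.03 as a stand-in 95 % CI) holding all
else fixed, and adds a time-horizon entry (lifetime vs 15 years); entries
are ranked by ICER range with name-based tie-breaking so ordering is
independent of registry order.

The PSA draws all parameters jointly and independently from one seeded
generator in fixed registry order: gamma for costs, beta for utilities,
both moment-matched so the mean equals the base case and the central 95 %
interval matches the stated spread (`sd = fraction * mean / 1.96` for
costs). Unit costs taken from a single national price list are sampled as a
*shared multiplier* applied to both arms — sampling each arm's copy of the
same tariff independently would model two different price lists and
manufacture spurious incremental-cost variance. Adjuvant drug acquisition
prices are treated as fixed tariffs (known list prices, not uncertain
quantities) and excluded from the PSA registry, consistent with Dutch
costing practice; they are varied in the one-way analysis. Survival-curve
uncertainty is not propagated (the original analysis gives no indication it
was); this understates total decision uncertainty. Invalid draws are
resampled with a counter and a warning above a 1 % rate.

## Synthetic trial arms

`simulate_trial_arm` draws event times from a chosen family, applies
constant-hazard censoring plus administrative censoring at the last grid
point, computes the exact KM estimator (via lifelines) and at-risk counts,
and digitizes onto the grid. The default digitization grid spacing should
be small relative to the event-time median — the recovery studies use about
one ninth of the median — since digitizing a steep early curve coarsely
discards most of the information the interval likelihood uses. The
simulator emulates digitization of a clean published plot: no coordinate
jitter, no at-risk rounding, no delayed-entry or competing risks. Passing
recovery tests therefore show correctness of the reconstruction/fit chain,
not robustness to digitization noise.

At 500 patients per arm, distinguishing log-normal from log-logistic by AIC
is near the information limit: direct maximum likelihood on the raw
simulated data picks the generating family in about 18 of 20 seeds, and the
digitized pipeline matches that rate. Per-seed parameter recovery at
n = 500 is limited by sampling noise (a ~1-in-20 sample puts sigma's MLE
itself ~10 % off); recovery within 10 % holds on average over seeds, and
per-seed at n = 1000.

## Numerical choices

* Interval likelihood guards all logs at 1e-300; failed optimizations raise
  a named fit-failure error rather than returning garbage.
* Blended survival is interpolated log-linearly between monthly grid
  points; evaluation beyond the grid clamps to the last value.
* Occupancy sums are enforced to 1e-9, matrix round trips to 1e-8,
  accounting identities to 1e-6 EUR.
* Monetary outputs are reported to the nearest euro; internal arithmetic is
  full precision.
* All randomness flows through `numpy.random.default_rng(seed)`; PSA draws
  and simulated arms are bitwise reproducible per seed.

## Known limitations

* The calibrated base case is one of many parameterizations consistent with
  the published aggregates; between-component trade-offs (e.g. scan vs
  state costs) are not identified.
* Partitioned survival cannot represent treatment effects on
  post-recurrence survival separately from recurrence effects.
* No tunnel states: RPD costs and utility do not depend on time since
  recurrence, which is why subsequent treatment is a lump cost.
* Beta utility spreads are stand-ins; the original confidence intervals are
  not published in the main text.
* The 15-year-horizon scenario and the WTP grid are the only scenario
  analyses; no EVPI/EVPPI.
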