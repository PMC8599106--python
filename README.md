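# melcea

Cost-effectiveness modelling of adjuvant systemic therapy for resected
stage III melanoma, from a societal perspective.

Three systemic strategies — nivolumab (2-week cycles), pembrolizumab
(3-week cycles) and dabrafenib–trametinib (4-week cycles), each given for up
to one year after complete resection — are compared against routine
surveillance. Because long-term trial follow-up is unavailable, the model
works from *digitized* Kaplan–Meier curves: published recurrence-free
survival (RFS) and overall survival (OS) coordinates plus numbers-at-risk
tables are converted back into interval event data, fitted with parametric
event-time distributions, and extrapolated over a lifetime horizon.

## The model

**Survival reconstruction and extrapolation.** For each digitized interval
the package solves the Kaplan–Meier identity
`S(t_end) = S(t_start) · (1 − d/n_eff)` jointly with the at-risk bookkeeping
`n_end = n_start − d − c` (censoring uniform within the interval,
`n_eff = n_start − c/2`) to recover events `d` and censorings `c`. Four
families — exponential, Weibull, log-normal, log-logistic — are fitted by
maximizing the interval-censored likelihood, and selected by AIC
(`AIC = 2k − 2 ln L`), with an override to force a family where visual
assessment argues for it. Extrapolated curves are floored at general-
population mortality: on a monthly grid the applied hazard is
`max(h_disease, h_background)` with `h_background = −ln(1 − q_x)` from a
life table.

**Cohort model.** A three-state partitioned-survival structure — NED (no
evidence of disease), RPD (recurrent/progressive disease), death — with
`NED(t) = RFS(t)`, `death(t) = 1 − OS(t)`, `RPD(t) = OS(t) − RFS(t)`, and an
equivalent per-cycle transition-matrix view. Patients on treatment follow
the RFS decrement (`RFS(t−1) − RFS(t)` newly recur each cycle) up to the
one-year cap.

**Economics.** Per cycle the model accrues adjuvant drug acquisition and
administration, surveillance scans (3-monthly for 2 years, then 6-monthly
for 3), annual health-state costs, recurrence-triggered subsequent-treatment
and best-supportive-care lump costs (weight-based drugs costed at the
78.4 kg cohort median), and societal costs (informal care, productivity
loss, travel). Costs are discounted at 4.0 %/year and health effects at
1.5 %/year (Dutch guidance). Strategies are compared by
`ICER = ΔCost/ΔQALY` (and per LY) with dominance flags, and by net monetary
benefit `NMB = λ·ΔQALY − ΔCost` at a willingness to pay of €50 000/QALY.

**Uncertainty.** One-way sensitivity analysis re-runs the pipeline at each
parameter's bounds (costs ±25 %, utilities over 95 % CIs, lifetime vs
15-year horizon) ranked for a tornado diagram; probabilistic sensitivity
analysis draws all parameters jointly (gamma for costs, beta for utilities;
1000 Monte-Carlo iterations) and summarizes cost-effectiveness
acceptability curves.

## Worked example

```python
from melcea import build_reference_fixture, accumulate, compare

fixture = build_reference_fixture()
nivo = accumulate(fixture.trace("nivolumab"), fixture.specs["nivolumab"])
surv = accumulate(
    fixture.trace("routine_surveillance_ici"),
    fixture.specs["routine_surveillance_ici"],
)
comp = compare(nivo, surv, wtp=50_000)
print(f"total cost nivolumab     EUR {nivo.total_cost:,.0f}")
print(f"total cost surveillance  EUR {surv.total_cost:,.0f}")
print(f"QALYs: {nivo.qalys.total:.2f} vs {surv.qalys.total:.2f}")
print(f"ICER  EUR {comp.icer_per_qaly:,.0f}/QALY")
print(f"NMB at EUR 50,000/QALY: EUR {comp.nmb_at_wtp:,.0f}")
```

prints

```
total cost nivolumab     EUR 168,826
total cost surveillance  EUR 126,095
QALYs: 7.43 vs 5.41
ICER  EUR 21,154/QALY
NMB at EUR 50,000/QALY: EUR 58,269
```

Adjuvant nivolumab costs €42,731 more per patient than routine surveillance
and yields 2.02 extra quality-adjusted life years, i.e. about €21,000 per
QALY gained — well under the €50,000 Dutch threshold for this disease
burden, so the positive net monetary benefit says the strategy is
cost-effective at that threshold.

The same pipeline runs from files: `melcea fixture --out-dir bundle` writes
a complete input bundle (digitized KM CSVs, life table, strategy JSONs,
run config), `melcea run-model --config bundle/run_config.json` executes
it, and `melcea simulate` writes a sampled (noisy) bundle instead. `melcea
dsa`, `psa` and `ceac` run the sensitivity stages.

## Layout

- `melcea.survival_models` — KM reconstruction, interval-likelihood fits,
  AIC selection, background-mortality blending
- `melcea.markov_engine` — cohort traces, transition matrices,
  treated-fraction series
- `melcea.economics` — strategy parameterization, discounted accumulation,
  ICER/NMB comparisons
- `melcea.sensitivity` — tornado, PSA, CEAC
- `melcea.synthetic_data` — trial-arm simulator, life tables, calibrated
  base-case fixture
- `melcea.interface` / `melcea.cli` — config validation, orchestration,
  report writers, command line

See `docs/methods.md` for the modelling assumptions, calibration procedure
and known limitations.
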