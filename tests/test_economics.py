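"""Discounting, cost/QALY accumulation, and incremental comparisons."""

import copy

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import MONTHLY_SCHEDULE, make_trace
from melcea.economics import (
    COST_COMPONENTS,
    CEAResult,
    DiscountRates,
    SocietalCosts,
    SpecValidationError,
    StrategySpec,
    SubsequentTreatment,
    Utilities,
    WeightBasedDrug,
    accumulate,
    compare,
    discount_factor,
)
from melcea.markov_engine import CycleSchedule, WEEKS_PER_MONTH


def zero_spec(**kw) -> StrategySpec:
    kw.setdefault("name", "toy")
    kw.setdefault("schedule", MONTHLY_SCHEDULE)
    kw.setdefault("discount", DiscountRates(cost_rate=0.0, effect_rate=0.0))
    return StrategySpec(**kw)


class TestDiscountFactor:
    def test_zero_rate_is_one_everywhere(self):
        assert discount_factor(0.0, 0.0) == 1.0
        assert np.all(discount_factor(np.linspace(0, 50, 7), 0.0) == 1.0)

    def test_closed_form_values(self):
        assert discount_factor(2.0, 0.04) == pytest.approx(0.924556, abs=1e-6)
        assert discount_factor(10.0, 0.015) == pytest.approx(0.861667, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1.0, 0.04)


class TestAccumulate:
    def test_identity_accounting(self):
        # Everyone alive in NED for ten undiscounted years, no costs,
        # utility one: LYs = QALYs = 10 and zero spend.
        n = 121
        trace = make_trace(np.ones(n), np.zeros(n), cap_months=0.0)
        res = accumulate(trace, zero_spec())
        assert res.total_cost == 0.0
        assert res.lys.total == pytest.approx(10.0)
        assert res.qalys.total == pytest.approx(10.0)

    def test_three_cycle_hand_oracle(self):
        # Hand-computed (exact decimal arithmetic) totals for a 3-cycle toy:
        # drug EUR 1000/cycle while on treatment, u_ned = 0.8, 4%/1.5% rates.
        trace = make_trace([1.0, 0.9, 0.8, 0.7], [0.0, 0.05, 0.1, 0.15])
        spec = zero_spec(
            drug_cost_per_cycle=1000.0,
            utilities=Utilities(u_ned=0.8, u_rpd=0.0),
            discount=DiscountRates(cost_rate=0.04, effect_rate=0.015),
        )
        res = accumulate(trace, spec)
        assert res.costs["adjuvant_acquisition"] == pytest.approx(2691.8509, abs=5e-3)
        assert res.total_cost == pytest.approx(2691.8509, abs=5e-3)
        assert res.qalys.total == pytest.approx(0.17979342, abs=1e-7)
        assert res.lys.total == pytest.approx(0.23721596, abs=1e-7)
        assert res.costs_undiscounted["adjuvant_acquisition"] == pytest.approx(2700.0)
        assert res.qalys_undiscounted.total == pytest.approx(0.18)

    def test_recurrence_lump_costs(self):
        # 0.1 cohort mass recurs at month 1 (undiscounted): mix of one
        # treatment at EUR 10 000 with probability 0.6 plus BSC EUR 2 000.
        trace = make_trace([1.0, 0.9, 0.9], [0.0, 0.1, 0.1], cap_months=0.0)
        spec = zero_spec(
            bsc_cost_per_patient_entering_rpd=2000.0,
            subsequent_treatments=[
                SubsequentTreatment("systemic", 0.6, 10_000.0, 500.0)
            ],
        )
        res = accumulate(trace, spec)
        assert res.costs["subsequent_acquisition"] == pytest.approx(0.1 * 0.6 * 10_000)
        assert res.costs["subsequent_admin"] == pytest.approx(0.1 * 0.6 * 500)
        assert res.costs["bsc"] == pytest.approx(0.1 * 2000)

    def test_weight_based_drug_costed_at_median_weight(self):
        # Ipilimumab-style: 3 mg/kg at 78.4 kg median weight, 4 doses.
        trace = make_trace([1.0, 0.9, 0.9], [0.0, 0.1, 0.1], cap_months=0.0)
        drug = WeightBasedDrug(
            label="ipilimumab", probability=0.5, cost_per_mg=40.0,
            dose_mg_per_kg=3.0, n_doses=4,
        )
        assert drug.acquisition_cost == pytest.approx(40.0 * 3.0 * 78.4 * 4)
        spec = zero_spec(rpd_weight_based=drug)
        res = accumulate(trace, spec)
        assert res.costs["subsequent_acquisition"] == pytest.approx(
            0.1 * 0.5 * drug.acquisition_cost
        )

    def test_scan_costs_charged_to_alive_on_scan_cycles(self):
        # Default schedule scans at months 3..24 (3-monthly): with a horizon
        # of 7 months only the two scans at 3 and 6 months are charged.
        n = 8
        trace = make_trace(np.ones(n), np.zeros(n), cap_months=0.0)
        spec = zero_spec(scan_cost_per_event=100.0)
        res = accumulate(trace, spec)
        assert res.costs["health_state_ned"] == pytest.approx(200.0)

    def test_cycle_length_mismatch_rejected(self):
        trace = make_trace([1.0, 0.9, 0.8], [0.0, 0.0, 0.0])
        spec = zero_spec(schedule=CycleSchedule(cycle_length_weeks=2.0))
        with pytest.raises(ValueError, match="cycle length"):
            accumulate(trace, spec)

    def test_overfull_subsequent_mix_rejected(self):
        trace = make_trace([1.0, 0.9, 0.8], [0.0, 0.0, 0.0])
        spec = zero_spec(
            subsequent_treatments=[
                SubsequentTreatment("a", 0.7, 1.0),
                SubsequentTreatment("b", 0.5, 1.0),
            ]
        )
        with pytest.raises(SpecValidationError, match="sum"):
            accumulate(trace, spec)


class TestCompare:
    def test_published_worked_example(self, reference_fixture):
        # Printed totals and QALYs/LYs give ICER EUR 21 153/QALY for
        # nivolumab against routine surveillance.
        s = reference_fixture.reported_result("nivolumab")
        c = reference_fixture.reported_result("routine_surveillance_ici")
        comp = compare(s, c)
        assert round(comp.icer_per_qaly) == 21_153
        assert comp.delta_cost == pytest.approx(42_730.0)
        assert comp.delta_qaly == pytest.approx(2.02)

    def test_self_comparison_is_undefined(self, reference_fixture):
        r = reference_fixture.reported_result("nivolumab")
        comp = compare(r, r)
        assert comp.delta_cost == 0.0 and comp.delta_qaly == 0.0
        assert comp.qaly_flag == "undefined"
        assert comp.icer_per_qaly is None
        assert comp.nmb_at_wtp == 0.0

    def test_cheaper_and_more_effective_is_dominant(self):
        a = CEAResult.from_components("a", {"health_state_ned": 1000.0}, (5.0, 0.0), (4.0, 0.0))
        b = CEAResult.from_components("b", {"health_state_ned": 2000.0}, (4.0, 0.0), (3.0, 0.0))
        comp = compare(a, b)
        assert comp.qaly_flag == "dominant"
        assert comp.icer_per_qaly is None

    def test_costlier_and_less_effective_is_dominated(self):
        a = CEAResult.from_components("a", {"health_state_ned": 2000.0}, (4.0, 0.0), (3.0, 0.0))
        b = CEAResult.from_components("b", {"health_state_ned": 1000.0}, (5.0, 0.0), (4.0, 0.0))
        assert compare(a, b).qaly_flag == "dominated"


@st.composite
def random_spec_and_trace(draw):
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    n = draw(st.integers(3, 40))
    ned = np.sort(rng.uniform(0, 1, n))[::-1]
    ned[0] = 1.0
    alive = np.minimum(ned + rng.uniform(0, 0.3, n), 1.0)
    alive = np.maximum.accumulate(alive[::-1])[::-1]  # alive non-increasing
    alive[0] = 1.0
    alive = np.maximum(alive, ned)
    trace = make_trace(ned, alive - ned)
    spec = StrategySpec(
        name="rand",
        schedule=MONTHLY_SCHEDULE,
        drug_cost_per_cycle=rng.uniform(0, 5000),
        admin_cost_per_cycle=rng.uniform(0, 500),
        scan_cost_per_event=rng.uniform(0, 300),
        ned_cost_per_year=rng.uniform(0, 3000),
        rpd_cost_per_year=rng.uniform(0, 8000),
        bsc_cost_per_patient_entering_rpd=rng.uniform(0, 3000),
        subsequent_treatments=[
            SubsequentTreatment("mix", rng.uniform(0, 1), rng.uniform(0, 50_000))
        ],
        societal=SocietalCosts(*rng.uniform(0, 1000, 4)),
        utilities=Utilities(u_ned=rng.uniform(0.3, 1.0), u_rpd=rng.uniform(0.0, 0.9)),
        discount=DiscountRates(cost_rate=0.04, effect_rate=0.015),
    )
    return spec, trace


@given(random_spec_and_trace())
def test_total_cost_equals_component_sum(spec_trace):
    spec, trace = spec_trace
    res = accumulate(trace, spec)
    assert res.total_cost == pytest.approx(sum(res.costs.values()), abs=1e-6)
    assert set(res.costs) == set(COST_COMPONENTS)


@given(random_spec_and_trace())
def test_discounted_never_exceeds_undiscounted(spec_trace):
    spec, trace = spec_trace
    res = accumulate(trace, spec)
    for k in COST_COMPONENTS:
        assert res.costs[k] <= res.costs_undiscounted[k] + 1e-9
    assert res.qalys.total <= res.qalys_undiscounted.total + 1e-12
    assert res.qalys.total <= res.lys.total + 1e-12  # utilities <= 1


@given(random_spec_and_trace(), st.floats(0.1, 2.0))
def test_cost_monotonicity_and_qaly_monotonicity(spec_trace, bump):
    spec, trace = spec_trace
    base = accumulate(trace, spec)
    more = copy.deepcopy(spec)
    more.drug_cost_per_cycle += bump * 1000
    assert accumulate(trace, more).total_cost >= base.total_cost
    better = copy.deepcopy(spec)
    better.utilities.u_ned = min(1.0, spec.utilities.u_ned + 0.05)
    assert accumulate(trace, better).qalys.total >= base.qalys.total


@given(random_spec_and_trace())
def test_zero_rates_reproduce_undiscounted_totals(spec_trace):
    spec, trace = spec_trace
    spec.discount = DiscountRates(cost_rate=0.0, effect_rate=0.0)
    res = accumulate(trace, spec)
    assert res.total_cost == pytest.approx(res.total_cost_undiscounted)
    assert res.qalys.total == pytest.approx(res.qalys_undiscounted.total)


@given(st.floats(1e-3, 1e3))
def test_icer_invariant_under_common_scaling(scale):
    a = CEAResult.from_components("a", {"health_state_ned": 1000.0 * scale},
                                  (1.0, 0.0), (0.5 * scale, 0.0))
    b = CEAResult.from_components("b", {"health_state_ned": 0.0}, (0.0, 0.0), (0.0, 0.0))
    icer = compare(a, b).icer_per_qaly
    assert icer == pytest.approx(1000.0 / 0.5, rel=1e-9)
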