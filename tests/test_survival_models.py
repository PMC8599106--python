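"""Curve reconstruction, interval-likelihood fitting, AIC selection, and
background-mortality blending."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from melcea.survival_models import (
    FAMILIES,
    DegenerateIntervalError,
    InsufficientEventsError,
    InvalidCurveError,
    KMCurve,
    LifeTable,
    ParametricFit,
    SurvivalCurveModel,
    blend_background_mortality,
    fit_all_families,
    fit_parametric,
    reconstruct_interval_data,
    select_best_fit,
)
from melcea.synthetic_data import SimulationConfig, make_life_table, simulate_trial_arm


def make_curve(times, survival, at_risk_times=None, at_risk_counts=None, **kw):
    return KMCurve(
        endpoint=kw.get("endpoint", "RFS"),
        arm_label=kw.get("arm_label", "test"),
        times=times,
        survival=survival,
        at_risk_times=times if at_risk_times is None else at_risk_times,
        at_risk_counts=at_risk_counts,
    )


class TestReconstruction:
    def test_flat_survival_means_pure_censoring(self):
        # No KM drop: the whole at-risk decrement is censoring.
        curve = make_curve([0.0, 6.0], [1.0, 1.0], at_risk_counts=[100.0, 90.0])
        data = reconstruct_interval_data(curve)
        assert data.events[0] == pytest.approx(0.0)
        assert data.censored[0] == pytest.approx(10.0)

    def test_km_identity_with_full_followup(self):
        # S 1.0 -> 0.8 with at-risk 100 -> 80: twenty events, nothing censored.
        curve = make_curve([0.0, 6.0], [1.0, 0.8], at_risk_counts=[100.0, 80.0])
        data = reconstruct_interval_data(curve)
        assert data.events[0] == pytest.approx(20.0)
        assert data.censored[0] == pytest.approx(0.0)

    def test_counts_match_simulation_truth(self):
        # Frozen-seed simulation oracle: exponential arm, exact KM, three
        # digitized intervals; reconstructed counts land on the true ones.
        cfg = SimulationConfig(
            family="exponential",
            params=(0.05,),
            n_patients=200,
            censoring_rate_per_month=0.01,
            grid=(10.0, 20.0, 30.0),
            seed=0,
        )
        curve, truth = simulate_trial_arm(cfg)
        data = reconstruct_interval_data(curve)
        assert np.all(np.abs(data.events - truth.true_events) <= 1.0)
        assert np.all(np.abs(data.censored - truth.true_censored) <= 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_close_to_truth_across_seeds(self, seed):
        cfg = SimulationConfig(
            family="exponential",
            params=(0.05,),
            n_patients=200,
            censoring_rate_per_month=0.01,
            grid=(10.0, 20.0, 30.0),
            seed=seed,
        )
        curve, truth = simulate_trial_arm(cfg)
        data = reconstruct_interval_data(curve)
        assert np.all(np.abs(data.events - truth.true_events) <= 2.0)

    def test_rising_survival_rejected(self):
        with pytest.raises((InvalidCurveError, ValueError)):
            make_curve([0.0, 6.0, 12.0], [1.0, 0.8, 0.9], at_risk_counts=[100, 80, 70])

    def test_zero_at_risk_with_drop_rejected(self):
        curve = make_curve([0.0, 6.0, 12.0], [1.0, 0.8, 0.4], at_risk_counts=[10, 0, 0])
        with pytest.raises(DegenerateIntervalError):
            reconstruct_interval_data(curve)


def _interval_data_from(family, params, n=4000, seed=5, grid_stop=120.0, step=1.0):
    """Interval data from an exactly digitized simulated arm (no censoring)."""
    cfg = SimulationConfig(
        family=family,
        params=params,
        n_patients=n,
        censoring_rate_per_month=0.0,
        grid=tuple(np.arange(step, grid_stop + step / 2, step)),
        seed=seed,
    )
    curve, _ = simulate_trial_arm(cfg)
    return reconstruct_interval_data(curve)


class TestFitting:
    def test_exponential_rate_recovered(self):
        # At n = 20 000 the sampling error of the rate is ~0.7%, so a 2% band
        # is comfortably analytically forced.
        data = _interval_data_from("exponential", (0.2,), n=20_000, grid_stop=40.0, step=0.5)
        fit = fit_parametric(data, "exponential")
        assert fit.params[0] == pytest.approx(0.2, rel=0.02)

    def test_weibull_recovers_exponential_special_case(self):
        data = _interval_data_from("exponential", (0.2,), n=20_000, grid_stop=40.0, step=0.5)
        fit = fit_parametric(data, "weibull")
        assert fit.params[0] == pytest.approx(1.0, rel=0.05)  # shape ~ 1

    def test_aic_identity_all_families(self):
        data = _interval_data_from("lognormal", (3.0, 1.0), n=500)
        for fit in fit_all_families(data):
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-9)

    def test_generating_family_attains_minimum_aic(self):
        data = _interval_data_from("lognormal", (1.5, 0.8), n=500, seed=2,
                                   grid_stop=36.0, step=0.5)
        best = select_best_fit(fit_all_families(data))
        assert best.family == "lognormal"

    @pytest.mark.parametrize(
        "family,params",
        [
            ("exponential", (0.05,)),
            ("weibull", (1.3, 20.0)),
            ("lognormal", (3.0, 1.0)),
            ("loglogistic", (1.8, 18.0)),
        ],
    )
    def test_parameter_recovery_each_family(self, family, params):
        # Simulate 1000 patients from the family, digitize, reconstruct, refit.
        cfg = SimulationConfig(
            family=family,
            params=params,
            n_patients=1000,
            censoring_rate_per_month=0.01,
            grid=tuple(np.arange(1.0, 121.0, 1.0)),
            seed=7,
        )
        curve, _ = simulate_trial_arm(cfg)
        fit = fit_parametric(reconstruct_interval_data(curve), family)
        for est, true in zip(fit.params, params):
            assert abs(est - true) / abs(true) < 0.10

    def test_roundtrip_survival_close_to_generating_curve(self):
        cfg = SimulationConfig(
            family="lognormal",
            params=(3.2, 1.1),
            n_patients=500,
            censoring_rate_per_month=0.01,
            grid=tuple(np.arange(2.0, 122.0, 2.0)),
            seed=11,
        )
        curve, _ = simulate_trial_arm(cfg)
        fit = fit_parametric(reconstruct_interval_data(curve), "lognormal")
        gen = ParametricFit.from_params("lognormal", (3.2, 1.1))
        for t in (12.0, 36.0, 60.0):
            assert abs(fit.survival([t])[0] - gen.survival([t])[0]) < 0.03

    def test_all_censored_rejected(self):
        curve = make_curve([0.0, 6.0, 12.0], [1.0, 1.0, 1.0], at_risk_counts=[50, 40, 30])
        data = reconstruct_interval_data(curve)
        with pytest.raises(InsufficientEventsError):
            fit_parametric(data, "exponential")


class TestSelection:
    def _fit(self, family, aic, n_params=2):
        loglik = (2 * n_params - aic) / 2.0
        return ParametricFit(
            family=family, params=(1.0,) * n_params, loglik=loglik,
            n_params=n_params, aic=aic,
        )

    def test_argmin_aic(self):
        fits = [
            self._fit("exponential", 520.1, 1),
            self._fit("weibull", 514.8),
            self._fit("lognormal", 519.9),
            self._fit("loglogistic", 515.0),
        ]
        assert select_best_fit(fits).aic == 514.8

    def test_tie_broken_by_fewer_parameters(self):
        fits = [self._fit("weibull", 500.0, 2), self._fit("exponential", 500.0, 1)]
        assert select_best_fit(fits).family == "exponential"

    def test_override_wins_with_warning(self, caplog):
        fits = [self._fit("weibull", 500.0), self._fit("lognormal", 510.0)]
        with caplog.at_level(logging.WARNING, logger="melcea.survival_models"):
            chosen = select_best_fit(fits, override="lognormal")
        assert chosen.family == "lognormal"
        assert any("override" in rec.message for rec in caplog.records)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best_fit([])


class TestBackgroundMortality:
    def test_zero_background_hazard_is_identity(self):
        lt = LifeTable(ages=np.arange(0, 101), qx=np.zeros(101))
        fit = ParametricFit.from_params("exponential", (0.02,))
        model = blend_background_mortality(fit, lt, start_age=50)
        t = np.arange(0.0, 300.0, 1.0)
        assert np.allclose(model(t), fit.survival(t), atol=1e-12)

    def test_constant_hazards_follow_max_rule(self):
        # Disease hazard 0.01/month vs background 0.03/month: the blended
        # curve is exp(-0.03 t) on the monthly grid.
        qx_year = 1.0 - math.exp(-0.03 * 12.0)
        lt = LifeTable(ages=np.arange(0, 111), qx=np.full(111, qx_year))
        fit = ParametricFit.from_params("exponential", (0.01,))
        model = blend_background_mortality(fit, lt, start_age=50)
        t = np.arange(0.0, 241.0, 1.0)
        assert np.max(np.abs(model(t) - np.exp(-0.03 * t))) < 1e-6

    def test_blended_curve_dominated_by_both_components(self, reference_fixture):
        lt = reference_fixture.life_table
        fit = ParametricFit.from_params("lognormal", (4.0, 1.0))
        model = blend_background_mortality(fit, lt, start_age=50)
        t = np.arange(0.0, 600.0, 1.0)
        bg_haz = np.cumsum(lt.annual_hazard(50 + t / 12.0) / 12.0)
        s_bg = np.concatenate([[1.0], np.exp(-bg_haz[:-1])])
        assert np.all(model(t) <= fit.survival(t) + 1e-12)
        assert np.all(model(t) <= s_bg + 1e-9)

    def test_start_age_outside_table_rejected(self):
        lt = LifeTable(ages=np.arange(0, 80), qx=np.full(80, 0.01))
        fit = ParametricFit.from_params("exponential", (0.01,))
        with pytest.raises(ValueError):
            blend_background_mortality(fit, lt, start_age=90)


@given(
    family=st.sampled_from(FAMILIES),
    p1=st.floats(0.02, 3.0),
    p2=st.floats(0.3, 40.0),
)
def test_survival_evaluators_are_proper(family, p1, p2):
    """S(0)=1, values in [0,1], non-increasing — for every family and
    randomized parameters."""
    params = (p1,) if family == "exponential" else (
        (math.log(p2), p1) if family == "lognormal" else (p1, p2)
    )
    fit = ParametricFit.from_params(family, params)
    t = np.linspace(0.0, 500.0, 400)
    s = fit.survival(t)
    assert s[0] == pytest.approx(1.0)
    assert np.all((s >= 0.0) & (s <= 1.0))
    assert np.all(np.diff(s) <= 1e-12)


def test_life_table_lookup_clamps_beyond_max_age():
    lt = make_life_table(max_age=100)
    assert lt.qx_at(150) == lt.qx[-1]
    assert lt.qx_at(-5) == lt.qx[0]
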