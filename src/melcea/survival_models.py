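"""Parametric survival modelling from digitized Kaplan-Meier curves.

Published trial survival is usually available only as a plotted KM curve with
a numbers-at-risk table. This module rebuilds interval-level event/censoring
counts from those digitized coordinates, maximizes the corresponding
interval-censored likelihood for four candidate event-time families
(exponential, Weibull, log-normal, log-logistic), selects among them by AIC,
and extrapolates the chosen curve to a lifetime horizon with an age-specific
background-mortality floor taken from a life table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "FAMILY_N_PARAMS",
    "KMCurve",
    "IntervalData",
    "ParametricFit",
    "LifeTable",
    "SurvivalCurveModel",
    "InvalidCurveError",
    "DegenerateIntervalError",
    "FitFailureError",
    "InsufficientEventsError",
    "reconstruct_interval_data",
    "fit_parametric",
    "fit_all_families",
    "select_best_fit",
    "blend_background_mortality",
]

logger = logging.getLogger(__name__)

#: Candidate event-time families, in canonical (tie-break) order.
FAMILIES: tuple[str, ...] = ("exponential", "weibull", "lognormal", "loglogistic")

FAMILY_N_PARAMS: dict[str, int] = {
    "exponential": 1,
    "weibull": 2,
    "lognormal": 2,
    "loglogistic": 2,
}

_TINY = 1e-300


class InvalidCurveError(ValueError):
    """Digitized survival increases over time (not a valid KM curve)."""


class DegenerateIntervalError(ValueError):
    """A survival drop occurs on an interval with no patients at risk."""


class FitFailureError(RuntimeError):
    """The optimizer failed to converge for a family."""


class InsufficientEventsError(ValueError):
    """Interval data carry too few events to identify a survival model."""


# ---------------------------------------------------------------------------
# Survival functions per family (parameters are plain positive reals except
# the log-normal location mu, which is unconstrained).
# ---------------------------------------------------------------------------


def _sf_exponential(t: np.ndarray, params: Sequence[float]) -> np.ndarray:
    (rate,) = params
    return np.exp(-rate * np.asarray(t, dtype=float))


def _sf_weibull(t: np.ndarray, params: Sequence[float]) -> np.ndarray:
    shape, scale = params
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        return np.exp(-np.power(np.maximum(t, 0.0) / scale, shape))


def _sf_lognormal(t: np.ndarray, params: Sequence[float]) -> np.ndarray:
    mu, sigma = params
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    out[pos] = stats.norm.sf((np.log(t[pos]) - mu) / sigma)
    return out


def _sf_loglogistic(t: np.ndarray, params: Sequence[float]) -> np.ndarray:
    shape, scale = params
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + np.power(np.maximum(t, 0.0) / scale, shape))


_SF: dict[str, Callable[[np.ndarray, Sequence[float]], np.ndarray]] = {
    "exponential": _sf_exponential,
    "weibull": _sf_weibull,
    "lognormal": _sf_lognormal,
    "loglogistic": _sf_loglogistic,
}


def _pdf(family: str, t: np.ndarray, params: Sequence[float]) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (rate,) = params
        return rate * np.exp(-rate * t)
    if family == "weibull":
        shape, scale = params
        return stats.weibull_min.pdf(t, shape, scale=scale)
    if family == "lognormal":
        mu, sigma = params
        return stats.lognorm.pdf(t, sigma, scale=math.exp(mu))
    if family == "loglogistic":
        shape, scale = params
        return stats.fisk.pdf(t, shape, scale=scale)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMCurve:
    """Digitized Kaplan-Meier step points with an at-risk table for one arm.

    Times are months from randomization; the first point must be (0, 1).
    """

    endpoint: str
    arm_label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk_times: np.ndarray
    at_risk_counts: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "survival", "at_risk_times", "at_risk_counts"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.endpoint not in ("RFS", "OS"):
            raise ValueError(f"endpoint must be 'RFS' or 'OS', got {self.endpoint!r}")
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least two digitized points")
        if self.times.size != self.survival.size:
            raise ValueError("times and survival must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if self.times[0] != 0 or not math.isclose(self.survival[0], 1.0):
            raise ValueError("curve must start at (0, 1)")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise InvalidCurveError("survival increases between digitized points")
        if np.any(np.diff(self.at_risk_times) <= 0):
            raise ValueError("at-risk times must be strictly increasing")
        if np.any(np.diff(self.at_risk_counts) > 1e-9):
            raise ValueError("at-risk counts must be non-increasing in time")
        if np.any(self.at_risk_counts < 0):
            raise ValueError("at-risk counts must be non-negative")

    @classmethod
    def from_csv(
        cls, survival_csv, at_risk_csv, endpoint: str, arm_label: str
    ) -> "KMCurve":
        """Read a file pair: (time_months, survival) and (time_months, n_at_risk)."""
        surv = pd.read_csv(survival_csv)
        risk = pd.read_csv(at_risk_csv)
        return cls(
            endpoint=endpoint,
            arm_label=arm_label,
            times=surv["time_months"].to_numpy(),
            survival=surv["survival"].to_numpy(),
            at_risk_times=risk["time_months"].to_numpy(),
            at_risk_counts=risk["n_at_risk"].to_numpy(),
        )


@dataclass(frozen=True)
class IntervalData:
    """Reconstructed per-interval event bookkeeping.

    ``events`` and ``censored`` are real-valued estimates; ``n_remaining``
    patients are administratively censored at ``t_max`` (end of follow-up).
    """

    t_start: np.ndarray
    t_end: np.ndarray
    n_start: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    n_remaining: float
    t_max: float

    def __post_init__(self) -> None:
        for name in ("t_start", "t_end", "n_start", "events", "censored"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.allclose(self.t_start[1:], self.t_end[:-1]):
            raise ValueError("intervals must be contiguous and non-overlapping")
        if np.any(self.events + self.censored > self.n_start + 1e-9):
            raise ValueError("events + censored exceed patients at risk")
        if np.any(self.events < -1e-12) or np.any(self.censored < -1e-12):
            raise ValueError("events and censorings must be non-negative")

    @property
    def total_events(self) -> float:
        return float(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_start": self.t_start,
                "t_end": self.t_end,
                "n_at_risk_start": self.n_start,
                "events": self.events,
                "censored": self.censored,
            }
        )


@dataclass(frozen=True)
class ParametricFit:
    """A fitted event-time distribution with survival/hazard evaluators.

    The AIC identity ``aic = 2 * n_params - 2 * loglik`` is enforced whenever
    the log-likelihood is finite (externally calibrated curves may carry NaN).
    """

    family: str
    params: tuple[float, ...]
    loglik: float
    n_params: int
    aic: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if math.isfinite(self.loglik):
            expect = 2 * self.n_params - 2 * self.loglik
            if not math.isclose(self.aic, expect, rel_tol=1e-12, abs_tol=1e-9):
                raise ValueError("aic must equal 2*n_params - 2*loglik")

    @classmethod
    def from_params(cls, family: str, params: Sequence[float]) -> "ParametricFit":
        """Build an evaluator-only fit (no likelihood attached)."""
        return cls(
            family=family,
            params=tuple(params),
            loglik=float("nan"),
            n_params=FAMILY_N_PARAMS[family],
            aic=float("nan"),
        )

    def survival(self, t) -> np.ndarray:
        """S(t) for t in months."""
        return np.clip(_SF[self.family](np.asarray(t, dtype=float), self.params), 0.0, 1.0)

    def hazard(self, t) -> np.ndarray:
        """Instantaneous hazard f(t)/S(t) per month."""
        t = np.asarray(t, dtype=float)
        sf = np.maximum(self.survival(t), _TINY)
        return _pdf(self.family, t, self.params) / sf

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": list(self.params),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
        }


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(x) by integer age.

    Lookups beyond the last tabulated age return the last q(x).
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=int))
        object.__setattr__(self, "qx", np.asarray(self.qx, dtype=float))
        if self.ages.size != self.qx.size or self.ages.size == 0:
            raise ValueError("ages and qx must be non-empty and of equal length")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be contiguous integers")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("qx must lie in [0, 1]")

    def qx_at(self, age) -> np.ndarray:
        """q(x) for (possibly fractional) ages, clamped to the table range."""
        idx = np.clip(
            np.floor(np.asarray(age, dtype=float)).astype(int) - self.ages[0],
            0,
            self.ages.size - 1,
        )
        return self.qx[idx]

    def annual_hazard(self, age) -> np.ndarray:
        """Background hazard per year, -ln(1 - qx)."""
        return -np.log1p(-np.minimum(self.qx_at(age), 1 - 1e-12))

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)


class SurvivalCurveModel:
    """A lifetime survival evaluator S(t months), optionally mortality-adjusted.

    When a life table is attached, the per-step death hazard on a monthly grid
    is the maximum of the disease-model hazard and the age-specific background
    hazard, so modelled patients never outlive the general population.
    """

    def __init__(
        self,
        evaluate: Callable[[np.ndarray], np.ndarray],
        start_age: float = 50.0,
        base_fit: ParametricFit | None = None,
        life_table: LifeTable | None = None,
    ):
        self._evaluate = evaluate
        self.start_age = float(start_age)
        self.base_fit = base_fit
        self.life_table = life_table

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        return np.clip(self._evaluate(t), 0.0, 1.0)

    @classmethod
    def from_fit(cls, fit: ParametricFit, start_age: float = 50.0) -> "SurvivalCurveModel":
        return cls(fit.survival, start_age=start_age, base_fit=fit)

    @classmethod
    def from_function(
        cls, fn: Callable[[np.ndarray], np.ndarray], start_age: float = 50.0
    ) -> "SurvivalCurveModel":
        return cls(fn, start_age=start_age)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def reconstruct_interval_data(curve: KMCurve) -> IntervalData:
    """Estimate per-interval events and censorings from a digitized KM curve.

    On each digitized interval the KM identity
    ``S(t_end) = S(t_start) * (1 - d / n_eff)`` is solved jointly with the
    at-risk bookkeeping ``n_end = n_start - d - c``, taking censoring as
    uniform within the interval (effective denominator ``n_start - c/2``).
    At-risk counts at interval boundaries are interpolated linearly in time
    from the published at-risk table.
    """
    t = curve.times
    S = curve.survival
    n = np.interp(t, curve.at_risk_times, curve.at_risk_counts)

    events = np.zeros(t.size - 1)
    censored = np.zeros(t.size - 1)
    for i in range(t.size - 1):
        s0, s1 = S[i], S[i + 1]
        n0, n1 = n[i], n[i + 1]
        if s1 > s0 + 1e-12:
            raise InvalidCurveError(
                f"survival increases on [{t[i]:g}, {t[i + 1]:g}] months"
            )
        if s0 <= 0:
            # Curve already exhausted: nobody left to fail.
            events[i] = 0.0
            censored[i] = max(n0 - n1, 0.0)
            continue
        r = s1 / s0
        if n0 <= 0:
            if s1 < s0 - 1e-12:
                raise DegenerateIntervalError(
                    f"survival drops on [{t[i]:g}, {t[i + 1]:g}] months with "
                    "zero patients at risk"
                )
            continue
        c = max(2.0 * (r * n0 - n1) / (1.0 + r), 0.0)
        d = max((1.0 - r) * (n0 - c / 2.0), 0.0)
        if d + c > n0:
            c = max(n0 - d, 0.0)
        events[i] = d
        censored[i] = c

    n_remaining = max(float(n[-1]), 0.0)
    return IntervalData(
        t_start=t[:-1],
        t_end=t[1:],
        n_start=n[:-1],
        events=events,
        censored=censored,
        n_remaining=n_remaining,
        t_max=float(t[-1]),
    )


def _initial_theta(data: IntervalData, family: str) -> np.ndarray:
    mids = 0.5 * (data.t_start + data.t_end)
    d = data.events
    d_tot = d.sum()
    mean_t = float((d * mids).sum() / d_tot) if d_tot > 0 else float(data.t_max) / 2
    exposure = float((d * mids).sum() + (data.censored * mids).sum()) + (
        data.n_remaining * data.t_max
    )
    rate0 = max(d_tot / max(exposure, 1e-9), 1e-6)
    if family == "exponential":
        return np.array([math.log(rate0)])
    if family == "weibull":
        return np.array([0.0, math.log(1.0 / rate0)])
    if family == "lognormal":
        logs = np.log(np.maximum(mids, 1e-6))
        if d_tot > 0:
            mu0 = float((d * logs).sum() / d_tot)
            var0 = float((d * (logs - mu0) ** 2).sum() / d_tot)
            sigma0 = max(math.sqrt(var0), 0.3)
        else:  # pragma: no cover - guarded by caller
            mu0, sigma0 = math.log(mean_t), 1.0
        return np.array([mu0, math.log(sigma0)])
    if family == "loglogistic":
        return np.array([math.log(1.5), math.log(max(mean_t, 1e-3))])
    raise ValueError(f"unknown family {family!r}")


def _theta_to_params(theta: np.ndarray, family: str) -> tuple[float, ...]:
    if family == "lognormal":
        return (float(theta[0]), float(math.exp(theta[1])))
    return tuple(float(math.exp(v)) for v in theta)


def fit_parametric(data: IntervalData, family: str) -> ParametricFit:
    """Maximize the interval-censored likelihood for one family.

    Each reconstructed event contributes the probability mass of its interval,
    each censoring the survival at the interval midpoint, and patients still
    at risk at the end of follow-up the survival at that time.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if data.t_start.size < 2:
        raise InsufficientEventsError("need at least two intervals")
    if data.total_events <= 0:
        raise InsufficientEventsError("all observations censored; no events to fit")

    mids = 0.5 * (data.t_start + data.t_end)
    sf = _SF[family]

    def nll(theta: np.ndarray) -> float:
        params = _theta_to_params(theta, family)
        s_start = sf(data.t_start, params)
        s_end = sf(data.t_end, params)
        mass = np.maximum(s_start - s_end, _TINY)
        s_mid = np.maximum(sf(mids, params), _TINY)
        s_last = max(float(sf(np.array([data.t_max]), params)[0]), _TINY)
        ll = (
            float((data.events * np.log(mass)).sum())
            + float((data.censored * np.log(s_mid)).sum())
            + data.n_remaining * math.log(s_last)
        )
        return -ll if math.isfinite(ll) else 1e12

    theta0 = _initial_theta(data, family)
    res = optimize.minimize(
        nll,
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000, "maxfev": 4000},
    )
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Powell")
        if res2.fun <= res.fun:
            res = res2
    if not math.isfinite(res.fun) or res.fun >= 1e12:
        raise FitFailureError(f"{family} fit failed to converge")

    params = _theta_to_params(res.x, family)
    loglik = -float(res.fun)
    k = FAMILY_N_PARAMS[family]
    return ParametricFit(
        family=family, params=params, loglik=loglik, n_params=k, aic=2 * k - 2 * loglik
    )


def fit_all_families(
    data: IntervalData, families: Iterable[str] = FAMILIES
) -> list[ParametricFit]:
    """Fit every candidate family, skipping (and logging) failures."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_parametric(data, fam))
        except FitFailureError as exc:  # pragma: no cover - rare
            logger.warning("fit failure: %s", exc)
    if not fits:
        raise FitFailureError("no family converged")
    return fits


def select_best_fit(
    fits: Sequence[ParametricFit], override: str | None = None
) -> ParametricFit:
    """Pick the minimum-AIC fit; ties go to fewer parameters, then family order.

    ``override`` forces a family (mirroring selection informed by visual
    assessment); a warning is logged if that family is not AIC-best.
    """
    if not fits:
        raise ValueError("empty fit list")
    best = min(
        fits,
        key=lambda f: (f.aic, f.n_params, FAMILIES.index(f.family)),
    )
    if override is not None:
        chosen = next((f for f in fits if f.family == override), None)
        if chosen is None:
            raise ValueError(f"override family {override!r} not among fits")
        if chosen.family != best.family:
            logger.warning(
                "override %s selected although %s has lower AIC (%.2f vs %.2f)",
                override,
                best.family,
                best.aic,
                chosen.aic,
            )
        return chosen
    return best


def blend_background_mortality(
    fit: ParametricFit,
    life_table: LifeTable,
    start_age: float = 50.0,
    max_age: float = 100.0,
    grid_step_months: float = 1.0,
) -> SurvivalCurveModel:
    """Floor modelled mortality at general-population mortality.

    On a monthly grid the applied per-step hazard is
    ``max(disease hazard, background hazard)``; annual q(x) is converted to a
    per-step probability under a constant hazard within the year. The adjusted
    curve is the cumulative product of per-step survival, interpolated
    log-linearly between grid points.
    """
    if not (life_table.ages[0] <= start_age <= life_table.ages[-1]):
        raise ValueError(
            f"start_age {start_age} outside life-table range "
            f"[{life_table.ages[0]}, {life_table.ages[-1]}]"
        )
    horizon = max((max_age - start_age) * 12.0, grid_step_months)
    n_steps = int(math.ceil(horizon / grid_step_months))
    grid = np.arange(n_steps + 1) * grid_step_months

    s_dis = np.maximum(fit.survival(grid), _TINY)
    h_dis = np.log(s_dis[:-1]) - np.log(s_dis[1:])  # per-step cumulative hazard
    ages = start_age + grid[:-1] / 12.0
    h_bg = life_table.annual_hazard(ages) * (grid_step_months / 12.0)
    h = np.maximum(h_dis, h_bg)
    log_s = np.concatenate([[0.0], -np.cumsum(h)])

    def evaluate(t: np.ndarray) -> np.ndarray:
        return np.exp(np.interp(t, grid, log_s))

    return SurvivalCurveModel(
        evaluate, start_age=start_age, base_fit=fit, life_table=life_table
    )
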