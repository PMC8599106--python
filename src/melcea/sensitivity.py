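"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-runs the full comparison with each parameter at
its low/high bound; probabilistic analysis draws all parameters jointly
(gamma for costs, beta for utilities) over 1000 Monte-Carlo iterations and
summarizes the draws as cost-effectiveness acceptability curves (CEACs).

Parameters are addressed by a dotted path into a :class:`StrategySpec`
(``"utilities.u_ned"``, ``"subsequent_treatments.0.acquisition_cost"``) with a
scope saying whether the draw applies to the strategy arm, the comparator
arm, or — for unit costs taken from one national price list — to both arms at
once as a shared multiplier.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .economics import CEAResult, Comparison, StrategySpec, accumulate, compare
from .markov_engine import CohortTrace, derive_occupancy
from .survival_models import SurvivalCurveModel

__all__ = [
    "ModelBundle",
    "ParameterDistribution",
    "TornadoEntry",
    "PSAResult",
    "CEACCurve",
    "ParameterPathError",
    "parameterize_distribution",
    "run_dsa",
    "run_psa",
    "compute_ceac",
    "default_wtp_grid",
]

logger = logging.getLogger(__name__)


class ParameterPathError(KeyError):
    """A distribution's target path does not resolve inside the spec."""


def _resolve(obj, parts: Sequence[str], path: str):
    """Return (parent, final accessor) for a dotted path with list indices."""
    for i, part in enumerate(parts):
        last = i == len(parts) - 1
        if part.isdigit():
            idx = int(part)
            try:
                nxt = obj[idx]
            except (TypeError, IndexError) as exc:
                raise ParameterPathError(f"cannot index {path!r}") from exc
            if last:
                return obj, idx
            obj = nxt
        else:
            if not hasattr(obj, part):
                raise ParameterPathError(f"no field {part!r} along {path!r}")
            if last:
                return obj, part
            obj = getattr(obj, part)
    raise ParameterPathError(path)  # pragma: no cover


def get_path(spec: StrategySpec, path: str) -> float:
    parent, key = _resolve(spec, path.split("."), path)
    return parent[key] if isinstance(key, int) else getattr(parent, key)


def set_path(spec: StrategySpec, path: str, value: float) -> None:
    parent, key = _resolve(spec, path.split("."), path)
    if isinstance(key, int):
        parent[key] = value
    else:
        setattr(parent, key, value)


@dataclass(frozen=True)
class ParameterDistribution:
    """Uncertainty specification for one model input.

    ``kind`` is ``gamma`` (non-negative costs), ``beta`` (utilities in [0,1])
    or ``fixed_range`` (DSA-only bounds, degenerate in PSA). ``mean`` is the
    base-case value (1.0 for relative/multiplier parameters), ``low``/``high``
    the one-way bounds, ``sd`` the PSA standard deviation.
    """

    name: str
    target: str
    scope: str  # "strategy" | "comparator" | "both"
    kind: str  # "gamma" | "beta" | "fixed_range"
    mean: float
    low: float
    high: float
    sd: float
    relative: bool = False

    def __post_init__(self) -> None:
        if self.scope not in ("strategy", "comparator", "both"):
            raise ValueError(f"bad scope {self.scope!r}")
        if self.kind not in ("gamma", "beta", "fixed_range"):
            raise ValueError(f"bad kind {self.kind!r}")
        if not self.low <= self.mean <= self.high:
            raise ValueError(f"{self.name}: need low <= mean <= high")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0 or self.kind == "fixed_range":
            return self.mean
        if self.kind == "gamma":
            shape = (self.mean / self.sd) ** 2
            scale = self.sd**2 / self.mean
            return float(rng.gamma(shape, scale))
        # beta, moment-matched
        m, v = self.mean, self.sd**2
        nu = m * (1 - m) / v - 1.0
        return float(rng.beta(m * nu, (1 - m) * nu))


def parameterize_distribution(
    name: str,
    target: str,
    kind: str,
    mean: float,
    *,
    scope: str = "strategy",
    fraction: float | None = None,
    ci: tuple[float, float] | None = None,
    sd: float | None = None,
    relative: bool = False,
) -> ParameterDistribution:
    """Method-of-moments distribution from a +/-fraction or a 95% CI.

    For costs the default spread is a fraction of the mean, mapped to the PSA
    standard deviation as ``sd = fraction * mean / 1.96`` so that the central
    95% interval of the gamma approximately matches the stated range. Betas
    take ``sd = (hi - lo) / (2 * 1.96)`` from the CI.
    """
    if sum(x is not None for x in (fraction, ci, sd)) != 1:
        raise ValueError("give exactly one of fraction, ci, sd")
    if fraction is not None:
        if fraction < 0:
            raise ValueError("fraction must be >= 0")
        low, high = mean * (1 - fraction), mean * (1 + fraction)
        sd_val = fraction * abs(mean) / 1.96
    elif ci is not None:
        low, high = ci
        if not low <= mean <= high:
            raise ValueError(f"{name}: mean {mean:g} outside CI {ci}")
        sd_val = (high - low) / (2 * 1.96)
    else:
        sd_val = float(sd)
        low = mean - 1.96 * sd_val
        high = mean + 1.96 * sd_val
    if kind == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"{name}: beta mean must lie strictly in (0, 1)")
        if sd_val > 0 and sd_val**2 >= mean * (1 - mean):
            raise ValueError(
                f"{name}: beta variance {sd_val ** 2:g} infeasible; must be "
                f"< mean*(1-mean) = {mean * (1 - mean):g}"
            )
        low, high = max(low, 0.0), min(high, 1.0)
    if kind == "gamma" and mean < 0:
        raise ValueError(f"{name}: gamma mean must be non-negative")
    return ParameterDistribution(
        name=name,
        target=target,
        scope=scope,
        kind=kind,
        mean=mean,
        low=low,
        high=high,
        sd=sd_val,
        relative=relative,
    )


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]

    @property
    def width(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return float("nan")
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PSAResult:
    """Joint Monte-Carlo draws of (delta_cost, delta_qaly) for one comparison."""

    strategy: str
    comparator: str
    n_draws: int
    seed: int
    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    n_resampled: int = 0

    def __post_init__(self) -> None:
        if self.delta_costs.size != self.n_draws or self.delta_qalys.size != self.n_draws:
            raise ValueError("draw arrays must have length n_draws")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "strategy": self.strategy,
                "delta_cost": self.delta_costs,
                "delta_qaly": self.delta_qalys,
            }
        )


@dataclass(frozen=True)
class CEACCurve:
    strategy: str
    wtp_grid: np.ndarray
    probability_cost_effective: np.ndarray

    def __post_init__(self) -> None:
        if self.wtp_grid.size == 0:
            raise ValueError("empty WTP grid")
        if np.any(np.diff(self.wtp_grid) <= 0):
            raise ValueError("WTP grid must be strictly increasing")
        p = self.probability_cost_effective
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        return float(self.probability_cost_effective[idx])


def default_wtp_grid() -> np.ndarray:
    """EUR 0 to 100 000 per QALY in 2 500 steps (covers the 50k threshold)."""
    return np.arange(0.0, 100_000.0 + 1, 2_500.0)


class ModelBundle:
    """A strategy/comparator pair bound to its survival curves and horizon.

    Caches cohort traces, which depend only on the curves, schedules and
    horizon — re-evaluations with perturbed economic parameters reuse them.
    """

    def __init__(
        self,
        strategy_spec: StrategySpec,
        comparator_spec: StrategySpec,
        strategy_curves: tuple[SurvivalCurveModel, SurvivalCurveModel],
        comparator_curves: tuple[SurvivalCurveModel, SurvivalCurveModel],
        horizon_months: float | None = None,
        wtp: float = 50_000.0,
    ):
        self.strategy_spec = strategy_spec
        self.comparator_spec = comparator_spec
        self.strategy_curves = strategy_curves
        self.comparator_curves = comparator_curves
        self.horizon_months = horizon_months
        self.wtp = wtp
        self._trace_cache: dict = {}

    def _trace(self, which: str, horizon: float | None) -> CohortTrace:
        spec = self.strategy_spec if which == "strategy" else self.comparator_spec
        curves = self.strategy_curves if which == "strategy" else self.comparator_curves
        key = (which, spec.schedule, horizon)
        if key not in self._trace_cache:
            self._trace_cache[key] = derive_occupancy(
                curves[0], curves[1], spec.schedule, horizon_months=horizon
            )
        return self._trace_cache[key]

    def evaluate(
        self,
        strategy_spec: StrategySpec | None = None,
        comparator_spec: StrategySpec | None = None,
        horizon_months: float | None = None,
    ) -> Comparison:
        horizon = self.horizon_months if horizon_months is None else horizon_months
        s_spec = strategy_spec or self.strategy_spec
        c_spec = comparator_spec or self.comparator_spec
        s_res = accumulate(self._trace("strategy", horizon), s_spec)
        c_res = accumulate(self._trace("comparator", horizon), c_spec)
        return compare(s_res, c_res, wtp=self.wtp)

    def modified_specs(
        self, settings: Sequence[tuple[ParameterDistribution, float]]
    ) -> tuple[StrategySpec, StrategySpec]:
        """Copies of both specs with each distribution's target set to a value.

        Relative parameters multiply the arm's own baseline, so a shared draw
        moves both arms coherently; absolute parameters overwrite the field.
        """
        s = copy.deepcopy(self.strategy_spec)
        c = copy.deepcopy(self.comparator_spec)
        for dist, value in settings:
            targets = []
            if dist.scope in ("strategy", "both"):
                targets.append((s, self.strategy_spec))
            if dist.scope in ("comparator", "both"):
                targets.append((c, self.comparator_spec))
            for spec, base in targets:
                if dist.relative:
                    base_val = get_path(base, dist.target)
                    set_path(spec, dist.target, base_val * value)
                else:
                    set_path(spec, dist.target, value)
        return s, c


def run_dsa(
    bundle: ModelBundle,
    distributions: Sequence[ParameterDistribution],
    horizon_alternative_years: float = 15.0,
) -> list[TornadoEntry]:
    """One-way sensitivity of the ICER per QALY, ranked for a tornado diagram.

    Each parameter is set to its low and high bound with everything else at
    base case; a time-horizon entry (lifetime vs ``horizon_alternative_years``)
    is appended. Entries come back sorted by descending ICER range, with the
    parameter name breaking ties so the ordering is independent of input order.
    """
    bundle.evaluate()  # fail fast if the base case is broken
    entries: list[TornadoEntry] = []
    for dist in distributions:
        icers = []
        for bound in (dist.low, dist.high):
            s, c = bundle.modified_specs([(dist, bound)])
            icers.append(bundle.evaluate(strategy_spec=s, comparator_spec=c).icer_per_qaly)
        entries.append(TornadoEntry(dist.name, icers[0], icers[1]))
    short = bundle.evaluate(horizon_months=horizon_alternative_years * 12.0)
    life = bundle.evaluate()
    entries.append(
        TornadoEntry("time_horizon", short.icer_per_qaly, life.icer_per_qaly)
    )
    return sorted(
        entries,
        key=lambda e: (-(e.width if math.isfinite(e.width) else -math.inf), e.parameter),
    )


def run_psa(
    bundle: ModelBundle,
    distributions: Sequence[ParameterDistribution],
    n_draws: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Joint Monte-Carlo resampling of all parameters, deterministic per seed.

    Parameters are sampled independently in registry order from one seeded
    generator. Draws producing an invalid spec are resampled (counted; a >1%
    resample rate logs a warning).
    """
    rng = np.random.default_rng(seed)
    dc = np.empty(n_draws)
    dq = np.empty(n_draws)
    n_resampled = 0
    for i in range(n_draws):
        for _attempt in range(100):
            settings = [(d, d.sample(rng)) for d in distributions]
            s, c = bundle.modified_specs(settings)
            if not s.validation_errors() and not c.validation_errors():
                break
            n_resampled += 1
        else:  # pragma: no cover - distributions would have to be degenerate
            raise RuntimeError("PSA draw kept producing invalid specs")
        comp = bundle.evaluate(strategy_spec=s, comparator_spec=c)
        dc[i] = comp.delta_cost
        dq[i] = comp.delta_qaly
    if n_resampled > 0.01 * n_draws:
        logger.warning("PSA resampled %d draws (>1%% of %d)", n_resampled, n_draws)
    return PSAResult(
        strategy=bundle.strategy_spec.name,
        comparator=bundle.comparator_spec.name,
        n_draws=n_draws,
        seed=seed,
        delta_costs=dc,
        delta_qalys=dq,
        n_resampled=n_resampled,
    )


def compute_ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """Probability of positive net monetary benefit at each willingness to pay."""
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    nmb = grid[:, None] * psa.delta_qalys[None, :] - psa.delta_costs[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(strategy=psa.strategy, wtp_grid=grid, probability_cost_effective=prob)
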