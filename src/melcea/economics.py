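"""Discounted cost, life-year and QALY accounting, and ICER comparisons.

A :class:`StrategySpec` carries the full economic parameterization of one
strategy from a societal perspective: adjuvant drug acquisition and
administration per cycle, surveillance scans, annual health-state costs,
subsequent-treatment and best-supportive-care costs charged at recurrence,
societal costs (informal care, productivity loss, travel), state utilities,
and the differential discount rates (4.0%/year for costs, 1.5%/year for
health effects, per Dutch guidance). :func:`accumulate` folds a cohort trace
through the parameterization; :func:`compare` forms incremental ratios and
net monetary benefit against a comparator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markov_engine import CohortTrace, CycleSchedule

__all__ = [
    "SubsequentTreatment",
    "WeightBasedDrug",
    "SocietalCosts",
    "Utilities",
    "DiscountRates",
    "StrategySpec",
    "EffectTotals",
    "CEAResult",
    "Comparison",
    "SpecValidationError",
    "COST_COMPONENTS",
    "discount_factor",
    "accumulate",
    "compare",
]

#: Cost breakdown keys, in reporting order.
COST_COMPONENTS: tuple[str, ...] = (
    "adjuvant_acquisition",
    "adjuvant_admin",
    "subsequent_acquisition",
    "subsequent_admin",
    "health_state_ned",
    "health_state_rpd",
    "bsc",
    "informal_care",
    "productivity",
    "travel",
)


class SpecValidationError(ValueError):
    """A strategy parameterization violates its schema; lists every violation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class SubsequentTreatment:
    """One option in the post-recurrence treatment mix, costed per patient."""

    label: str
    probability: float
    acquisition_cost: float
    admin_cost: float = 0.0


@dataclass
class WeightBasedDrug:
    """A weight-based post-recurrence drug (e.g. ipilimumab at 3 mg/kg).

    Costed as ``cost_per_mg * dose_mg_per_kg * median_weight_kg * n_doses``
    per treated patient, at the cohort's median weight.
    """

    label: str
    probability: float
    cost_per_mg: float
    dose_mg_per_kg: float
    n_doses: int = 4
    admin_cost_per_dose: float = 0.0
    median_weight_kg: float = 78.4

    @property
    def acquisition_cost(self) -> float:
        return self.cost_per_mg * self.dose_mg_per_kg * self.median_weight_kg * self.n_doses

    @property
    def admin_cost(self) -> float:
        return self.admin_cost_per_dose * self.n_doses


@dataclass
class SocietalCosts:
    informal_care_per_rpd_year: float = 0.0
    productivity_per_ned_year: float = 0.0
    productivity_per_rpd_year: float = 0.0
    travel_cost_per_visit: float = 0.0


@dataclass
class Utilities:
    u_ned: float = 1.0
    u_rpd: float = 1.0


@dataclass
class DiscountRates:
    cost_rate: float = 0.04
    effect_rate: float = 0.015


@dataclass
class StrategySpec:
    """Economic parameterization of one strategy (all monetary values in EUR)."""

    name: str
    schedule: CycleSchedule
    drug_cost_per_cycle: float = 0.0
    admin_cost_per_cycle: float = 0.0
    scan_cost_per_event: float = 0.0
    ned_cost_per_year: float = 0.0
    rpd_cost_per_year: float = 0.0
    bsc_cost_per_patient_entering_rpd: float = 0.0
    subsequent_treatments: list[SubsequentTreatment] = field(default_factory=list)
    rpd_weight_based: Optional[WeightBasedDrug] = None
    societal: SocietalCosts = field(default_factory=SocietalCosts)
    utilities: Utilities = field(default_factory=Utilities)
    discount: DiscountRates = field(default_factory=DiscountRates)

    def validation_errors(self) -> list[str]:
        errors: list[str] = []
        for fname in (
            "drug_cost_per_cycle",
            "admin_cost_per_cycle",
            "scan_cost_per_event",
            "ned_cost_per_year",
            "rpd_cost_per_year",
            "bsc_cost_per_patient_entering_rpd",
        ):
            if getattr(self, fname) < 0:
                errors.append(f"{self.name}.{fname} must be >= 0")
        for fname in (
            "informal_care_per_rpd_year",
            "productivity_per_ned_year",
            "productivity_per_rpd_year",
            "travel_cost_per_visit",
        ):
            if getattr(self.societal, fname) < 0:
                errors.append(f"{self.name}.societal.{fname} must be >= 0")
        for fname in ("u_ned", "u_rpd"):
            u = getattr(self.utilities, fname)
            if not 0.0 <= u <= 1.0:
                errors.append(f"{self.name}.utilities.{fname}={u:g} outside [0, 1]")
        for fname in ("cost_rate", "effect_rate"):
            if getattr(self.discount, fname) < 0:
                errors.append(f"{self.name}.discount.{fname} must be >= 0")
        p_total = sum(s.probability for s in self.subsequent_treatments)
        if self.rpd_weight_based is not None:
            p_total += self.rpd_weight_based.probability
        for s in self.subsequent_treatments:
            if not 0.0 <= s.probability <= 1.0:
                errors.append(
                    f"{self.name}.subsequent_treatments[{s.label}].probability "
                    "outside [0, 1]"
                )
        if p_total > 1.0 + 1e-9:
            errors.append(
                f"{self.name}: subsequent-treatment probabilities sum to "
                f"{p_total:g} > 1"
            )
        return errors

    def validate(self) -> None:
        errors = self.validation_errors()
        if errors:
            raise SpecValidationError(errors)

    def expected_subsequent_costs(self) -> tuple[float, float]:
        """Expected (acquisition, administration) cost per recurring patient."""
        acq = sum(s.probability * s.acquisition_cost for s in self.subsequent_treatments)
        adm = sum(s.probability * s.admin_cost for s in self.subsequent_treatments)
        if self.rpd_weight_based is not None:
            w = self.rpd_weight_based
            acq += w.probability * w.acquisition_cost
            adm += w.probability * w.admin_cost
        return acq, adm

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class EffectTotals:
    ned: float
    rpd: float

    @property
    def total(self) -> float:
        return self.ned + self.rpd


@dataclass(frozen=True)
class CEAResult:
    """Cost breakdown, LYs and QALYs for one strategy.

    ``costs``/``lys``/``qalys`` are discounted; ``*_undiscounted`` twins keep
    the raw accruals. The total always equals the component sum.
    """

    strategy: str
    costs: dict[str, float]
    costs_undiscounted: dict[str, float]
    lys: EffectTotals
    lys_undiscounted: EffectTotals
    qalys: EffectTotals
    qalys_undiscounted: EffectTotals

    def __post_init__(self) -> None:
        missing = set(COST_COMPONENTS) - set(self.costs)
        if missing:
            raise ValueError(f"missing cost components: {sorted(missing)}")

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))

    @property
    def total_cost_undiscounted(self) -> float:
        return float(sum(self.costs_undiscounted.values()))

    @classmethod
    def from_components(
        cls,
        strategy: str,
        costs: dict[str, float],
        lys: tuple[float, float],
        qalys: tuple[float, float],
    ) -> "CEAResult":
        """Build a result from externally reported discounted aggregates."""
        full = {k: float(costs.get(k, 0.0)) for k in COST_COMPONENTS}
        return cls(
            strategy=strategy,
            costs=full,
            costs_undiscounted=dict(full),
            lys=EffectTotals(*lys),
            lys_undiscounted=EffectTotals(*lys),
            qalys=EffectTotals(*qalys),
            qalys_undiscounted=EffectTotals(*qalys),
        )

    def to_row(self) -> dict:
        row = {"strategy": self.strategy}
        row.update({k: self.costs[k] for k in COST_COMPONENTS})
        row.update(
            total_cost=self.total_cost,
            ly_ned=self.lys.ned,
            ly_rpd=self.lys.rpd,
            ly_total=self.lys.total,
            qaly_ned=self.qalys.ned,
            qaly_rpd=self.qalys.rpd,
            qaly_total=self.qalys.total,
            total_cost_undiscounted=self.total_cost_undiscounted,
            ly_total_undiscounted=self.lys_undiscounted.total,
            qaly_total_undiscounted=self.qalys_undiscounted.total,
        )
        return row


@dataclass(frozen=True)
class Comparison:
    """Incremental comparison of a strategy against a comparator."""

    strategy: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    qaly_flag: str  # "ratio" | "dominant" | "dominated" | "undefined"
    ly_flag: str
    wtp: float
    nmb_at_wtp: float

    def to_row(self) -> dict:
        return {
            "strategy": self.strategy,
            "comparator": self.comparator,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
            "qaly_flag": self.qaly_flag,
            "ly_flag": self.ly_flag,
            "wtp": self.wtp,
            "nmb_at_wtp": self.nmb_at_wtp,
        }


def discount_factor(t_years, rate: float):
    """Discrete annual discounting, ``(1 + rate) ** (-t)`` at cycle start."""
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    out = np.power(1.0 + rate, -t)
    return float(out) if np.isscalar(t_years) else out


def accumulate(trace: CohortTrace, spec: StrategySpec) -> CEAResult:
    """Accumulate discounted costs, LYs and QALYs over a cohort trace.

    Per-cycle accruals use state occupancy at the cycle start (no half-cycle
    correction) over the cycle length; recurrence-triggered lump costs
    (subsequent treatment, BSC) are charged to the newly recurrent mass at
    the boundary where it appears. Scan costs hit every alive patient on
    cycles containing a scheduled scan and are booked under the health-state
    components in proportion to occupancy.
    """
    spec.validate()
    if not math.isclose(
        trace.cycle_length_months, spec.schedule.cycle_length_months, rel_tol=1e-9
    ):
        raise ValueError(
            f"trace cycle length {trace.cycle_length_months:g} months does not "
            f"match strategy schedule {spec.schedule.cycle_length_months:g}"
        )

    t = trace.t_start
    t_years = t / 12.0
    cycle_years = trace.cycle_length_months / 12.0
    df_c = discount_factor(t_years, spec.discount.cost_rate)
    df_e = discount_factor(t_years, spec.discount.effect_rate)
    ones = np.ones_like(df_c)

    # Occupancy-at-cycle-start views (last boundary only closes the horizon).
    ned, rpd = trace.ned[:-1], trace.rpd[:-1]
    on_tx = trace.on_treatment[:-1]
    alive = ned + rpd
    wc, wu = df_c[:-1], ones[:-1]

    # Scans due per cycle [t_k, t_{k+1}); scans beyond the horizon are lost.
    scan_times = spec.schedule.scan_times()
    scans = np.histogram(scan_times, bins=t)[0].astype(float)

    e_acq, e_adm = spec.expected_subsequent_costs()
    newly = trace.newly_recurrent

    def costs_with(w_cycle: np.ndarray, w_event: np.ndarray) -> dict[str, float]:
        ned_share = np.divide(ned, alive, out=np.zeros_like(ned), where=alive > 0)
        scan_cost = spec.scan_cost_per_event * scans * alive
        return {
            "adjuvant_acquisition": float(spec.drug_cost_per_cycle * (on_tx * w_cycle).sum()),
            "adjuvant_admin": float(spec.admin_cost_per_cycle * (on_tx * w_cycle).sum()),
            "subsequent_acquisition": float(e_acq * (newly * w_event).sum()),
            "subsequent_admin": float(e_adm * (newly * w_event).sum()),
            "health_state_ned": float(
                ((spec.ned_cost_per_year * cycle_years * ned + scan_cost * ned_share) * w_cycle).sum()
            ),
            "health_state_rpd": float(
                ((spec.rpd_cost_per_year * cycle_years * rpd + scan_cost * (1 - ned_share)) * w_cycle).sum()
            ),
            "bsc": float(spec.bsc_cost_per_patient_entering_rpd * (newly * w_event).sum()),
            "informal_care": float(
                spec.societal.informal_care_per_rpd_year * cycle_years * (rpd * w_cycle).sum()
            ),
            "productivity": float(
                (
                    (
                        spec.societal.productivity_per_ned_year * ned
                        + spec.societal.productivity_per_rpd_year * rpd
                    )
                    * cycle_years
                    * w_cycle
                ).sum()
            ),
            "travel": float(
                spec.societal.travel_cost_per_visit * ((on_tx + scans * alive) * w_cycle).sum()
            ),
        }

    costs = costs_with(wc, df_c)
    costs_undisc = costs_with(wu, ones)

    def effects_with(w: np.ndarray) -> tuple[EffectTotals, EffectTotals]:
        ly_ned = float((ned * w).sum() * cycle_years)
        ly_rpd = float((rpd * w).sum() * cycle_years)
        q_ned = spec.utilities.u_ned * ly_ned
        q_rpd = spec.utilities.u_rpd * ly_rpd
        return EffectTotals(ly_ned, ly_rpd), EffectTotals(q_ned, q_rpd)

    lys, qalys = effects_with(df_e[:-1])
    lys_u, qalys_u = effects_with(wu)

    return CEAResult(
        strategy=spec.name,
        costs=costs,
        costs_undiscounted=costs_undisc,
        lys=lys,
        lys_undiscounted=lys_u,
        qalys=qalys,
        qalys_undiscounted=qalys_u,
    )


def _ratio_and_flag(delta_cost: float, delta_effect: float) -> tuple[Optional[float], str]:
    if delta_cost == 0.0 and delta_effect == 0.0:
        return None, "undefined"
    if delta_effect >= 0.0 and delta_cost <= 0.0:
        return None, "dominant"
    if delta_effect <= 0.0 and delta_cost >= 0.0:
        return None, "dominated"
    return delta_cost / delta_effect, "ratio"


def compare(strategy: CEAResult, comparator: CEAResult, wtp: float = 50_000.0) -> Comparison:
    """Incremental costs and effects, ICERs (with dominance flags) and NMB.

    ICERs are ``delta_cost / delta_effect`` when the deltas have the
    interpretable sign pattern (more costly, more effective — or the reverse);
    quadrants where one option dominates are flagged instead of ratioed.
    ``NMB = wtp * delta_qaly - delta_cost``.
    """
    dc = strategy.total_cost - comparator.total_cost
    dq = strategy.qalys.total - comparator.qalys.total
    dl = strategy.lys.total - comparator.lys.total
    icer_q, flag_q = _ratio_and_flag(dc, dq)
    icer_l, flag_l = _ratio_and_flag(dc, dl)
    return Comparison(
        strategy=strategy.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dl,
        icer_per_qaly=icer_q,
        icer_per_ly=icer_l,
        qaly_flag=flag_q,
        ly_flag=flag_l,
        wtp=wtp,
        nmb_at_wtp=wtp * dq - dc,
    )
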