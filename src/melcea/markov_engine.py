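"""Cohort state occupancy from recurrence-free and overall survival curves.

Three health states: NED (no evidence of disease), RPD (recurrent/progressive
disease) and death. Occupancy is derived directly from the two survival
curves (partitioned-survival arithmetic): NED(t) = RFS(t), death(t) = 1-OS(t),
RPD(t) = OS(t) - RFS(t). A transition-matrix view is provided as a derived
artifact; applied sequentially from (1, 0, 0) it reproduces the same trace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .survival_models import SurvivalCurveModel

__all__ = [
    "HealthState",
    "CycleSchedule",
    "CohortTrace",
    "TransitionMatrix",
    "TraceConsistencyError",
    "derive_occupancy",
    "to_transition_matrices",
    "apply_transition_matrices",
    "treated_fraction_series",
    "WEEKS_PER_MONTH",
]

logger = logging.getLogger(__name__)

#: 52 weeks / 12 months.
WEEKS_PER_MONTH = 52.0 / 12.0

#: Cohort mass below which the lifetime horizon is truncated.
ALIVE_FLOOR = 1e-6


class HealthState(IntEnum):
    NED = 0
    RPD = 1
    DEATH = 2


class TraceConsistencyError(ValueError):
    """Occupancy differences imply a negative transition probability."""


@dataclass(frozen=True)
class CycleSchedule:
    """Model time step and treatment/surveillance timing for one strategy.

    The cycle length equals the dosing interval (2 weeks nivolumab, 3 weeks
    pembrolizumab, 4 weeks dabrafenib-trametinib). Adjuvant treatment stops at
    ``treatment_duration_cap_months`` (one year by default). Surveillance scans
    run every 3 months for two years, then every 6 months for three more.
    """

    cycle_length_weeks: float
    treatment_duration_cap_months: float = 12.0
    scan_schedule: tuple[tuple[float, float, float], ...] = ((0.0, 24.0, 3.0), (24.0, 60.0, 6.0))

    def __post_init__(self) -> None:
        if self.cycle_length_weeks <= 0:
            raise ValueError("cycle_length_weeks must be positive")
        if self.treatment_duration_cap_months < 0:
            raise ValueError("treatment_duration_cap_months must be non-negative")
        object.__setattr__(
            self, "scan_schedule", tuple(tuple(map(float, s)) for s in self.scan_schedule)
        )
        spans = sorted(self.scan_schedule)
        for (a0, b0, _), (a1, _, _) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError("scan intervals must not overlap")

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_length_weeks / WEEKS_PER_MONTH

    def scan_times(self) -> np.ndarray:
        """Scheduled scan times in months (open at the window start)."""
        times: list[float] = []
        for start, stop, interval in self.scan_schedule:
            t = start + interval
            while t <= stop + 1e-9:
                times.append(t)
                t += interval
        return np.asarray(sorted(times))


@dataclass(frozen=True)
class CohortTrace:
    """Per-boundary occupancy of the three states plus treatment indicators.

    Arrays hold values at cycle boundaries ``t_start[k] = k * cycle_length``;
    the last boundary closes the final cycle. ``newly_recurrent[k]`` is the
    NED outflow during the cycle ending at ``t_start[k]``.
    """

    t_start: np.ndarray
    ned: np.ndarray
    rpd: np.ndarray
    death: np.ndarray
    on_treatment: np.ndarray
    newly_recurrent: np.ndarray
    cycle_length_months: float
    start_age: float = 50.0

    def __post_init__(self) -> None:
        for name in ("t_start", "ned", "rpd", "death", "on_treatment", "newly_recurrent"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        occ = self.ned + self.rpd + self.death
        if np.any(np.abs(occ - 1.0) > 1e-9):
            raise ValueError("occupancy must sum to 1 at every cycle boundary")
        if np.any(np.diff(self.ned) > 1e-9):
            raise ValueError("NED occupancy must be non-increasing")
        if np.any(np.diff(self.death) < -1e-9):
            raise ValueError("death occupancy must be non-decreasing")
        if np.any(self.rpd < -1e-12):
            raise ValueError("RPD occupancy must be non-negative")
        if np.any(self.on_treatment > self.ned + 1e-9):
            raise ValueError("on_treatment cannot exceed NED occupancy")

    @property
    def n_cycles(self) -> int:
        return self.t_start.size - 1

    @property
    def alive(self) -> np.ndarray:
        return self.ned + self.rpd

    def occupancy(self, k: int) -> np.ndarray:
        return np.array([self.ned[k], self.rpd[k], self.death[k]])

    def truncated(self, horizon_months: float) -> "CohortTrace":
        """The trace restricted to boundaries at or before ``horizon_months``."""
        keep = int(np.searchsorted(self.t_start, horizon_months + 1e-9, side="right"))
        if keep < 2:
            raise ValueError("horizon shorter than one cycle")
        return CohortTrace(
            t_start=self.t_start[:keep],
            ned=self.ned[:keep],
            rpd=self.rpd[:keep],
            death=self.death[:keep],
            on_treatment=self.on_treatment[:keep],
            newly_recurrent=self.newly_recurrent[:keep],
            cycle_length_months=self.cycle_length_months,
            start_age=self.start_age,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.t_start.size),
                "t_start_months": self.t_start,
                "p_ned": self.ned,
                "p_rpd": self.rpd,
                "p_death": self.death,
                "on_treatment": self.on_treatment,
                "newly_recurrent": self.newly_recurrent,
            }
        )


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 3x3 transition matrix for one cycle."""

    cycle_index: int
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("rows must sum to 1")
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if not math.isclose(p[HealthState.DEATH, HealthState.DEATH], 1.0):
            raise ValueError("death must be absorbing")
        if p[HealthState.RPD, HealthState.NED] > 1e-12:
            raise ValueError("RPD cannot return to NED")


def derive_occupancy(
    rfs: SurvivalCurveModel,
    os_curve: SurvivalCurveModel,
    schedule: CycleSchedule,
    horizon_months: float | None = None,
    max_age: float = 100.0,
) -> CohortTrace:
    """Partition the cohort over NED/RPD/death at every cycle boundary.

    Everyone starts in NED. If the independently extrapolated curves cross
    (RFS above OS), NED is clipped to OS and a warning identifies the cycles.
    A ``None`` horizon means lifetime: until the cohort reaches ``max_age`` or
    virtually nobody is left alive.
    """
    if not math.isclose(rfs.start_age, os_curve.start_age):
        raise ValueError("RFS and OS models must share start_age")
    delta = schedule.cycle_length_months
    if horizon_months is None:
        horizon_months = (max_age - rfs.start_age) * 12.0
    if horizon_months < delta:
        raise ValueError("horizon shorter than one cycle")

    n_cycles = int(math.ceil(horizon_months / delta - 1e-9))
    t = np.arange(n_cycles + 1) * delta
    s_rfs = rfs(t)
    s_os = os_curve(t)

    # Lifetime truncation once the cohort is (numerically) extinct.
    dead_idx = np.nonzero(s_os < ALIVE_FLOOR)[0]
    if horizon_months >= (max_age - rfs.start_age) * 12.0 - 1e-9 and dead_idx.size:
        keep = max(int(dead_idx[0]) + 1, 2)
        t, s_rfs, s_os = t[:keep], s_rfs[:keep], s_os[:keep]

    clipped = s_rfs > s_os + 1e-12
    if np.any(clipped):
        idx = np.nonzero(clipped)[0]
        logger.warning(
            "RFS exceeds OS on cycles %d-%d; RPD clipped at 0", idx[0], idx[-1]
        )
    ned = np.minimum(s_rfs, s_os)
    death = 1.0 - s_os
    rpd = s_os - ned

    cap = schedule.treatment_duration_cap_months
    on_treatment = np.where(t < cap - 1e-9, ned, 0.0)
    newly = np.concatenate([[0.0], np.maximum(ned[:-1] - ned[1:], 0.0)])

    return CohortTrace(
        t_start=t,
        ned=ned,
        rpd=rpd,
        death=death,
        on_treatment=on_treatment,
        newly_recurrent=newly,
        cycle_length_months=delta,
        start_age=rfs.start_age,
    )


def to_transition_matrices(trace: CohortTrace) -> list[TransitionMatrix]:
    """Infer per-cycle transition matrices that reproduce the trace.

    NED outflow splits between RPD and death; deaths are drawn from RPD first
    (capped by its occupancy), the remainder from NED. States with zero
    occupancy get self-loop rows. Raises ``TraceConsistencyError`` if the
    occupancy differences imply a negative flow.
    """
    mats: list[TransitionMatrix] = []
    for k in range(trace.n_cycles):
        ned0, rpd0 = trace.ned[k], trace.rpd[k]
        ned1, rpd1 = trace.ned[k + 1], trace.rpd[k + 1]
        d_death = trace.death[k + 1] - trace.death[k]
        a_total = ned0 - ned1  # NED outflow
        if a_total < -1e-9 or d_death < -1e-9:
            raise TraceConsistencyError(f"negative flow at cycle {k}")
        from_rpd = min(d_death, rpd0)
        from_ned_death = d_death - from_rpd
        to_rpd = a_total - from_ned_death
        if to_rpd < -1e-9:
            raise TraceConsistencyError(
                f"NED outflow smaller than NED deaths at cycle {k}"
            )
        to_rpd = max(to_rpd, 0.0)

        p = np.eye(3)
        if ned0 > 0:
            p[HealthState.NED] = [
                max(ned0 - a_total, 0.0) / ned0,
                to_rpd / ned0,
                from_ned_death / ned0,
            ]
        if rpd0 > 0:
            p[HealthState.RPD] = [0.0, (rpd0 - from_rpd) / rpd0, from_rpd / rpd0]
        p /= p.sum(axis=1, keepdims=True)
        mats.append(TransitionMatrix(cycle_index=k, p=p))
    return mats


def apply_transition_matrices(
    mats: list[TransitionMatrix], initial: np.ndarray | None = None
) -> np.ndarray:
    """Propagate an occupancy row vector through the matrices (rows x states)."""
    occ = np.array([1.0, 0.0, 0.0]) if initial is None else np.asarray(initial, float)
    out = [occ]
    for m in mats:
        occ = occ @ m.p
        out.append(occ)
    return np.vstack(out)


def treated_fraction_series(trace: CohortTrace) -> list[tuple[int, float]]:
    """Per-cycle probability of receiving adjuvant drug, for acquisition costing.

    Follows the RFS decrement (discontinuation at recurrence) and is zero from
    the treatment-duration cap onward.
    """
    return [(k, float(trace.on_treatment[k])) for k in range(trace.n_cycles)]
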