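"""Particle clearance kinetics and mechanical-dose accounting.

Elemental iron measured in a tissue over days after injection decays
roughly exponentially as particles are cleared. Fitting log-linear ordinary
least squares to ln(mass) vs time gives a decay rate and half-life; the
fitted exponential then interpolates particle count — and hence ensemble
force at a known gradient — continuously over the treatment course, so the
mechanical dose (∫F dt over stimulation-ON intervals) can be integrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate

from .particle_model import particle_count_from_iron

__all__ = [
    "IronTimeSeries",
    "ClearanceFit",
    "ForceReport",
    "ClearanceFitError",
    "fit_clearance",
    "force_timecourse",
    "cumulative_impulse",
]

SEC_PER_MIN = 60.0
PG_PER_UG = 1e6


class ClearanceFitError(ValueError):
    """The iron time series cannot support a log-linear fit."""


@dataclass(frozen=True)
class IronTimeSeries:
    """Elemental-iron mass in one tissue vs time.

    times in days (strictly increasing), masses in μg.
    """

    times_days: tuple[float, ...]
    masses_ug: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.times_days) != len(self.masses_ug):
            raise ValueError("times and masses must have equal length")
        t = self.times_days
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")
        if any(ti < 0 for ti in t):
            raise ValueError("times must be >= 0")
        if any(m < 0 for m in self.masses_ug):
            raise ValueError("masses must be >= 0")


@dataclass(frozen=True)
class ClearanceFit:
    """First-order clearance parameters from a log-linear fit."""

    initial_mass_ug: float
    decay_rate_per_day: float
    half_life_days: float
    r_squared: float

    def mass_at(self, t_days):
        """Fitted mass m₀·e^(−kt), μg; accepts scalars or arrays."""
        return self.initial_mass_ug * np.exp(-self.decay_rate_per_day * np.asarray(t_days, dtype=float))


@dataclass(frozen=True)
class ForceReport:
    """Derived dose quantities at one time point / condition."""

    time_days: float
    iron_mass_ug: float
    particle_count: float
    per_particle_force_pN: float
    ensemble_force_pN: float

    @property
    def ensemble_force_uN(self) -> float:
        return self.ensemble_force_pN / 1e6


def fit_clearance(series: IronTimeSeries) -> ClearanceFit:
    """Fit m(t) = m₀·e^(−kt) by OLS on (t, ln m).

    decay_rate = −slope, initial_mass = exp(intercept); half-life is
    ln2/k, or infinite for a non-decaying (k ≤ 0) series.
    """
    if len(series.times_days) < 2:
        raise ClearanceFitError("need at least 2 time points to fit clearance")
    for t, m in zip(series.times_days, series.masses_ug):
        if m <= 0:
            raise ClearanceFitError(
                f"non-positive mass {m} μg at day {t}: log-linear fit undefined")
    t = np.asarray(series.times_days, dtype=float)
    y = np.log(np.asarray(series.masses_ug, dtype=float))
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    k = -float(slope)
    half_life = math.log(2) / k if k > 0 else math.inf
    return ClearanceFit(
        initial_mass_ug=float(np.exp(intercept)),
        decay_rate_per_day=k,
        half_life_days=half_life,
        r_squared=r2,
    )


def force_timecourse(series: IronTimeSeries, per_particle_iron_pg: float,
                     per_particle_force_pN: float) -> list[ForceReport]:
    """Per-time-point particle counts and ensemble forces.

    count = mass / per-particle iron; force = count × per-particle force.
    Masses are μg, per-particle iron pg, forces pN.
    """
    if per_particle_iron_pg <= 0 or per_particle_force_pN <= 0:
        raise ValueError("per-particle iron mass and force must be > 0")
    reports = []
    for t, m_ug in zip(series.times_days, series.masses_ug):
        n = particle_count_from_iron(m_ug * PG_PER_UG, per_particle_iron_pg)
        reports.append(ForceReport(
            time_days=t,
            iron_mass_ug=m_ug,
            particle_count=n,
            per_particle_force_pN=per_particle_force_pN,
            ensemble_force_pN=n * per_particle_force_pN,
        ))
    return reports


def cumulative_impulse(intervals: Sequence[tuple[float, float]],
                       force_fn: Callable[[float], float]) -> float:
    """Mechanical dose ∫F(t)dt over the ON intervals, in pN·s.

    ``intervals`` are (start, end) in minutes on the schedule's time axis;
    ``force_fn`` maps time in minutes to a non-negative force in pN. Each
    interval is integrated by adaptive quadrature and the pieces summed, so
    the result is additive over any disjoint partition of the schedule.
    """
    total = 0.0
    for a, b in intervals:
        lo = min(force_fn(a), force_fn(b), force_fn(0.5 * (a + b)))
        if lo < 0:
            raise ValueError(f"force is negative within interval ({a}, {b}) min")
        piece, _ = integrate.quad(force_fn, a, b, limit=200)
        total += piece
    return total * SEC_PER_MIN
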