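"""Outcome metrics for nerve-regeneration and cell-mechanics assays.

Implements the standard scalar formulas these experiments report:

* SFI — sciatic functional index from walking-track footprints (Bain
  formula): 0 ≈ normal hindlimb function, −100 ≈ complete dysfunction.
* CCK-8 viability percentage with blank and nanomaterial-absorbance
  controls.
* Orientation index Oi = cos θ of cell alignment with the field vector.
* G-ratio (axon diameter / fiber diameter) of myelinated axons.
* ΔF/F₀ and F_max/F₀ from calcium-indicator fluorescence traces.
* Motor nerve conduction velocity from two-point stimulation latencies.
* F/G-actin ratio.

Batch helpers aggregate per-group medians with interquartile ranges, the
reporting style used for the non-normally distributed morphometrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FootprintRecord",
    "ViabilityRecord",
    "CalciumTrace",
    "FiberRecord",
    "sfi",
    "viability_percent",
    "orientation_index",
    "fold_angle",
    "g_ratio",
    "calcium_metrics",
    "mncv",
    "fg_ratio",
    "median_iqr",
]

# Bain et al. sciatic-functional-index coefficients
SFI_PL_COEF = -38.3
SFI_TS_COEF = 109.5
SFI_ITS_COEF = 13.3
SFI_OFFSET = -8.8


@dataclass(frozen=True)
class FootprintRecord:
    """Bilateral walking-track footprint lengths, mm.

    E = experimental (injured) limb, N = contralateral normal limb;
    PL print length, TS toe spread (toes 1–5), IT intermediary toe
    spread (toes 2–4).
    """

    EPL: float
    NPL: float
    ETS: float
    NTS: float
    EIT: float
    NIT: float

    def __post_init__(self) -> None:
        for name in ("EPL", "NPL", "ETS", "NTS", "EIT", "NIT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ViabilityRecord:
    """CCK-8 absorbances: sample, untreated control, no-cell blank, and a
    drug control (nanomaterial + reagent, no cells) that removes particle
    absorbance."""

    A_sample: float
    A_control: float
    A_blank: float
    A_drug: float

    def __post_init__(self) -> None:
        if self.A_control <= self.A_blank:
            raise ValueError("A_control must exceed A_blank")


@dataclass(frozen=True)
class CalciumTrace:
    """A fluorescence time series with a pre-stimulation baseline window.

    Baseline F₀ is the mean intensity before ``stimulation_onset_s``
    (default 50 s, with imaging typically spanning 650 s total).
    """

    times_s: tuple[float, ...]
    intensities: tuple[float, ...]
    stimulation_onset_s: float = 50.0

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.intensities):
            raise ValueError("times and intensities must have equal length")
        t = self.times_s
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")
        if any(i < 0 for i in self.intensities):
            raise ValueError("intensities must be >= 0")
        if not t[0] < self.stimulation_onset_s <= t[-1]:
            raise ValueError("stimulation onset must fall inside the time range "
                             "with a non-empty baseline window")


@dataclass(frozen=True)
class FiberRecord:
    """Axon and total fiber (axon + myelin) diameters of one myelinated
    fiber, μm."""

    axon_diameter_um: float
    fiber_diameter_um: float

    def __post_init__(self) -> None:
        if self.axon_diameter_um <= 0:
            raise ValueError("axon diameter must be > 0")
        if self.fiber_diameter_um < self.axon_diameter_um:
            raise ValueError("fiber diameter must be >= axon diameter")


def sfi(record: FootprintRecord) -> float:
    """Sciatic functional index (Bain formula).

    −38.3·(EPL−NPL)/NPL + 109.5·(ETS−NTS)/NTS + 13.3·(EIT−NIT)/NIT − 8.8.
    Identity (E == N) scores −8.8; scale-invariant under a common
    rescaling of all six lengths.
    """
    return (SFI_PL_COEF * (record.EPL - record.NPL) / record.NPL
            + SFI_TS_COEF * (record.ETS - record.NTS) / record.NTS
            + SFI_ITS_COEF * (record.EIT - record.NIT) / record.NIT
            + SFI_OFFSET)


def viability_percent(record: ViabilityRecord) -> float:
    """CCK-8 viability: 100·(A_sample − A_drug)/(A_control − A_blank).

    May exceed 100 (proliferation) or go negative (reported as-is, with a
    warning, since negative viability flags an assay problem).
    """
    v = 100.0 * (record.A_sample - record.A_drug) / (record.A_control - record.A_blank)
    if v < 0:
        warnings.warn(f"negative viability {v:.1f}%: check absorbance controls",
                      stacklevel=2)
    return v


def fold_angle(theta_rad: float) -> float:
    """Fold any angle to the acute angle in [0, π/2] between two axes.

    Axes are direction-free, so θ, −θ, π−θ all describe the same
    alignment; folding is idempotent.
    """
    t = math.fmod(abs(theta_rad), math.pi)
    return min(t, math.pi - t)


def orientation_index(theta_rad: float) -> float:
    """Oi = cos θ of the acute angle between cell axis and field vector.

    1 = fully aligned with the field, 0 = perpendicular. Angles outside
    [0, π/2] are folded first.
    """
    return math.cos(fold_angle(theta_rad))


def g_ratio(record: FiberRecord) -> float:
    """Axon diameter / fiber diameter ∈ (0, 1]; lower = thicker myelin."""
    return record.axon_diameter_um / record.fiber_diameter_um


def calcium_metrics(trace: CalciumTrace,
                    response_window_s: tuple[float, float] | None = None) -> dict:
    """ΔF/F₀ (percent) and F_max/F₀ of a calcium trace.

    F₀ is the mean intensity over the baseline window (start of trace to
    stimulation onset). ΔF/F₀ = (F_stim − F₀)/F₀ × 100 with F_stim the
    mean over the post-onset response window (default: everything after
    onset); F_max/F₀ uses the post-onset maximum. Both are ratios, hence
    invariant under multiplicative rescaling of the raw intensities.
    """
    t = np.asarray(trace.times_s, dtype=float)
    f = np.asarray(trace.intensities, dtype=float)
    baseline = f[t < trace.stimulation_onset_s]
    f0 = float(baseline.mean())
    if f0 <= 0:
        raise ValueError(f"baseline fluorescence F0 = {f0} must be > 0")
    if response_window_s is None:
        post = f[t >= trace.stimulation_onset_s]
    else:
        lo, hi = response_window_s
        post = f[(t >= lo) & (t <= hi)]
    if post.size == 0:
        raise ValueError("response window contains no samples")
    f_stim = float(post.mean())
    return {
        "F0": f0,
        "dF_over_F0_percent": (f_stim - f0) / f0 * 100.0,
        "Fmax_over_F0": float(post.max()) / f0,
    }


def mncv(distance_mm: float, latency_proximal_ms: float,
         latency_distal_ms: float) -> float:
    """Motor nerve conduction velocity, m/s.

    Inter-electrode distance divided by the proximal−distal latency
    difference; mm/ms ≡ m/s.
    """
    if distance_mm <= 0:
        raise ValueError("distance must be > 0")
    if latency_distal_ms < 0:
        raise ValueError("latencies must be >= 0")
    dt = latency_proximal_ms - latency_distal_ms
    if dt <= 0:
        raise ValueError("proximal latency must exceed distal latency")
    return distance_mm / dt


def fg_ratio(f_actin: float, g_actin: float) -> float:
    """Filamentous/globular actin ratio (same units top and bottom)."""
    if g_actin <= 0:
        raise ValueError("G-actin amount must be > 0")
    if f_actin < 0:
        raise ValueError("F-actin amount must be >= 0")
    return f_actin / g_actin


def median_iqr(values: Sequence[float]) -> dict:
    """Median with [Q1–Q3] interquartile range, the reporting convention
    for non-normally distributed morphometrics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to aggregate")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}
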