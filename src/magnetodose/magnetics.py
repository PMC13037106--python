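"""Magnetization and force models, plus the two gradient-field generators.

A superparamagnetic particle with moment m in a flux-density gradient ∇B
feels F = (m·∇)B; in the 1-D axial convention used throughout this package
(moment aligned with the field, only axial gradients reported) this reduces
to F = m·dB/dz.

Two ways of obtaining the per-particle moment are supported:

* ``model`` — Langevin magnetization M_s·L(x) from the saturation
  magnetization, crystallite size and the *local field* B, which must be
  supplied by the caller.
* ``calibrated`` — per-particle force constants measured at known gradients
  are taken as ground truth and the moment is backed out as F/∇B. This is
  the default, because local field magnitudes at the sample are rarely
  characterized while forces at a given gradient are.

Field generators: a current-calibrated electromagnet (linear fit through
calibration points) and an annular-magnet array whose on-axis field follows
from the closed-form solid-cylinder expression (outer minus inner radius).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .particle_model import ParticleSpec, magnetite_mass_per_particle

__all__ = [
    "MagnetizationModel",
    "MomentCalibration",
    "ElectromagnetCalibration",
    "RingMagnet",
    "RingArray",
    "CalibrationError",
    "langevin",
    "langevin_magnetization",
    "particle_moment",
    "calibrated_moment",
    "force_on_particle",
    "ensemble_force",
    "format_force",
    "electromagnet_gradient",
    "ring_axial_profile",
]

MU_0 = 4e-7 * math.pi          # T·m/A
K_B = 1.380649e-23             # J/K
PN_PER_N = 1e12

#: default per-particle force calibration: (gradient T/m, force pN) pairs
#: measured for the electromagnet (in vitro) and ring array (in vivo) settings
DEFAULT_FORCE_CALIBRATION: tuple[tuple[float, float], ...] = (
    (3.25, 1.59e-5),
    (16.0, 1.27e-4),
)


class CalibrationError(ValueError):
    """A field-source calibration is unusable (too few points, bad order)."""


# ---------------------------------------------------------------------------
# magnetization


@dataclass(frozen=True)
class MagnetizationModel:
    """Langevin superparamagnet described by its saturation magnetization.

    ``bulk_crystallite_magnetization_A_m`` sets the moment of one
    crystallite (μ = M_bulk·V_crystallite) that enters the Langevin
    argument x = μB/(k_B·T). Default 480 kA/m, bulk magnetite.
    """

    saturation_magnetization_emu_g: float = 30.0
    crystallite_diameter_nm: float = 5.80
    bulk_crystallite_magnetization_A_m: float = 4.8e5
    temperature_K: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature_K}")
        if self.saturation_magnetization_emu_g < 0:
            raise ValueError("saturation magnetization must be >= 0")
        if self.crystallite_diameter_nm <= 0 or self.bulk_crystallite_magnetization_A_m <= 0:
            raise ValueError("crystallite diameter and bulk magnetization must be > 0")

    @property
    def crystallite_moment_A_m2(self) -> float:
        v = (math.pi / 6.0) * (self.crystallite_diameter_nm * 1e-9) ** 3
        return self.bulk_crystallite_magnetization_A_m * v


def langevin(x):
    """L(x) = coth(x) − 1/x, evaluated stably near 0.

    Odd, monotone, L(x) → x/3 as x → 0 and → ±1 as x → ±∞. The series
    branch (|x| < 1e-4) keeps the x→0 limit exact and avoids catastrophic
    cancellation.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)  # dummy to avoid warnings
    with np.errstate(over="ignore"):
        full = 1.0 / np.tanh(xs) - 1.0 / xs
    series = x / 3.0 - x**3 / 45.0
    out = np.where(small, series, full)
    return float(out) if out.ndim == 0 else out


def langevin_magnetization(field_T: float, model: MagnetizationModel) -> float:
    """Field-dependent mass magnetization M_s·L(μB/k_BT), in emu/g.

    Zero at zero field, saturating to M_s; never exceeds M_s.
    """
    if field_T < 0:
        raise ValueError("field must be >= 0 in the scalar co-linear convention")
    x = model.crystallite_moment_A_m2 * field_T / (K_B * model.temperature_K)
    return model.saturation_magnetization_emu_g * langevin(x)


def particle_moment(spec: ParticleSpec, field_T: float,
                    model: MagnetizationModel | None = None) -> float:
    """Magnetic moment of one superparticle at a given local field, in A·m².

    Mass magnetization (emu/g ≡ A·m²/kg) times the magnetite mass of the
    particle. Use :func:`calibrated_moment` when the local field is unknown
    but a per-particle force at a known gradient has been measured.
    """
    if model is None:
        model = MagnetizationModel(
            saturation_magnetization_emu_g=spec.saturation_magnetization_emu_g,
            crystallite_diameter_nm=spec.crystallite_diameter_nm,
        )
    sigma = langevin_magnetization(field_T, model)  # A·m²/kg
    return sigma * magnetite_mass_per_particle(spec)


@dataclass(frozen=True)
class MomentCalibration:
    """Per-particle force constants at known gradients ("calibrated" mode)."""

    points: tuple[tuple[float, float], ...] = DEFAULT_FORCE_CALIBRATION

    def moment_at(self, gradient_T_m: float) -> float:
        """Moment F/∇B (A·m²) from the calibration point nearest in gradient."""
        if not self.points:
            raise CalibrationError("no force calibration points")
        grad, force_pn = min(self.points, key=lambda p: abs(p[0] - gradient_T_m))
        if grad <= 0:
            raise CalibrationError("calibration gradient must be > 0")
        return (force_pn / PN_PER_N) / grad

    def force_at(self, gradient_T_m: float) -> float:
        """Per-particle force (pN) at a gradient, via the backed-out moment."""
        return force_on_particle(self.moment_at(gradient_T_m), gradient_T_m)


def calibrated_moment(force_pN: float, gradient_T_m: float) -> float:
    """Back a moment (A·m²) out of a measured per-particle force and gradient."""
    if gradient_T_m <= 0:
        raise ValueError("gradient must be > 0 to back out a moment")
    return (force_pN / PN_PER_N) / gradient_T_m


# ---------------------------------------------------------------------------
# force


def force_on_particle(moment_A_m2: float, gradient_T_m: float) -> float:
    """F = m·∇B in the scalar co-linear convention, returned in pN."""
    if gradient_T_m < 0:
        raise ValueError("gradient must be >= 0 in the scalar co-linear convention")
    return moment_A_m2 * gradient_T_m * PN_PER_N


def ensemble_force(count: float, per_particle_force_pN: float) -> float:
    """Total force of ``count`` identical particles, in pN."""
    if count < 0 or per_particle_force_pN < 0:
        raise ValueError("count and per-particle force must be >= 0")
    return count * per_particle_force_pN


def format_force(force_pN: float) -> str:
    """Render a force in pN, switching to μN above 10⁶ pN (3 s.f.)."""
    if force_pN >= 1e6:
        return f"{force_pN / 1e6:.3g} μN"
    return f"{force_pN:.3g} pN"


# ---------------------------------------------------------------------------
# field sources


@dataclass(frozen=True)
class ElectromagnetCalibration:
    """Electromagnet described by (current A → axial gradient T/m) points."""

    points: tuple[tuple[float, float], ...] = ((1.0, 1.25), (2.0, 2.25), (3.0, 3.25))

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise CalibrationError("need at least 2 calibration points")
        currents = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(currents, currents[1:])):
            raise CalibrationError("calibration currents must be strictly increasing")


def electromagnet_gradient(current_A: float, source: ElectromagnetCalibration) -> float:
    """Axial gradient (T/m) at a drive current, from the linear calibration fit.

    Ordinary least squares through the calibration points; exactly 0 at zero
    current by convention (no current, no field). Extrapolating beyond the
    calibrated range warns.
    """
    if current_A < 0:
        raise ValueError("current must be >= 0")
    if current_A == 0:
        return 0.0
    pts = np.asarray(source.points, dtype=float)
    slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
    lo, hi = pts[0, 0], pts[-1, 0]
    if not lo <= current_A <= hi:
        warnings.warn(
            f"current {current_A} A outside calibrated range [{lo}, {hi}] A; "
            "extrapolating", stacklevel=2)
    return float(slope * current_A + intercept)


@dataclass(frozen=True)
class RingMagnet:
    """One axially magnetized annular magnet.

    ``z_center_mm`` places the magnet's mid-plane on the axis; ``polarity``
    flips the magnetization direction.
    """

    inner_radius_mm: float = 35.0
    outer_radius_mm: float = 75.0
    thickness_mm: float = 15.0
    z_center_mm: float = 0.0
    polarity: int = 1
    remanence_T: float = 1.40

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("need outer_radius > inner_radius > 0")
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be > 0")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be ±1")
        if self.remanence_T < 0:
            raise ValueError("remanence must be >= 0")


@dataclass(frozen=True)
class RingArray:
    """A stack of annular magnets on a common axis."""

    magnets: tuple[RingMagnet, ...]


def _cylinder_bz(z_m, radius_m, z1_m, z2_m, br_T):
    """On-axis B_z of a uniformly axially magnetized solid cylinder.

    B(z) = (Br/2)[(z−z1)/√((z−z1)²+R²) − (z−z2)/√((z−z2)²+R²)], finite at
    the faces.
    """
    u1 = z_m - z1_m
    u2 = z_m - z2_m
    return 0.5 * br_T * (u1 / np.sqrt(u1**2 + radius_m**2)
                         - u2 / np.sqrt(u2**2 + radius_m**2))


def _cylinder_dbz(z_m, radius_m, z1_m, z2_m, br_T):
    """Analytic d/dz of :func:`_cylinder_bz` (d/du[u/√(u²+R²)] = R²/(u²+R²)^{3/2})."""
    u1 = z_m - z1_m
    u2 = z_m - z2_m
    r2 = radius_m**2
    return 0.5 * br_T * (r2 / (u1**2 + r2) ** 1.5 - r2 / (u2**2 + r2) ** 1.5)


def ring_axial_profile(z_positions_mm, array: RingArray):
    """On-axis (B, dB/dz) of an annular-magnet array.

    Each annulus is the difference of two co-axial solid cylinders (outer
    radius minus inner radius); magnets superpose with their polarity signs.

    Parameters
    ----------
    z_positions_mm
        Axial evaluation positions, mm.
    array
        The magnet stack.

    Returns
    -------
    (B, dBdz)
        Arrays of flux density (T) and axial gradient (T/m) at each z.
    """
    z = np.asarray(z_positions_mm, dtype=float) * 1e-3
    b = np.zeros_like(z)
    g = np.zeros_like(z)
    for m in array.magnets:
        z1 = (m.z_center_mm - m.thickness_mm / 2.0) * 1e-3
        z2 = (m.z_center_mm + m.thickness_mm / 2.0) * 1e-3
        br = m.polarity * m.remanence_T
        ro = m.outer_radius_mm * 1e-3
        ri = m.inner_radius_mm * 1e-3
        b += _cylinder_bz(z, ro, z1, z2, br) - _cylinder_bz(z, ri, z1, z2, br)
        g += _cylinder_dbz(z, ro, z1, z2, br) - _cylinder_dbz(z, ri, z1, z2, br)
    return b, g


def study_ring_array(remanence_T: float = 1.40, gap_mm: float = 15.0) -> RingArray:
    """Four-annulus array: two co-oriented pairs in opposition across a gap.

    Each pair is two stacked 70 mm ID / 150 mm OD / 15 mm thick annuli; the
    pairs face each other across ``gap_mm`` with opposed polarity, which
    nulls B on the mid-plane while maximizing the axial gradient there —
    the configuration used for whole-limb gradient exposure. The exact
    arrangement of such devices varies; this factory reproduces the
    geometry qualitatively.
    """
    t = 15.0
    z0 = gap_mm / 2.0 + t / 2.0
    mk = lambda zc, pol: RingMagnet(inner_radius_mm=35.0, outer_radius_mm=75.0,
                                    thickness_mm=t, z_center_mm=zc, polarity=pol,
                                    remanence_T=remanence_T)
    return RingArray((mk(-z0 - t, 1), mk(-z0, 1), mk(z0, -1), mk(z0 + t, -1)))


def ring_array_total_moment(array: RingArray) -> float:
    """Total dipole moment Σ polarity·(Br/μ₀)·V of the array, in A·m²."""
    total = 0.0
    for m in array.magnets:
        vol = math.pi * ((m.outer_radius_mm * 1e-3) ** 2
                         - (m.inner_radius_mm * 1e-3) ** 2) * m.thickness_mm * 1e-3
        total += m.polarity * (m.remanence_T / MU_0) * vol
    return total
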