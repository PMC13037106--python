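"""Superparticle composition model: geometry and iron content.

Converts the geometry and composition of a core–shell superparamagnetic
iron oxide superparticle (magnetite crystallites packed inside a spherical
core, organic shell) into the elemental-iron mass carried by one particle,
and elemental-iron measurements (ICP-AES) into particle counts.

Internally everything is SI (kg, m); the public surface speaks the units
the measurements arrive in (nm, pg, μg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "ParticleSpec",
    "IronMassMeasurement",
    "InvalidSpecError",
    "UnitError",
    "FE_MASS_FRACTION_MAGNETITE",
    "iron_mass_per_particle",
    "magnetite_mass_per_particle",
    "particle_count_from_iron",
    "read_iron_measurements",
    "write_iron_measurements",
]

# Fe3O4 stoichiometry: 3 * M(Fe) / M(Fe3O4) = 3 * 55.845 / 231.533
FE_MASS_FRACTION_MAGNETITE = 3 * 55.845 / 231.533

#: unit → pg conversion factors for iron-mass measurement tables
_MASS_TO_PG = {"pg": 1.0, "ng": 1e3, "ug": 1e6, "μg": 1e6, "mg": 1e9, "g": 1e12}

PG_PER_KG = 1e15
M_PER_NM = 1e-9


class InvalidSpecError(ValueError):
    """A particle specification violates its physical invariants."""


class UnitError(ValueError):
    """A mass carries an undeclared or unrecognized unit."""


@dataclass(frozen=True)
class ParticleSpec:
    """Geometry, density and magnetization of one superparticle.

    Parameters
    ----------
    crystallite_diameter_nm
        Diameter of the individual magnetite crystallites (building blocks
        of the core). Enters only the Langevin magnetization argument.
    core_diameter_nm
        Diameter of the magnetite/dye superparticle core. Only the core
        carries iron; the organic shell is elementally inert.
    shell_thickness_nm
        Organic coating thickness. Metadata for the overall particle size;
        contributes no iron and no moment.
    packing_fraction
        Volume fraction of the core occupied by magnetite crystallites
        (remainder is dye/surfactant/voids). Calibrated default 0.62.
    magnetite_density_g_cm3
        Crystalline magnetite density, 5.18 g/cm³.
    fe_mass_fraction_of_magnetite
        Elemental-iron mass fraction of magnetite, ≈0.7236 from Fe₃O₄
        stoichiometry.
    saturation_magnetization_emu_g
        Mass saturation magnetization of the magnetite content
        (emu/g ≡ A·m²/kg).
    """

    crystallite_diameter_nm: float = 5.80
    core_diameter_nm: float = 56.60
    shell_thickness_nm: float = 5.79
    packing_fraction: float = 0.62
    magnetite_density_g_cm3: float = 5.18
    fe_mass_fraction_of_magnetite: float = FE_MASS_FRACTION_MAGNETITE
    saturation_magnetization_emu_g: float = 30.0

    def __post_init__(self) -> None:
        for name in ("crystallite_diameter_nm", "core_diameter_nm",
                     "magnetite_density_g_cm3"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.shell_thickness_nm < 0:
            raise InvalidSpecError("shell_thickness_nm must be >= 0")
        if not 0 < self.packing_fraction <= 1:
            raise InvalidSpecError(
                f"packing_fraction must be in (0, 1], got {self.packing_fraction}")
        if not 0 < self.fe_mass_fraction_of_magnetite < 1:
            raise InvalidSpecError(
                "fe_mass_fraction_of_magnetite must be in (0, 1), "
                f"got {self.fe_mass_fraction_of_magnetite}")
        if self.saturation_magnetization_emu_g < 0:
            raise InvalidSpecError("saturation_magnetization_emu_g must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "ParticleSpec":
        """Build from a config mapping with unit-suffixed keys."""
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise InvalidSpecError(f"unknown particle-spec keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class IronMassMeasurement:
    """One elemental-iron mass measurement (per cell or per tissue).

    ``iron_mass`` is in pg for ``compartment='cell'`` and μg for
    ``compartment='tissue'`` by convention of the CSV schema; the
    ``iron_mass_units`` column makes this explicit on disk.
    """

    subject_id: str
    compartment: str  # "cell" | "tissue"
    time_days: float
    iron_mass: float
    iron_mass_units: str = "pg"
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.compartment not in ("cell", "tissue"):
            raise ValueError(f"compartment must be 'cell' or 'tissue', got "
                             f"{self.compartment!r}")
        if self.iron_mass < 0:
            raise ValueError("iron_mass must be >= 0")
        if self.time_days < 0:
            raise ValueError("time_days must be >= 0")
        if self.uncertainty is not None and self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")
        if self.iron_mass_units not in _MASS_TO_PG:
            raise UnitError(f"unrecognized mass unit {self.iron_mass_units!r}")

    @property
    def iron_mass_pg(self) -> float:
        return self.iron_mass * _MASS_TO_PG[self.iron_mass_units]


def magnetite_mass_per_particle(spec: ParticleSpec) -> float:
    """Magnetite mass in one superparticle core, in kg.

    (π/6)·d_core³ · packing_fraction · ρ_magnetite — the sphere volume of
    the core times the fraction actually filled with magnetite.
    """
    d_m = spec.core_diameter_nm * M_PER_NM
    rho_kg_m3 = spec.magnetite_density_g_cm3 * 1e3
    return (math.pi / 6.0) * d_m**3 * spec.packing_fraction * rho_kg_m3


def iron_mass_per_particle(spec: ParticleSpec) -> float:
    """Elemental-iron mass carried by one superparticle, in pg.

    Multiplies the magnetite mass of the core by the Fe mass fraction of
    magnetite. With the default 56.60 nm core, 0.62 packing and 5.18 g/cm³
    this evaluates to ≈2.21e-4 pg.
    """
    return magnetite_mass_per_particle(spec) * spec.fe_mass_fraction_of_magnetite * PG_PER_KG


def particle_count_from_iron(total_iron_pg: float, per_particle_iron_pg: float) -> float:
    """Number of particles implied by a total elemental-iron mass.

    Both masses in pg. Returns a real number (counts at the 1e10 scale are
    never meaningfully integral).
    """
    if per_particle_iron_pg <= 0:
        raise ZeroDivisionError(
            f"per-particle iron mass must be > 0, got {per_particle_iron_pg}")
    if total_iron_pg < 0:
        raise ValueError(f"total iron mass must be >= 0, got {total_iron_pg}")
    return total_iron_pg / per_particle_iron_pg


_CSV_COLUMNS = ["subject_id", "compartment", "time_days", "iron_mass",
                "iron_mass_units", "uncertainty"]


def read_iron_measurements(path: str | Path) -> list[IronMassMeasurement]:
    """Read an iron-measurement table (CSV with the canonical header)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        unc = getattr(row, "uncertainty", None)
        if unc is not None and pd.isna(unc):
            unc = None
        out.append(IronMassMeasurement(
            subject_id=str(row.subject_id),
            compartment=str(row.compartment),
            time_days=float(row.time_days),
            iron_mass=float(row.iron_mass),
            iron_mass_units=str(row.iron_mass_units),
            uncertainty=None if unc is None else float(unc),
        ))
    return out


def write_iron_measurements(measurements: Iterable[IronMassMeasurement],
                            path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.subject_id, m.compartment, m.time_days, m.iron_mass,
          m.iron_mass_units, m.uncertainty) for m in measurements],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)
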