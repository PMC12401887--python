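"""Core domain types for leaf–air temperature coupling analysis.

The central object is a :class:`PairedSeries`: one plant's minute-resolution
leaf and canopy-air thermocouple record under one temperature treatment.
Timestamps are local clock times (minutes since midnight); the analysis is
clock-time based, so no timezone or date arithmetic is performed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Sanity bounds for any thermocouple reading (°C). Glasshouse data far
#: outside this range indicate a logger or parsing fault, not a leaf.
TEMP_BOUNDS = (-20.0, 70.0)


class Treatment(str, enum.Enum):
    """Glasshouse temperature treatment."""

    BENIGN = "benign"
    HIGH = "high"


class Biome(str, enum.Enum):
    """Biome of origin of a species."""

    ALPINE = "alpine"
    TEMPERATE = "temperate"
    DESERT = "desert"


class ThermoClass(str, enum.Enum):
    """Thermoregulatory class inferred from coupling strength β.

    β ≈ 1 means the leaf tracks air temperature (poikilothermy); β < 1 means
    leaf excursions are damped relative to air (limited homeothermy); β > 1
    means the leaf amplifies air-temperature variation (megathermy).
    """

    POIKILOTHERM = "poikilotherm"
    LIMITED_HOMEOTHERM = "limited_homeotherm"
    MEGATHERM = "megatherm"


class FormatError(ValueError):
    """A file does not conform to the documented CSV layout."""


class EmptyInputError(ValueError):
    """An operation received no usable data."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class DomainError(ValueError):
    """A numeric argument is outside its physical domain."""


def parse_clock(value) -> float:
    """Parse a clock time to minutes since midnight.

    Accepts ``HH:MM``, ``HH:MM:SS``, ISO-8601 datetimes (date part ignored),
    or a bare number of minutes.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if not math.isfinite(float(value)):
            raise FormatError(f"non-finite clock value: {value!r}")
        return float(value)
    s = str(value).strip()
    if not s:
        raise FormatError("empty timestamp")
    # ISO-8601 with a date part: keep the time of day only.
    if "T" in s or (" " in s and "-" in s.split(" ")[0]):
        s = s.replace("T", " ").split(" ", 1)[1]
    parts = s.split(":")
    if len(parts) not in (2, 3):
        raise FormatError(f"unparseable timestamp: {value!r}")
    try:
        h, m = int(parts[0]), int(parts[1])
        sec = float(parts[2]) if len(parts) == 3 else 0.0
    except ValueError as exc:
        raise FormatError(f"unparseable timestamp: {value!r}") from exc
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= sec < 60):
        raise FormatError(f"clock fields out of range: {value!r}")
    return h * 60.0 + m + sec / 60.0


def format_clock(minutes: float) -> str:
    """Format minutes since midnight as ``HH:MM`` (whole minutes only)."""
    total = int(round(minutes))
    return f"{total // 60:02d}:{total % 60:02d}"


@dataclass(eq=False)
class PairedSeries:
    """Aligned 1-min (T_leaf, T_air) record for one plant × treatment.

    Invariants: strictly increasing timestamps, equal channel lengths, and
    all temperatures finite within :data:`TEMP_BOUNDS`. A zero-length series
    is permitted (it is the result of filtering everything out) and carries
    a warning at the operation that produced it.
    """

    plant_id: str
    treatment: Treatment
    minutes: np.ndarray
    t_leaf: np.ndarray
    t_air: np.ndarray

    def __post_init__(self) -> None:
        self.treatment = Treatment(self.treatment)
        self.minutes = np.asarray(self.minutes, dtype=np.float64)
        self.t_leaf = np.asarray(self.t_leaf, dtype=np.float64)
        self.t_air = np.asarray(self.t_air, dtype=np.float64)
        n = self.minutes.size
        if self.t_leaf.size != n or self.t_air.size != n:
            raise ValidationError(
                f"{self.plant_id}: channel lengths differ "
                f"({n}, {self.t_leaf.size}, {self.t_air.size})"
            )
        if n > 1 and not np.all(np.diff(self.minutes) > 0):
            raise ValidationError(f"{self.plant_id}: timestamps not strictly increasing")
        for name, arr in (("t_leaf", self.t_leaf), ("t_air", self.t_air)):
            if n and not np.all(np.isfinite(arr)):
                raise ValidationError(f"{self.plant_id}: non-finite {name} values")
            if n and (arr.min() < TEMP_BOUNDS[0] or arr.max() > TEMP_BOUNDS[1]):
                raise ValidationError(
                    f"{self.plant_id}: {name} outside sanity bounds {TEMP_BOUNDS}"
                )

    def __len__(self) -> int:
        return int(self.minutes.size)

    @property
    def timestamps(self) -> list[str]:
        return [format_clock(m) for m in self.minutes]

    def select(self, mask: np.ndarray) -> "PairedSeries":
        """Row-filter both channels together, preserving order."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            minutes=self.minutes[mask],
            t_leaf=self.t_leaf[mask],
            t_air=self.t_air[mask],
        )

    def equals(self, other: "PairedSeries") -> bool:
        return (
            self.plant_id == other.plant_id
            and self.treatment == other.treatment
            and np.array_equal(self.minutes, other.minutes)
            and np.array_equal(self.t_leaf, other.t_leaf)
            and np.array_equal(self.t_air, other.t_air)
        )


@dataclass(frozen=True)
class PlantMeta:
    """Design metadata for one plant."""

    plant_id: str
    species: str
    biome: Biome
    family: str
    growth_form: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "biome", Biome(self.biome))


@dataclass
class LeafTraits:
    """Raw single-leaf measurements plus derived structural traits.

    Raw: wet/dry mass (mg), projected area (cm²), thickness and width (mm),
    and stomatal conductance g_sw (mol m⁻² s⁻¹, may be missing). Derived
    (filled by :func:`thermoreg.traits.derive_traits`): leaf water content
    LWC = (wet−dry)/wet, dry matter content LDMC = dry/wet, mass per area
    LMA (kg m⁻²) and tissue density LD (g cm⁻³).
    """

    plant_id: str
    wet_mass_mg: float
    dry_mass_mg: float
    area_cm2: float
    thickness_mm: float
    width_mm: float
    gsw_mol_m2_s: Optional[float] = None
    lwc: Optional[float] = None
    ld_g_cm3: Optional[float] = None
    lma_kg_m2: Optional[float] = None
    ldmc: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("wet_mass_mg", "dry_mass_mg", "area_cm2", "thickness_mm", "width_mm"):
            v = getattr(self, name)
            if v is None or not math.isfinite(float(v)) or float(v) <= 0:
                raise ValidationError(f"{self.plant_id}: {name} must be positive, got {v!r}")
        if self.dry_mass_mg > self.wet_mass_mg:
            raise ValidationError(
                f"{self.plant_id}: dry mass {self.dry_mass_mg} mg exceeds "
                f"wet mass {self.wet_mass_mg} mg"
            )
        if self.gsw_mol_m2_s is not None and (
            not math.isfinite(float(self.gsw_mol_m2_s)) or self.gsw_mol_m2_s < 0
        ):
            raise ValidationError(f"{self.plant_id}: invalid gsw {self.gsw_mol_m2_s!r}")

    @property
    def has_gsw(self) -> bool:
        return self.gsw_mol_m2_s is not None


@dataclass(frozen=True)
class WindowSlope:
    """OLS slope of T_leaf on T_air within one 30-min window."""

    start_minute: float
    slope: float
    n_points: int
    r2: float
    retained: bool = True
    note: str = ""


@dataclass
class CouplingMetrics:
    """Per-plant thermal-coupling summary."""

    plant_id: str
    treatment: Treatment
    delta_t_mean: float
    delta_t_series: np.ndarray
    window_slopes: list[WindowSlope]
    beta: float
    thermo_class: ThermoClass

    @property
    def n_windows(self) -> int:
        return sum(1 for w in self.window_slopes if w.retained)


@dataclass(frozen=True)
class TrimReport:
    """Row counts through the preprocessing stages for one series."""

    plant_id: str
    treatment: Treatment
    n_input: int
    n_after_window: int
    n_after_threshold: int

    def __post_init__(self) -> None:
        if not (self.n_input >= self.n_after_window >= self.n_after_threshold >= 0):
            raise ValidationError("trim counts must be non-increasing")

    @property
    def fraction_trimmed_by_threshold(self) -> float:
        if self.n_after_window == 0:
            return 0.0
        return 1.0 - self.n_after_threshold / self.n_after_window


@dataclass(frozen=True)
class TauParams:
    """Parameters of the leaf thermal time constant.

    phi is the projected-to-total leaf area ratio; cp_w and cp_d the specific
    heat capacities of water and dry matter (J kg⁻¹ K⁻¹); u the wind speed
    (m s⁻¹); a_h the single coefficient of the laminar flat-plate forced
    convection correlation h = a_h·sqrt(u/width).
    """

    phi: float = 0.5
    cp_w: float = 4181.0
    cp_d: float = 2814.0
    u: float = 1.0
    a_h: float = 3.87

    def __post_init__(self) -> None:
        for name in ("phi", "cp_w", "cp_d", "u", "a_h"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.phi > 1:
            raise DomainError("phi must lie in (0, 1]")
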