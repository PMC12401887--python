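"""Synthetic glasshouse experiment generator.

Emulates the study design the analysis pipeline expects: 15 Australian
native species (5 per biome of origin), 5 replicate plants each, measured
under a benign (25 °C setpoint) and a high-temperature (38 °C setpoint)
treatment with paired 1-min leaf/air thermocouple records from 12:00 to
15:00, a metadata table, and a single-leaf trait table.

Generating model per plant × treatment:

* Air: canopy-level mean below the room setpoint (benign 23.2 °C, high
  35.7 °C) plus an AR(1) fluctuation, interrupted by stochastic
  evaporative-cooler dips (episodic drops ~9 °C deep) calibrated so that
  roughly 10 % of minutes fall below the treatment's trim threshold.
* Leaf: linear coupling t_leaf = pivot + δ + β_g·(t_air − pivot) + ε with
  iid Gaussian noise. The pivot is the mean of the air minutes retained by
  the measurement protocol (12:30–15:00 clock window, above-threshold), so
  the generating δ is exactly the protocol-level thermal offset and β_g
  exactly the generating slope.
* Offsets: within each biome×treatment cohort of 25 plants, per-plant δ
  are Normal draws standardized to the cohort's preset mean and sd, so the
  generated cohort reproduces the preset statistics exactly as observed
  statistics. Per-plant slopes are iid Normal draws.
* Traits: log-normal biome clusters (alpine: thick, less dense, wet,
  high-g_sw leaves; temperate: thin, dense, dry, low-g_sw, wide size range;
  desert: small, narrow leaves); g_sw is missing for a configurable number
  of plants (default 18 of 75).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as treg_io
from .preprocess import TRIM_THRESHOLDS_C, WINDOW_END, WINDOW_START
from .types import Biome, LeafTraits, PairedSeries, PlantMeta, Treatment, parse_clock

#: Study design table: (species, biome, family, growth form).
SPECIES_DESIGN = (
    ("Eucalyptus pauciflora", Biome.ALPINE, "Myrtaceae", "Tree"),
    ("Leptorhynchos squamatus", Biome.ALPINE, "Asteraceae", "Forb"),
    ("Oxylobium ellipticum", Biome.ALPINE, "Fabaceae", "Shrub"),
    ("Ranunculus graniticola", Biome.ALPINE, "Ranunculaceae", "Forb"),
    ("Xerochrysum subundulatum", Biome.ALPINE, "Asteraceae", "Forb"),
    ("Acacia binervata", Biome.TEMPERATE, "Fabaceae", "Tree-shrub"),
    ("Acacia longifolia", Biome.TEMPERATE, "Fabaceae", "Tree-shrub"),
    ("Backhousia myrtifolia", Biome.TEMPERATE, "Myrtaceae", "Tree"),
    ("Melaleuca hypericifolia", Biome.TEMPERATE, "Myrtaceae", "Tree-shrub"),
    ("Pittosporum undulatum", Biome.TEMPERATE, "Pittosporaceae", "Tree-shrub"),
    ("Acacia aneura", Biome.DESERT, "Fabaceae", "Tree-shrub"),
    ("Acacia salicina", Biome.DESERT, "Fabaceae", "Tree-shrub"),
    ("Dodonaea viscosa", Biome.DESERT, "Sapindaceae", "Shrub"),
    ("Eucalyptus largiflorens", Biome.DESERT, "Myrtaceae", "Tree"),
    ("Flindersia maculosa", Biome.DESERT, "Rutaceae", "Tree"),
)

#: Observed biome×treatment thermal-offset statistics (mean, sd in °C)
#: used as the generating cohort presets.
OFFSET_PRESETS_C = {
    (Biome.TEMPERATE, Treatment.BENIGN): (1.99, 1.30),
    (Biome.TEMPERATE, Treatment.HIGH): (0.60, 0.91),
    (Biome.ALPINE, Treatment.BENIGN): (0.63, 1.01),
    (Biome.ALPINE, Treatment.HIGH): (-1.25, 0.77),
    (Biome.DESERT, Treatment.BENIGN): (0.50, 1.05),
    (Biome.DESERT, Treatment.HIGH): (-1.66, 0.92),
}

#: Generating coupling slopes (mean, sd). Benign cohorts sit below 1
#: (limited homeothermy); at high temperature, temperate cohorts exceed 1
#: while alpine and desert track air. These directions follow the study's
#: qualitative pattern; the numeric values are the generator's defaults.
SLOPE_PRESETS = {
    (Biome.TEMPERATE, Treatment.BENIGN): (0.85, 0.10),
    (Biome.ALPINE, Treatment.BENIGN): (0.85, 0.10),
    (Biome.DESERT, Treatment.BENIGN): (0.85, 0.10),
    (Biome.TEMPERATE, Treatment.HIGH): (1.10, 0.10),
    (Biome.ALPINE, Treatment.HIGH): (1.00, 0.10),
    (Biome.DESERT, Treatment.HIGH): (1.00, 0.10),
}

#: Biome trait clusters: log-normal (median, sigma of log) for size and
#: density traits, Normal (mean, sd) for LWC. Invented defaults shaped by
#: the qualitative biome contrasts described above.
TRAIT_CLUSTERS = {
    Biome.ALPINE: dict(
        area_cm2=(10.0, 0.45),
        width_mm=(15.0, 0.30),
        thickness_mm=(0.50, 0.25),
        ld_g_cm3=(0.25, 0.20),
        lwc=(0.65, 0.05),
        gsw_mol_m2_s=(0.35, 0.40),
    ),
    Biome.TEMPERATE: dict(
        area_cm2=(12.0, 0.80),
        width_mm=(20.0, 0.60),
        thickness_mm=(0.25, 0.20),
        ld_g_cm3=(0.45, 0.20),
        lwc=(0.45, 0.05),
        gsw_mol_m2_s=(0.12, 0.40),
    ),
    Biome.DESERT: dict(
        area_cm2=(3.5, 0.50),
        width_mm=(6.0, 0.40),
        thickness_mm=(0.35, 0.25),
        ld_g_cm3=(0.40, 0.25),
        lwc=(0.55, 0.06),
        gsw_mol_m2_s=(0.25, 0.50),
    ),
}


@dataclass
class AirProfileConfig:
    """Canopy air-temperature model for one treatment."""

    canopy_mean_c: float
    ar_coef: float = 0.9
    innovation_sd_c: float = 0.3
    dip_start_prob: float = 0.02  # per-minute chance a cooler episode begins
    dip_mean_duration_min: float = 5.0
    dip_depth_mean_c: float = 9.0
    dip_depth_sd_c: float = 1.0


@dataclass
class SyntheticConfig:
    """Full design and generating parameters of a synthetic experiment."""

    n_species_per_biome: int = 5
    n_reps: int = 5
    biomes: tuple[Biome, ...] = (Biome.ALPINE, Biome.TEMPERATE, Biome.DESERT)
    minutes: int = 180
    start_clock: str = "12:00"
    noise_sd_c: float = 0.3
    n_missing_gsw: int = 18
    offset_presets: dict = field(default_factory=lambda: dict(OFFSET_PRESETS_C))
    slope_presets: dict = field(default_factory=lambda: dict(SLOPE_PRESETS))
    trait_clusters: dict = field(default_factory=lambda: copy.deepcopy(TRAIT_CLUSTERS))
    air: dict = field(
        default_factory=lambda: {
            Treatment.BENIGN: AirProfileConfig(canopy_mean_c=23.2),
            Treatment.HIGH: AirProfileConfig(canopy_mean_c=35.7),
        }
    )

    def __post_init__(self) -> None:
        if self.n_species_per_biome <= 0 or self.n_reps <= 0 or self.minutes <= 0:
            raise ValueError("design counts must be positive")
        for key, (_, sd) in self.offset_presets.items():
            if sd < 0:
                raise ValueError(f"offset sd for {key} must be ≥ 0")
        for key, (_, sd) in self.slope_presets.items():
            if sd < 0:
                raise ValueError(f"slope sd for {key} must be ≥ 0")


DEFAULT_CONFIG = SyntheticConfig()


def generate_air_profile(
    treatment: Treatment,
    minutes: int = 180,
    config: SyntheticConfig | None = None,
    seed=None,
    start_minute: float | None = None,
) -> np.ndarray:
    """One treatment's canopy air series: AR(1) around the canopy mean plus dips."""
    cfg = config or DEFAULT_CONFIG
    air = cfg.air[Treatment(treatment)]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # AR(1) fluctuation initialized at its stationary distribution.
    stat_sd = air.innovation_sd_c / np.sqrt(1.0 - air.ar_coef**2)
    f = np.empty(minutes)
    f[0] = rng.normal(0.0, stat_sd)
    innov = rng.normal(0.0, air.innovation_sd_c, size=minutes - 1)
    for t in range(1, minutes):
        f[t] = air.ar_coef * f[t - 1] + innov[t - 1]
    # Episodic cooler dips: geometric durations, Normal depths.
    dip = np.zeros(minutes)
    t = 0
    while t < minutes:
        if air.dip_start_prob > 0 and rng.random() < air.dip_start_prob:
            dur = int(rng.geometric(1.0 / air.dip_mean_duration_min))
            depth = max(rng.normal(air.dip_depth_mean_c, air.dip_depth_sd_c), 0.0)
            dip[t : t + dur] = depth
            t += dur
        else:
            t += 1
    return air.canopy_mean_c + f - dip


def generate_leaf_series(
    t_air: np.ndarray,
    offset: float,
    slope: float,
    noise_sd: float,
    seed=None,
    pivot: float | None = None,
) -> np.ndarray:
    """Leaf channel from the linear coupling model.

    t_leaf(t) = pivot + offset + slope·(t_air(t) − pivot) + ε(t), with ε iid
    N(0, noise_sd²) and the pivot defaulting to mean(t_air). Relative to the
    pivot baseline the generating thermal offset is exactly ``offset`` and
    the generating coupling slope exactly ``slope``.
    """
    t_air = np.asarray(t_air, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pv = float(np.mean(t_air)) if pivot is None else float(pivot)
    noise = rng.normal(0.0, noise_sd, size=t_air.size) if noise_sd > 0 else 0.0
    return pv + offset + slope * (t_air - pv) + noise


def _matched_normal(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Normal draws standardized to have exactly the given sample mean and sd."""
    x = rng.normal(0.0, 1.0, size=n)
    if n == 1 or sd == 0:
        return np.full(n, mean)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def _protocol_pivot(minutes: np.ndarray, t_air: np.ndarray, treatment: Treatment) -> float:
    """Mean air temperature over protocol-retained minutes (window + threshold)."""
    lo, hi = parse_clock(WINDOW_START), parse_clock(WINDOW_END)
    mask = (minutes >= lo) & (minutes <= hi) & (t_air > TRIM_THRESHOLDS_C[treatment])
    if not mask.any():  # degenerate config; fall back to the plain mean
        return float(t_air.mean())
    return float(t_air[mask].mean())


@dataclass
class Experiment:
    """A fully generated synthetic experiment."""

    config: SyntheticConfig
    seed: int
    meta: list[PlantMeta]
    traits: list[LeafTraits]
    series: dict[tuple[str, Treatment], PairedSeries]
    true_params: pd.DataFrame  # per plant×treatment generating δ and β

    def write(self, out_dir) -> Path:
        """Write the three-table layout read by the io module."""
        out = Path(out_dir)
        (out / "loggers").mkdir(parents=True, exist_ok=True)
        treg_io.write_metadata_csv(self.meta, out / "metadata.csv")
        treg_io.write_traits_csv(self.traits, out / "traits.csv")
        for (pid, trt), s in sorted(self.series.items()):
            treg_io.write_logger_csv(s, out / "loggers" / f"{pid}_{trt.value}.csv")
        self.true_params.to_csv(out / "true_params.csv", index=False)
        return out


def _species_for(config: SyntheticConfig) -> list[tuple[str, Biome, str, str]]:
    """First n species per biome from the design table (cycled if n > 5)."""
    by_biome: dict[Biome, list] = {b: [] for b in Biome}
    for row in SPECIES_DESIGN:
        by_biome[row[1]].append(row)
    out = []
    for biome in config.biomes:
        pool = by_biome[Biome(biome)]
        if not pool:
            continue
        for i in range(config.n_species_per_biome):
            sp, b, fam, gf = pool[i % len(pool)]
            out.append((sp if i < len(pool) else f"{sp} {i // len(pool) + 1}", b, fam, gf))
    return out


def generate_experiment(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> Experiment:
    """Generate metadata, traits, and paired logger series for every plant.

    Deterministic given (config, seed). If ``out_dir`` is given the CSV
    layout is also written there.
    """
    cfg = config or SyntheticConfig()
    root = np.random.default_rng(seed)
    rng_air, rng_leaf, rng_offsets, rng_slopes, rng_traits, rng_missing = root.spawn(6)

    species = _species_for(cfg)
    meta: list[PlantMeta] = []
    for sp, biome, family, growth_form in species:
        code = "".join(w[:3].upper() for w in sp.split()[:2])
        for rep in range(1, cfg.n_reps + 1):
            meta.append(
                PlantMeta(
                    plant_id=f"{code}-{rep}",
                    species=sp,
                    biome=biome,
                    family=family,
                    growth_form=growth_form,
                )
            )

    # Cohort offsets and per-plant slopes.
    by_cohort: dict[tuple[Biome, Treatment], list[str]] = {}
    for m in meta:
        for trt in (Treatment.BENIGN, Treatment.HIGH):
            by_cohort.setdefault((m.biome, trt), []).append(m.plant_id)
    offsets: dict[tuple[str, Treatment], float] = {}
    slopes: dict[tuple[str, Treatment], float] = {}
    for (biome, trt), pids in sorted(by_cohort.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)):
        om, osd = cfg.offset_presets[(biome, trt)]
        sm, ssd = cfg.slope_presets[(biome, trt)]
        deltas = _matched_normal(rng_offsets, len(pids), om, osd)
        bslopes = rng_slopes.normal(sm, ssd, size=len(pids))
        for pid, d, b in zip(pids, deltas, bslopes):
            offsets[(pid, trt)] = float(d)
            slopes[(pid, trt)] = float(b)

    start_min = parse_clock(cfg.start_clock)
    minutes = start_min + np.arange(cfg.minutes, dtype=float)
    series: dict[tuple[str, Treatment], PairedSeries] = {}
    rows = []
    for m in meta:
        for trt in (Treatment.BENIGN, Treatment.HIGH):
            t_air = generate_air_profile(trt, cfg.minutes, cfg, seed=rng_air)
            pivot = _protocol_pivot(minutes, t_air, trt)
            t_leaf = generate_leaf_series(
                t_air,
                offsets[(m.plant_id, trt)],
                slopes[(m.plant_id, trt)],
                cfg.noise_sd_c,
                seed=rng_leaf,
                pivot=pivot,
            )
            series[(m.plant_id, trt)] = PairedSeries(
                plant_id=m.plant_id,
                treatment=trt,
                minutes=minutes,
                t_leaf=np.round(t_leaf, 3),
                t_air=np.round(t_air, 3),
            )
            rows.append(
                {
                    "plant_id": m.plant_id,
                    "treatment": trt.value,
                    "biome": m.biome.value,
                    "true_offset_c": offsets[(m.plant_id, trt)],
                    "true_slope": slopes[(m.plant_id, trt)],
                }
            )

    # Traits: one measured leaf per plant, biome-clustered distributions.
    traits: list[LeafTraits] = []
    n_plants = len(meta)
    n_missing = min(cfg.n_missing_gsw, n_plants)
    missing_ids = set(
        np.array([m.plant_id for m in meta])[
            rng_missing.choice(n_plants, size=n_missing, replace=False)
        ]
    )
    for m in meta:
        cl = cfg.trait_clusters[m.biome]
        area = float(rng_traits.lognormal(np.log(cl["area_cm2"][0]), cl["area_cm2"][1]))
        width = float(rng_traits.lognormal(np.log(cl["width_mm"][0]), cl["width_mm"][1]))
        thick = float(rng_traits.lognormal(np.log(cl["thickness_mm"][0]), cl["thickness_mm"][1]))
        ld = float(rng_traits.lognormal(np.log(cl["ld_g_cm3"][0]), cl["ld_g_cm3"][1]))
        lwc = float(np.clip(rng_traits.normal(*cl["lwc"]), 0.15, 0.90))
        gsw = float(rng_traits.lognormal(np.log(cl["gsw_mol_m2_s"][0]), cl["gsw_mol_m2_s"][1]))
        dry_mg = ld * area * (thick / 10.0) * 1000.0  # g cm⁻³ × cm³ → g → mg
        wet_mg = dry_mg / (1.0 - lwc)
        traits.append(
            LeafTraits(
                plant_id=m.plant_id,
                wet_mass_mg=round(wet_mg, 2),
                dry_mass_mg=round(dry_mg, 2),
                area_cm2=round(area, 3),
                thickness_mm=round(thick, 3),
                width_mm=round(width, 3),
                gsw_mol_m2_s=None if m.plant_id in missing_ids else round(gsw, 4),
            )
        )

    exp = Experiment(
        config=cfg,
        seed=seed,
        meta=meta,
        traits=traits,
        series=series,
        true_params=pd.DataFrame(rows),
    )
    if out_dir is not None:
        exp.write(out_dir)
    return exp
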