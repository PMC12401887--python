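"""Readers and writers for logger series, metadata and trait tables.

Conventions: comma-separated UTF-8 CSV with a header row and "." decimal
mark. Logger files carry ``timestamp,t_leaf_c,t_air_c`` with ``HH:MM`` or
ISO-8601 timestamps. Missing g_sw is an empty field, never 0.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    Biome,
    EmptyInputError,
    FormatError,
    LeafTraits,
    PairedSeries,
    PlantMeta,
    TEMP_BOUNDS,
    Treatment,
    ValidationError,
    format_clock,
    parse_clock,
)

log = logging.getLogger(__name__)

LOGGER_COLUMNS = ("timestamp", "t_leaf_c", "t_air_c")
META_COLUMNS = ("plant_id", "species", "biome", "family", "growth_form")
TRAIT_COLUMNS = (
    "plant_id",
    "wet_mass_mg",
    "dry_mass_mg",
    "area_cm2",
    "thickness_mm",
    "width_mm",
    "gsw_mol_m2_s",
)


def _infer_identity(path: Path) -> tuple[str, Treatment]:
    """Infer (plant_id, treatment) from a ``<plant>_<treatment>.csv`` stem."""
    stem = path.stem
    if "_" in stem:
        pid, _, suffix = stem.rpartition("_")
        try:
            return pid, Treatment(suffix)
        except ValueError:
            pass
    raise FormatError(
        f"cannot infer plant id / treatment from filename {path.name!r}; "
        "pass plant_id= and treatment= explicitly"
    )


def read_logger_csv(
    path,
    plant_id: Optional[str] = None,
    treatment: Optional[Treatment] = None,
) -> PairedSeries:
    """Read one paired-thermocouple logger export.

    Rows with unparseable timestamps, non-numeric temperatures, or readings
    outside the sanity bounds are rejected; the count of rejected rows is
    logged, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LOGGER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: no data rows")
    if plant_id is None or treatment is None:
        pid, trt = _infer_identity(path)
        plant_id = plant_id or pid
        treatment = treatment or trt

    minutes, t_leaf, t_air = [], [], []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            m = parse_clock(getattr(row, "timestamp"))
            lf = float(getattr(row, "t_leaf_c"))
            ar = float(getattr(row, "t_air_c"))
        except (FormatError, ValueError):
            n_rejected += 1
            continue
        if not (np.isfinite(lf) and np.isfinite(ar)):
            n_rejected += 1
            continue
        if not (TEMP_BOUNDS[0] <= lf <= TEMP_BOUNDS[1] and TEMP_BOUNDS[0] <= ar <= TEMP_BOUNDS[1]):
            n_rejected += 1
            continue
        minutes.append(m)
        t_leaf.append(lf)
        t_air.append(ar)
    if n_rejected:
        log.warning("%s: rejected %d malformed row(s)", path.name, n_rejected)
    if not minutes:
        raise EmptyInputError(f"{path.name}: no parseable rows ({n_rejected} rejected)")
    return PairedSeries(
        plant_id=plant_id,
        treatment=Treatment(treatment),
        minutes=np.array(minutes),
        t_leaf=np.array(t_leaf),
        t_air=np.array(t_air),
    )


def write_logger_csv(series: PairedSeries, path) -> Path:
    """Write a series back to the logger CSV layout (HH:MM timestamps)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "timestamp": [format_clock(m) for m in series.minutes],
            "t_leaf_c": series.t_leaf,
            "t_air_c": series.t_air,
        }
    )
    df.to_csv(path, index=False)
    return path


def _parse_meta_frame(df: pd.DataFrame) -> list[PlantMeta]:
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata table missing column(s) {missing}")
    ids = df["plant_id"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate plant_id in metadata: {dupes}")
    out = []
    for row in df.itertuples(index=False):
        try:
            biome = Biome(str(row.biome).strip().lower())
        except ValueError as exc:
            raise ValidationError(f"unknown biome label {row.biome!r} for {row.plant_id}") from exc
        out.append(
            PlantMeta(
                plant_id=str(row.plant_id),
                species=str(row.species),
                biome=biome,
                family=str(row.family),
                growth_form=str(row.growth_form),
            )
        )
    return out


def _parse_traits_frame(df: pd.DataFrame) -> list[LeafTraits]:
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trait table missing column(s) {missing}")
    ids = df["plant_id"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate plant_id in traits: {dupes}")
    out = []
    for row in df.itertuples(index=False):
        gsw = row.gsw_mol_m2_s
        gsw = None if (pd.isna(gsw) or str(gsw).strip() == "") else float(gsw)
        out.append(
            LeafTraits(
                plant_id=str(row.plant_id),
                wet_mass_mg=float(row.wet_mass_mg),
                dry_mass_mg=float(row.dry_mass_mg),
                area_cm2=float(row.area_cm2),
                thickness_mm=float(row.thickness_mm),
                width_mm=float(row.width_mm),
                gsw_mol_m2_s=gsw,
            )
        )
    return out


def read_tables(meta_path, traits_path) -> tuple[list[PlantMeta], list[LeafTraits]]:
    """Read and cross-validate the plant metadata and leaf-trait tables.

    Plants missing g_sw are retained (flagged via ``LeafTraits.has_gsw``).
    A metadata plant absent from the trait table is kept with a warning;
    a trait row without metadata is likewise warned about.
    """
    meta = _parse_meta_frame(pd.read_csv(meta_path))
    traits = _parse_traits_frame(pd.read_csv(traits_path))
    meta_ids = {m.plant_id for m in meta}
    trait_ids = {t.plant_id for t in traits}
    for pid in sorted(meta_ids - trait_ids):
        warnings.warn(f"plant {pid} has metadata but no trait record", stacklevel=2)
    for pid in sorted(trait_ids - meta_ids):
        warnings.warn(f"plant {pid} has traits but no metadata record", stacklevel=2)
    n_flagged = sum(1 for t in traits if not t.has_gsw)
    if n_flagged:
        log.info("%d of %d plants lack g_sw (retained, flagged)", n_flagged, len(traits))
    return meta, traits


def write_metadata_csv(meta: Sequence[PlantMeta], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "plant_id": m.plant_id,
                "species": m.species,
                "biome": m.biome.value,
                "family": m.family,
                "growth_form": m.growth_form,
            }
            for m in meta
        ]
    ).to_csv(path, index=False)
    return path


def traits_to_frame(traits: Sequence[LeafTraits], derived: bool = False) -> pd.DataFrame:
    rows = []
    for t in traits:
        row = {
            "plant_id": t.plant_id,
            "wet_mass_mg": t.wet_mass_mg,
            "dry_mass_mg": t.dry_mass_mg,
            "area_cm2": t.area_cm2,
            "thickness_mm": t.thickness_mm,
            "width_mm": t.width_mm,
            "gsw_mol_m2_s": np.nan if t.gsw_mol_m2_s is None else t.gsw_mol_m2_s,
        }
        if derived:
            row.update(lwc=t.lwc, ldmc=t.ldmc, lma_kg_m2=t.lma_kg_m2, ld_g_cm3=t.ld_g_cm3)
        rows.append(row)
    return pd.DataFrame(rows)


def write_traits_csv(traits: Sequence[LeafTraits], path, derived: bool = False) -> Path:
    path = Path(path)
    traits_to_frame(traits, derived=derived).to_csv(path, index=False)
    return path
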