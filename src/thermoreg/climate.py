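"""Long-term climate presets for the three biomes of origin.

Values are 1981–2010 climate normals for the seed-collection regions
(alpine: Kosciuszko National Park; coastal temperate: Wollongong; desert:
Bourke, all NSW, Australia): mean annual temperature (MAT), mean minimum of
the coldest month (MinT), mean maximum of the warmest month (MaxT), their
range, and mean annual precipitation (MAP). The printed alpine temperature
range (22.7 °C) does not equal MaxT − MinT (21.7 °C); the validator reports
this discrepancy rather than silently resolving it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import Biome


@dataclass(frozen=True)
class ClimatePreset:
    """Climate normals for one biome of origin."""

    biome: Biome
    mat_c: float
    min_t_c: float
    max_t_c: float
    t_range_c: float  # as printed in the source table
    map_mm: float

    def recomputed_t_range(self) -> float:
        return self.max_t_c - self.min_t_c

    def t_range_discrepancy(self) -> float:
        """Printed minus recomputed range; 0 when the table is internally consistent."""
        return self.t_range_c - self.recomputed_t_range()


_PRESETS = (
    ClimatePreset(Biome.ALPINE, mat_c=4.5, min_t_c=-5.2, max_t_c=16.5, t_range_c=22.7, map_mm=1764),
    ClimatePreset(Biome.TEMPERATE, mat_c=16.5, min_t_c=7.4, max_t_c=24.6, t_range_c=17.2, map_mm=1285),
    ClimatePreset(Biome.DESERT, mat_c=20.2, min_t_c=4.5, max_t_c=36.0, t_range_c=31.5, map_mm=332),
)


def climate_presets() -> dict[Biome, ClimatePreset]:
    """The three biome climate presets, keyed by biome."""
    return {p.biome: p for p in _PRESETS}


def validate_t_range(tolerance_c: float = 0.05) -> pd.DataFrame:
    """Recompute MaxT − MinT per biome and flag disagreement with the printed range."""
    rows = []
    for p in _PRESETS:
        rows.append(
            {
                "biome": p.biome.value,
                "t_range_printed_c": p.t_range_c,
                "t_range_recomputed_c": round(p.recomputed_t_range(), 10),
                "discrepancy_c": round(p.t_range_discrepancy(), 10),
                "consistent": abs(p.t_range_discrepancy()) <= tolerance_c,
            }
        )
    return pd.DataFrame(rows)
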