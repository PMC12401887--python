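"""Equilibration-window clipping and cooler-cycle threshold trimming.

The measurement protocol records 12:00–15:00 but analyses only 12:30–15:00,
treating the first half hour as thermal equilibration. Minutes logged while
the glasshouse evaporative coolers were active show a characteristic air
temperature drop; they are removed by trimming minute-pairs whose air
reading is at or below a treatment-specific threshold (16 °C benign,
31 °C high). Both filters act on aligned (T_leaf, T_air) pairs, so the
channels never drift out of registration, and both are idempotent,
order-independent row filters.
"""

from __future__ import annotations

import warnings

from .types import PairedSeries, Treatment, TrimReport, parse_clock

#: Default analysis window (inclusive on both ends).
WINDOW_START = "12:30"
WINDOW_END = "15:00"

#: Default air-temperature trim thresholds (°C); strictly-greater-than keeps.
TRIM_THRESHOLDS_C = {Treatment.BENIGN: 16.0, Treatment.HIGH: 31.0}


class EmptySeriesWarning(UserWarning):
    """All rows of a series were filtered out."""


def clip_to_window(
    series: PairedSeries,
    start_clock=WINDOW_START,
    end_clock=WINDOW_END,
) -> PairedSeries:
    """Keep only minutes with start ≤ timestamp ≤ end (clock time)."""
    start = parse_clock(start_clock)
    end = parse_clock(end_clock)
    if not start < end:
        raise ValueError(f"window start {start_clock!r} must precede end {end_clock!r}")
    out = series.select((series.minutes >= start) & (series.minutes <= end))
    if len(out) == 0:
        warnings.warn(
            f"{series.plant_id}/{series.treatment.value}: no rows inside "
            f"{start_clock}–{end_clock}",
            EmptySeriesWarning,
            stacklevel=2,
        )
    return out


def trim_by_air_threshold(
    series: PairedSeries,
    treatment: Treatment | None = None,
    thresholds_c: dict | None = None,
) -> tuple[PairedSeries, TrimReport]:
    """Drop minute-pairs whose T_air is at or below the treatment threshold.

    The threshold is applied to the air channel (the cooler-cycle artefact
    is an air-circulation effect); retention is strictly greater-than.
    """
    treatment = Treatment(treatment or series.treatment)
    thresholds = dict(TRIM_THRESHOLDS_C)
    if thresholds_c:
        thresholds.update({Treatment(k): float(v) for k, v in thresholds_c.items()})
    threshold = thresholds[treatment]
    out = series.select(series.t_air > threshold)
    report = TrimReport(
        plant_id=series.plant_id,
        treatment=treatment,
        n_input=len(series),
        n_after_window=len(series),
        n_after_threshold=len(out),
    )
    if len(out) == 0 and len(series) > 0:
        warnings.warn(
            f"{series.plant_id}/{treatment.value}: all rows at or below "
            f"{threshold} °C trimmed",
            EmptySeriesWarning,
            stacklevel=2,
        )
    return out, report


def preprocess_series(
    series: PairedSeries,
    start_clock=WINDOW_START,
    end_clock=WINDOW_END,
    thresholds_c: dict | None = None,
) -> tuple[PairedSeries, TrimReport]:
    """Clip to the analysis window, then trim cooler-cycle minutes.

    Returns the cleaned series and a staged row-count report.
    """
    clipped = clip_to_window(series, start_clock, end_clock)
    trimmed, _ = trim_by_air_threshold(clipped, series.treatment, thresholds_c)
    return trimmed, TrimReport(
        plant_id=series.plant_id,
        treatment=series.treatment,
        n_input=len(series),
        n_after_window=len(clipped),
        n_after_threshold=len(trimmed),
    )
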