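"""Thermal offset ΔT, windowed coupling slopes, β, and classification.

ΔT = T_leaf − T_air per retained minute; its mean summarises how much a
leaf sits above (positive) or below (negative) air temperature. Coupling
strength β is the mean of ordinary-least-squares slopes of T_leaf on T_air
computed within non-overlapping 30-min windows. β < 1 marks limited
homeothermy (damped leaf excursions), β ≈ 1 poikilothermy, β > 1 megathermy.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .types import (
    CouplingMetrics,
    EmptyInputError,
    PairedSeries,
    ThermoClass,
    WindowSlope,
    parse_clock,
)

log = logging.getLogger(__name__)

#: Default coupling-slope configuration.
WINDOW_MINUTES = 30
MIN_POINTS = 10
MIN_AIR_RANGE_C = 0.2
EPSILON = 0.1
DEFAULT_ANCHOR = "12:30"


class NoValidWindowsError(EmptyInputError):
    """No window met the retention criteria for this plant."""


def thermal_offset(series: PairedSeries) -> tuple[np.ndarray, float]:
    """Per-minute ΔT = T_leaf − T_air and its mean over retained minutes."""
    if len(series) == 0:
        raise EmptyInputError(f"{series.plant_id}: empty series, no ΔT")
    delta = series.t_leaf - series.t_air
    return delta, float(delta.mean())


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope of y on x and r², via centred sums (exact for collinear data)."""
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    syy = float(yc @ yc)
    r2 = 1.0 if syy == 0.0 else float(xc @ yc) ** 2 / (sxx * syy)
    return slope, r2


def coupling_slopes(
    series: PairedSeries,
    window_minutes: int = WINDOW_MINUTES,
    min_points: int = MIN_POINTS,
    min_air_range: float = MIN_AIR_RANGE_C,
    anchor=DEFAULT_ANCHOR,
) -> list[WindowSlope]:
    """OLS slope of T_leaf on T_air within each 30-min window.

    Windows partition the clock, left-anchored at the analysis-window start
    (minute m falls in window floor((m − anchor)/width)). Windows with too
    few points or a near-constant air regressor are returned flagged
    ``retained=False``; they are logged, never imputed. Raises
    :class:`NoValidWindowsError` if no window qualifies.
    """
    if len(series) == 0:
        raise EmptyInputError(f"{series.plant_id}: empty series, no slopes")
    anchor_min = parse_clock(anchor)
    idx = np.floor((series.minutes - anchor_min) / float(window_minutes)).astype(int)
    out: list[WindowSlope] = []
    for k in np.unique(idx):
        mask = idx == k
        x = series.t_air[mask]
        y = series.t_leaf[mask]
        start = anchor_min + k * window_minutes
        n = int(mask.sum())
        air_range = float(x.max() - x.min()) if n else 0.0
        if n < min_points:
            out.append(WindowSlope(start, math.nan, n, math.nan, False, "too few points"))
            continue
        if air_range < min_air_range:
            out.append(WindowSlope(start, math.nan, n, math.nan, False, "air range too small"))
            continue
        slope, r2 = _ols_slope(x, y)
        out.append(WindowSlope(start, slope, n, r2, True))
    n_skipped = sum(1 for w in out if not w.retained)
    if n_skipped:
        log.info("%s: %d window(s) skipped", series.plant_id, n_skipped)
    if not any(w.retained for w in out):
        raise NoValidWindowsError(
            f"{series.plant_id}/{series.treatment.value}: no window with "
            f"≥{min_points} points and air range ≥{min_air_range} °C"
        )
    return out


def beta(window_slopes: list[WindowSlope]) -> float:
    """β as the unweighted mean of retained window slopes."""
    retained = [w.slope for w in window_slopes if w.retained]
    if not retained:
        raise NoValidWindowsError("no retained windows to aggregate")
    return float(np.mean(retained))


def beta_pooled(series: PairedSeries) -> float:
    """Alternative β: one OLS slope over all retained minutes."""
    if len(series) < 2:
        raise EmptyInputError(f"{series.plant_id}: too few minutes for pooled β")
    slope, _ = _ols_slope(series.t_air, series.t_leaf)
    return slope


def classify_thermoregulation(beta_value: float, epsilon: float = EPSILON) -> ThermoClass:
    """Map β to a thermoregulatory class with tolerance ε around 1."""
    if not math.isfinite(beta_value):
        raise ValueError(f"non-finite β: {beta_value!r}")
    # Inclusive boundary, robust to 1-ulp float error at β = 1 ± ε.
    if abs(beta_value - 1.0) <= epsilon * (1.0 + 1e-9) + 1e-12:
        return ThermoClass.POIKILOTHERM
    if beta_value < 1.0 - epsilon:
        return ThermoClass.LIMITED_HOMEOTHERM
    return ThermoClass.MEGATHERM


def coupling_metrics(
    series: PairedSeries,
    window_minutes: int = WINDOW_MINUTES,
    min_points: int = MIN_POINTS,
    min_air_range: float = MIN_AIR_RANGE_C,
    epsilon: float = EPSILON,
    anchor=DEFAULT_ANCHOR,
    method: str = "window_mean",
) -> CouplingMetrics:
    """Full per-plant coupling summary from a preprocessed series.

    ``method`` selects the β aggregation: ``"window_mean"`` (default) or
    ``"pooled"`` (single regression over all retained minutes).
    """
    delta_series, delta_mean = thermal_offset(series)
    slopes = coupling_slopes(series, window_minutes, min_points, min_air_range, anchor)
    if method == "window_mean":
        b = beta(slopes)
    elif method == "pooled":
        b = beta_pooled(series)
    else:
        raise ValueError(f"unknown β method {method!r}")
    return CouplingMetrics(
        plant_id=series.plant_id,
        treatment=series.treatment,
        delta_t_mean=delta_mean,
        delta_t_series=delta_series,
        window_slopes=slopes,
        beta=b,
        thermo_class=classify_thermoregulation(b, epsilon),
    )
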