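"""Leaf thermal time constant, heat transfer coefficient, and psychrometrics.

The thermal time constant τ (s) is the characteristic response time of leaf
temperature to a step change in the environment: areal heat capacity over
the sensible heat transfer coefficient,

    τ = φ · LMA · [ c_p,w / (LDMC · h) + (c_p,d − c_p,w) / h ]
      = φ · LMA · C_mass / h,   C_mass = c_p,w/LDMC + c_p,d − c_p,w,

where C_mass (J kg⁻¹ K⁻¹, per dry mass) is the specific heat of the wet
leaf: a leaf of dry mass m_d carries water mass m_d·(1/LDMC − 1), so
C_mass = c_p,d + c_p,w·(1/LDMC − 1) — the same expression rearranged. φ is
the projected-to-total area ratio, applied once to the whole bracket.
Dimensionally, kg m⁻² · J kg⁻¹ K⁻¹ / (W m⁻² K⁻¹) = s.

h follows the laminar forced-convection flat-plate correlation collapsed to
a single coefficient, h = a_h·sqrt(u/w), with leaf width w as the
characteristic length. Small τ = fast-responding leaves; wetter (low-LDMC)
and wider leaves respond more slowly.
"""

from __future__ import annotations

import math

import numpy as np

from .types import DomainError, TauParams

DEFAULT_TAU_PARAMS = TauParams()


def heat_transfer_coefficient(width_m, params: TauParams = DEFAULT_TAU_PARAMS):
    """Sensible heat transfer coefficient h (W m⁻² K⁻¹) from leaf width (m).

    No free-convection fallback: zero wind or width is a domain error.
    """
    width = np.asarray(width_m, dtype=float)
    if np.any(width <= 0):
        raise DomainError("leaf width must be strictly positive")
    if params.u <= 0:
        raise DomainError("wind speed must be strictly positive")
    h = params.a_h * np.sqrt(params.u / width)
    return float(h) if np.isscalar(width_m) else h


def thermal_time_constant(
    lma_kg_m2,
    ldmc,
    width_m,
    params: TauParams = DEFAULT_TAU_PARAMS,
):
    """Leaf thermal time constant τ in seconds.

    ``lma_kg_m2`` is leaf dry mass per area (kg m⁻²), ``ldmc`` the dry
    matter content in (0, 1], ``width_m`` the leaf width in metres.
    """
    lma = np.asarray(lma_kg_m2, dtype=float)
    d = np.asarray(ldmc, dtype=float)
    if np.any(lma <= 0):
        raise DomainError("LMA must be strictly positive")
    if np.any((d <= 0) | (d > 1)):
        raise DomainError("LDMC must lie in (0, 1]")
    h = heat_transfer_coefficient(width_m, params)
    c_mass = params.cp_w / d + params.cp_d - params.cp_w
    tau = params.phi * lma * c_mass / h
    return float(tau) if np.ndim(tau) == 0 else tau


def saturation_vapour_pressure(t_air_c):
    """Tetens saturation vapour pressure e_s (kPa) over water."""
    t = np.asarray(t_air_c, dtype=float)
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(es) if np.ndim(es) == 0 else es


def vpd(t_air_c, rh_percent):
    """Vapour pressure deficit (kPa) from air temperature and RH (%)."""
    rh = np.asarray(rh_percent, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise DomainError("relative humidity must lie in [0, 100] %")
    out = saturation_vapour_pressure(t_air_c) * (1.0 - rh / 100.0)
    return float(out) if np.ndim(out) == 0 else out
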