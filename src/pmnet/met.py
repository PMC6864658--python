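"""Humidity thermodynamics: vapor pressure and dew point.

Optical particle counters over-read PM2.5 when hygroscopic particles swell
at high humidity, so the accuracy analysis needs dew point as a proxy for
absolute water content.  Saturation vapor pressure uses the base-10 Magnus
form

    es(T) = 6.11 * 10 ** (7.5 T / (237.3 + T))   [hPa, T in degC]

and the dew point is the corresponding inversion expressed directly in
vapor pressure,

    Td = (237.3 log10(VP) - 186.52) / (8.29 - log10(VP)).

The two conventions are chosen to be mutually consistent: the round trip
``dew_point(vapor_pressure(T, 100)) == T`` holds to better than 0.1 degC
over the meteorologically relevant range.  The logarithm is base 10; a
natural logarithm breaks the round trip by tens of degrees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MAGNUS_ES0_HPA = 6.11
MAGNUS_A = 7.5
MAGNUS_B = 237.3

__all__ = [
    "saturation_vapor_pressure",
    "vapor_pressure",
    "dew_point",
    "dew_point_from_met",
    "enrich_met",
]


def saturation_vapor_pressure(temp_c):
    """Saturation vapor pressure es(T) in hPa (base-10 Magnus form)."""
    t = np.asarray(temp_c, dtype=float)
    return MAGNUS_ES0_HPA * 10.0 ** (MAGNUS_A * t / (MAGNUS_B + t))


def vapor_pressure(temp_c, rh_pct):
    """Actual vapor pressure in hPa from temperature (degC) and RH (%).

    RH values <= 0 have no defined dew point and map to NaN.
    """
    rh = np.asarray(rh_pct, dtype=float)
    vp = np.where(rh > 0, rh / 100.0, np.nan) * saturation_vapor_pressure(temp_c)
    if vp.ndim == 0:
        return float(vp)
    return vp


def dew_point(vapor_pressure_hpa):
    """Dew point (degC) from vapor pressure (hPa).

    Nonpositive vapor pressures map to NaN (undefined dew point).  Vapor
    pressures at or beyond the pole of the inversion (log10 VP >= 8.29,
    i.e. far outside any atmospheric value) are a domain error.
    """
    vp = np.asarray(vapor_pressure_hpa, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        logvp = np.where(vp > 0, np.log10(np.where(vp > 0, vp, 1.0)), np.nan)
    if np.any(np.asarray(logvp >= 8.29)):
        raise ValueError("vapor pressure beyond the dew-point inversion domain")
    td = (MAGNUS_B * logvp - 186.52) / (8.29 - logvp)
    if td.ndim == 0:
        return float(td)
    return td


def dew_point_from_met(temp_c, rh_pct):
    """Dew point (degC) from temperature (degC) and relative humidity (%)."""
    return dew_point(vapor_pressure(temp_c, rh_pct))


def enrich_met(met: pd.DataFrame) -> pd.DataFrame:
    """Add derived ``vp_hpa`` and ``dew_point_c`` columns to a met table.

    Expects ``temp_c`` and ``rh_pct`` columns; returns a copy.
    """
    out = met.copy()
    out["vp_hpa"] = vapor_pressure(out["temp_c"].to_numpy(), out["rh_pct"].to_numpy())
    out["dew_point_c"] = dew_point(out["vp_hpa"].to_numpy())
    return out
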