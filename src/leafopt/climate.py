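"""Growing-season climate drivers from monthly site climate.

Converts monthly Tmax/Tmin, shortwave radiation (or PPFD) and specific
humidity into the drivers the optimality model needs: mean daytime
growth temperature Tg, growing-season PPFD, vapour pressure deficit D
and atmospheric pressure.

The diurnal temperature cycle is assumed sinusoidal with daylight hours
set by latitude and month:

    Tg = Tmax * {1/2 + sqrt(1-x^2) / (2 acos x)}
       + Tmin * {1/2 - sqrt(1-x^2) / (2 acos x)},   x = -tan(lat) tan(decl)

D follows Magnus-Tetens: es = 0.611 exp[17.27 T / (T + 237.3)] (kPa) at
T = (Tmin + Tmax)/2, and ea from specific humidity via the mass mixing
ratio Wair = q / (1 - q):  ea = Patm Wair Rv / (Rd + Wair Rv), with
Rd = R/Md, Rv = R/Mv (Md = 28.963, Mv = 18.02 g/mol).

The thermal growing season comprises months with mean daily temperature
(Tmin + Tmax)/2 above 0 degC.  All functions are pure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .theory import GAS_CONSTANT, P_SEALEVEL

__all__ = [
    "MOLAR_MASS_DRY_AIR",
    "MOLAR_MASS_WATER",
    "GrowingSeasonClimate",
    "NoGrowingSeasonError",
    "PolarNightError",
    "solar_declination",
    "daytime_temperature",
    "ppfd_from_shortwave",
    "patm_from_elevation",
    "saturation_vapour_pressure",
    "vpd",
    "growing_season_aggregate",
    "aggregate_sites",
]

MOLAR_MASS_DRY_AIR = 28.963e-3  # kg mol-1
MOLAR_MASS_WATER = 18.02e-3     # kg mol-1
R_DRY = GAS_CONSTANT / MOLAR_MASS_DRY_AIR    # specific gas constant, dry air
R_VAP = GAS_CONSTANT / MOLAR_MASS_WATER      # specific gas constant, vapour

_MID_MONTH_DOY = (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)


class NoGrowingSeasonError(ValueError):
    """No month has mean daily temperature above 0 degC."""


class PolarNightError(ValueError):
    """The sun does not rise in this month at this latitude."""


@dataclass(frozen=True)
class GrowingSeasonClimate:
    """Growing-season drivers for one site."""

    tg: float        # degC
    ppfd: float      # umol m-2 s-1
    d: float         # kPa
    patm: float      # Pa
    months_used: tuple


def solar_declination(month: int) -> float:
    """Monthly mean solar declination (radians), mid-month approximation.

    delta = -23.45 deg * cos(2 pi (doy + 10) / 365) at the mid-month day
    of year.
    """
    if not 1 <= int(month) <= 12 or month != int(month):
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    doy = _MID_MONTH_DOY[int(month) - 1]
    return math.radians(-23.45) * math.cos(2.0 * math.pi * (doy + 10) / 365.0)


def daytime_temperature(tmax: float, tmin: float, lat_rad: float,
                        decl_rad: float) -> float:
    """Mean daytime temperature from the sinusoidal diurnal cycle, degC.

    Weights Tmax by 1/2 + sqrt(1-x^2)/(2 acos x), x = -tan(lat) tan(decl);
    the result always lies between the diurnal mean and Tmax.  Polar day
    (x <= -1) takes the continuous limit (weight 1/2, i.e. the diurnal
    mean); polar night (x >= 1) raises :class:`PolarNightError`.
    """
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    x = -math.tan(lat_rad) * math.tan(decl_rad)
    if x >= 1.0:
        raise PolarNightError("sun below horizon all month (x >= 1)")
    if x <= -1.0:
        w = 0.5  # 24 h daylight: daytime mean == diurnal mean
    else:
        w = 0.5 + math.sqrt(1.0 - x * x) / (2.0 * math.acos(x))
    return tmax * w + tmin * (1.0 - w)


def ppfd_from_shortwave(sw_wm2, e2f: float = 2.04):
    """Convert shortwave radiation (W m-2) to PPFD (umol m-2 s-1)."""
    sw = np.asarray(sw_wm2, dtype=float)
    if np.any(sw < 0):
        raise ValueError("shortwave radiation must be >= 0")
    out = sw * e2f
    return float(out) if np.ndim(sw_wm2) == 0 else out


def patm_from_elevation(z) -> float:
    """Barometric formula (standard-atmosphere lapse form), Pa.

    P = P0 * (1 - L z / T0)^(g Md / (R L)) with L = 0.0065 K/m,
    T0 = 288.15 K, g = 9.80665 m/s2; P(0) = 101325 Pa.
    """
    zz = np.asarray(z, dtype=float)
    if np.any(zz < -500) or np.any(zz > 9000):
        raise ValueError("elevation outside [-500, 9000] m")
    expo = 9.80665 * MOLAR_MASS_DRY_AIR / (GAS_CONSTANT * 0.0065)
    out = P_SEALEVEL * (1.0 - 0.0065 * zz / 288.15) ** expo
    return float(out) if np.ndim(z) == 0 else out


def saturation_vapour_pressure(t_c) -> float:
    """Magnus-Tetens saturation vapour pressure, kPa."""
    t = np.asarray(t_c, dtype=float)
    out = 0.611 * np.exp(17.27 * t / (t + 237.3))
    return float(out) if np.ndim(t_c) == 0 else out


def vpd(tmax: float, tmin: float, q_air: float, patm: float) -> float:
    """Vapour pressure deficit D = es - ea, kPa (clamped at 0).

    es is evaluated at the diurnal mean temperature; ea from the specific
    humidity ``q_air`` (kg/kg) at pressure ``patm`` (Pa).  Supersaturated
    inputs (ea > es, possible with coarse humidity data) clamp to 0 with
    a warning.
    """
    if not 0.0 <= q_air < 1.0:
        raise ValueError("q_air must be in [0, 1)")
    if patm <= 0:
        raise ValueError("patm must be positive")
    t = 0.5 * (tmin + tmax)
    es = saturation_vapour_pressure(t)
    w_air = q_air / (1.0 - q_air)
    ea = patm * w_air * R_VAP / (R_DRY + w_air * R_VAP) / 1000.0  # kPa
    d = es - ea
    if d < 0:
        warnings.warn(f"negative VPD ({d:.4f} kPa) clamped to 0", stacklevel=2)
        return 0.0
    return d


def growing_season_aggregate(months: pd.DataFrame, lat_deg: float,
                             elevation_m: float,
                             d_floor_kpa: float = 0.01) -> GrowingSeasonClimate:
    """Aggregate 12 monthly rows into growing-season drivers for one site.

    ``months`` needs columns ``month, tmax_c, tmin_c, q_air`` and either
    ``sw_wm2`` or ``ppfd``.  Months with diurnal mean temperature above
    0 degC (and a rising sun) form the thermal growing season; Tg, PPFD
    and D are averaged over those months.  D is floored at
    ``d_floor_kpa`` so ln D stays finite downstream.
    """
    if len(months) != 12:
        raise ValueError(f"expected 12 monthly rows, got {len(months)}")
    lat = math.radians(lat_deg)
    patm = patm_from_elevation(elevation_m)

    used, tgs, ppfds, ds = [], [], [], []
    for row in months.sort_values("month").itertuples():
        if 0.5 * (row.tmax_c + row.tmin_c) <= 0.0:
            continue
        decl = solar_declination(int(row.month))
        try:
            tg_m = daytime_temperature(row.tmax_c, row.tmin_c, lat, decl)
        except PolarNightError:
            continue
        used.append(int(row.month))
        tgs.append(tg_m)
        ppfds.append(row.ppfd if hasattr(row, "ppfd")
                     else ppfd_from_shortwave(row.sw_wm2))
        ds.append(vpd(row.tmax_c, row.tmin_c, row.q_air, patm))
    if not used:
        raise NoGrowingSeasonError("no month with mean daily temperature > 0 degC")
    return GrowingSeasonClimate(
        tg=float(np.mean(tgs)), ppfd=float(np.mean(ppfds)),
        d=max(float(np.mean(ds)), d_floor_kpa), patm=patm,
        months_used=tuple(used))


def aggregate_sites(monthly: pd.DataFrame,
                    d_floor_kpa: float = 0.01) -> pd.DataFrame:
    """Growing-season drivers for many sites.

    ``monthly`` needs columns ``site_id, lat, elevation_m`` plus the
    per-month columns of :func:`growing_season_aggregate`.  Returns one
    row per site: ``site_id, tg_c, ppfd, d_kpa, patm_pa, n_months_used``.
    """
    rows = []
    for site_id, grp in monthly.groupby("site_id", sort=True):
        gs = growing_season_aggregate(
            grp, float(grp["lat"].iloc[0]), float(grp["elevation_m"].iloc[0]),
            d_floor_kpa=d_floor_kpa)
        rows.append({"site_id": site_id, "tg_c": gs.tg, "ppfd": gs.ppfd,
                     "d_kpa": gs.d, "patm_pa": gs.patm,
                     "n_months_used": len(gs.months_used)})
    return pd.DataFrame(rows)
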