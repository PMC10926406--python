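"""Bioclimatic predictors derived from 52-week climate normals.

The retained variable set covers annual means, extremes, seasonality and
quarter aggregates of temperature and solar radiation.  "Quarters" are the 52
circular consecutive 13-week windows — not calendar quarters — so the
derivation is hemisphere-neutral: the driest/wettest quarter minimises or
maximises summed rainfall and the coldest/warmest quarter minimises or
maximises mean temperature, ties resolved to the earliest window.

Seasonality variables are coefficients of variation (100 * sd / mean); the
temperature CV (BIO4) is computed in kelvin by default so the ratio is taken
on an absolute scale (``bio4_kelvin=False`` restores the Celsius reading).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import ClimateGrid, GridGeometry, N_WEEKS

QUARTER_WEEKS = 13
KELVIN_OFFSET = 273.15

#: derivation order; BIO2 and BIO5 are helpers for BIO3/BIO7
ALL_VARIABLES = (
    "BIO1", "BIO2", "BIO3", "BIO4", "BIO5", "BIO6", "BIO7",
    "BIO9", "BIO11", "BIO20", "BIO21", "BIO22", "BIO23", "BIO24", "BIO26",
)
#: the 13 retained predictors (helpers excluded)
RETAINED_VARIABLES = tuple(v for v in ALL_VARIABLES if v not in ("BIO2", "BIO5"))

__all__ = [
    "ALL_VARIABLES",
    "RETAINED_VARIABLES",
    "derive_bioclim",
    "extract_at_points",
]


def _window_means(arr: np.ndarray) -> np.ndarray:
    """Mean of every circular 13-week window; out[w] starts at week w."""
    ext = np.concatenate([arr, arr[: QUARTER_WEEKS - 1]], axis=0)
    csum = np.cumsum(ext, axis=0)
    zero = np.zeros_like(csum[:1])
    csum = np.concatenate([zero, csum], axis=0)
    return (csum[QUARTER_WEEKS:] - csum[:-QUARTER_WEEKS])[:N_WEEKS] / QUARTER_WEEKS


def _pick(window_vals: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """window_vals[idx] along axis 0 for per-cell window indices."""
    return np.take_along_axis(window_vals, idx[None, ...], axis=0)[0]


def _cv(arr: np.ndarray) -> np.ndarray:
    """100 * population sd / mean; 0 where the mean is 0."""
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean != 0, 100.0 * sd / mean, 0.0)
    return out


def derive_bioclim(climate: ClimateGrid, bio4_kelvin: bool = True) -> dict[str, np.ndarray]:
    """All bioclim variables as grids keyed by id (shape ``geom.shape``)."""
    grids = _derive_from_series(climate.tmin, climate.tmax, climate.rain, climate.rad, bio4_kelvin)
    assert set(grids) == set(ALL_VARIABLES)
    return grids


def _derive_from_series(tmin, tmax, rain, rad, bio4_kelvin: bool = True) -> dict[str, np.ndarray]:
    """Core derivation over weekly arrays of shape (52, ...)."""
    for name, arr in (("tmin", tmin), ("tmax", tmax), ("rain", rain), ("rad", rad)):
        if np.asarray(arr).shape[0] != N_WEEKS:
            raise ValueError(f"{name} must have {N_WEEKS} weeks on axis 0")
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    rain = np.asarray(rain, float)
    rad = np.asarray(rad, float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in at least one week")
    tmean = 0.5 * (tmin + tmax)

    out: dict[str, np.ndarray] = {}
    out["BIO1"] = tmean.mean(axis=0)
    out["BIO2"] = (tmax - tmin).mean(axis=0)
    out["BIO5"] = tmax.max(axis=0)
    out["BIO6"] = tmin.min(axis=0)
    out["BIO7"] = out["BIO5"] - out["BIO6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["BIO3"] = np.where(out["BIO7"] > 0, out["BIO2"] / out["BIO7"], 0.0)
    out["BIO4"] = _cv(tmean + KELVIN_OFFSET if bio4_kelvin else tmean)

    t_q = _window_means(tmean)
    rain_q = _window_means(rain)  # mean is a monotone proxy for the 13-week sum
    rad_q = _window_means(rad)
    driest = np.argmin(rain_q, axis=0)
    wettest = np.argmax(rain_q, axis=0)
    coldest = np.argmin(t_q, axis=0)
    warmest = np.argmax(t_q, axis=0)
    out["BIO9"] = _pick(t_q, driest)
    out["BIO11"] = _pick(t_q, coldest)
    out["BIO24"] = _pick(rad_q, wettest)
    out["BIO26"] = _pick(rad_q, warmest)

    out["BIO20"] = rad.mean(axis=0)
    out["BIO21"] = rad.max(axis=0)
    out["BIO22"] = rad.min(axis=0)
    out["BIO23"] = _cv(rad)
    return out


def extract_at_points(
    rasters: dict[str, np.ndarray],
    geom: GridGeometry,
    points: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Cell values of every variable at each point (no interpolation).

    Returns (table, n_excluded); points outside the raster coverage or in
    all-NaN cells are excluded and counted.  An empty point set yields an
    empty table.
    """
    names = list(rasters)
    if points.empty:
        return pd.DataFrame(columns=["id", "lon", "lat", *names]), 0
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    inside = geom.contains(lon, lat)
    iy, ix = geom.cell_index(lon, lat, clip=True)
    values = {name: np.asarray(rasters[name], float)[iy, ix] for name in names}
    nodata = np.zeros(len(points), dtype=bool)
    for v in values.values():
        nodata |= np.isnan(v)
    ok = inside & ~nodata
    table = pd.DataFrame(
        {
            "id": points["id"].to_numpy() if "id" in points else np.arange(len(points)),
            "lon": lon,
            "lat": lat,
            **{name: v for name, v in values.items()},
        }
    )[ok]
    return table.reset_index(drop=True), int((~ok).sum())
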