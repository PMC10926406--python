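"""Process-based ecoclimatic suitability engine.

Computes, for every grid cell, an annual Growth Index (GI, 0-100) from weekly
trapezoidal temperature and soil-moisture indices, four linearly accumulated
climate stresses (cold, heat, dry, wet), the stress-discounted Ecoclimatic
Index (EI, 0-100) and a degree-day generation count.  GI > 0 marks climates
that can carry at least a seasonal population; EI > 0 marks climates where
the population can persist year-round.

Two scenarios are supported: rainfed, and irrigated with a constant top-up
(default 2.5 mm/day year-round).  ``run_scenarios`` composites the two using
an irrigation mask, taking the irrigated solution where irrigation is
practised and the rainfed one elsewhere.

The engine is fully deterministic and vectorised over arbitrary trailing
dimensions: every function accepts weekly arrays of shape ``(52, ...)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ClimateGrid, GridGeometry, N_WEEKS
from .params import ClimexParams

IRRIGATION_TOPUP_MM_DAY = 2.5

__all__ = [
    "SuitabilitySurface",
    "soil_moisture_series",
    "temperature_index",
    "moisture_index",
    "growth_index",
    "stress_indices",
    "ecoclimatic_index",
    "generations",
    "run_single_scenario",
    "run_scenarios",
    "IRRIGATION_TOPUP_MM_DAY",
]


@dataclass
class SuitabilitySurface:
    """Per-cell GI, EI and generation count for one scenario."""

    geom: GridGeometry
    GI: np.ndarray
    EI: np.ndarray
    generations: np.ndarray
    scenario: str  # rainfed | irrigated | composite

    def __post_init__(self) -> None:
        shape = self.geom.shape
        self.GI = np.asarray(self.GI, dtype=float)
        self.EI = np.asarray(self.EI, dtype=float)
        self.generations = np.asarray(self.generations, dtype=int)
        for name in ("GI", "EI", "generations"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match geometry {shape}")
        if np.any(self.GI < 0) or np.any(self.GI > 100):
            raise ValueError("GI out of [0, 100]")
        if np.any(self.EI < -1e-9) or np.any(self.EI > self.GI + 1e-9):
            raise ValueError("EI must satisfy 0 <= EI <= GI")
        if self.scenario not in ("rainfed", "irrigated", "composite"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _weekly(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape[0] != N_WEEKS:
        raise ValueError(f"{name} must have {N_WEEKS} weeks on axis 0")
    return arr


def soil_moisture_series(rain, temp, topup: float, params: ClimexParams) -> np.ndarray:
    """Weekly soil-moisture fractions from a single-bucket water budget.

    store <- clamp(store + rain + 7*topup - evap, 0, 2*capacity) with
    evaporative demand evap = max(0, evap_coeff * temp).  The budget starts
    half full and is iterated over two identical annual cycles; the second
    cycle (the spun-up equilibrium path) is returned as store/capacity, a
    fraction in [0, 2].
    """
    rain = _weekly(rain, "rain")
    temp = _weekly(temp, "temp")
    if np.any(rain < 0):
        raise ValueError("negative rainfall")
    if topup < 0:
        raise ValueError("topup must be >= 0")
    cap = params.bucket_capacity
    evap = np.maximum(0.0, params.evap_coeff * temp)
    supply = rain + 7.0 * topup
    store = np.full(rain.shape[1:], cap / 2.0, dtype=float)
    out = np.empty_like(rain)
    for cycle in range(2):
        for w in range(N_WEEKS):
            store = np.clip(store + supply[w] - evap[w], 0.0, 2.0 * cap)
            if cycle == 1:
                out[w] = store / cap
    return out


def _trapezoid(x, lo, ramp_lo, ramp_hi, hi) -> np.ndarray:
    """Piecewise-linear index: 0 at/below lo, 1 on [ramp_lo, ramp_hi], 0 at/above hi."""
    x = np.asarray(x, dtype=float)
    return np.interp(x, [lo, ramp_lo, ramp_hi, hi], [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)


def temperature_index(temp, params: ClimexParams) -> np.ndarray:
    """Weekly temperature growth index TI in [0, 1] (DV0-DV3 trapezoid)."""
    return _trapezoid(temp, params.DV0, params.DV1, params.DV2, params.DV3)


def moisture_index(sm, params: ClimexParams) -> np.ndarray:
    """Weekly moisture growth index MI in [0, 1] (SM0-SM3 trapezoid)."""
    return _trapezoid(sm, params.SM0, params.SM1, params.SM2, params.SM3)


def growth_index(TI, MI) -> np.ndarray:
    """Annual GI = 100 * mean over weeks of TI*MI."""
    TI = _weekly(TI, "TI")
    MI = _weekly(MI, "MI")
    return 100.0 * np.mean(TI * MI, axis=0)


def stress_indices(temp, sm, params: ClimexParams):
    """Linearly accumulated cold, dry, heat and wet stresses, each capped at 100.

    Each stress sums rate * weekly threshold exceedance over the year, e.g.
    CS = min(100, sum_w THCS * max(0, TTCS - temp_w)).
    """
    temp = _weekly(temp, "temp")
    sm = _weekly(sm, "sm")
    cs = np.minimum(100.0, params.THCS * np.sum(np.maximum(0.0, params.TTCS - temp), axis=0))
    hs = np.minimum(100.0, params.THHS * np.sum(np.maximum(0.0, temp - params.TTHS), axis=0))
    ds = np.minimum(100.0, params.HDS * np.sum(np.maximum(0.0, params.SMDS - sm), axis=0))
    ws = np.minimum(100.0, params.HWS * np.sum(np.maximum(0.0, sm - params.SMWS), axis=0))
    return cs, ds, hs, ws


def ecoclimatic_index(GI, stresses) -> np.ndarray:
    """EI = GI * prod(1 - stress/100) over the four stresses; in [0, GI]."""
    GI = np.asarray(GI, dtype=float)
    ei = GI.copy()
    for s in stresses:
        ei = ei * (1.0 - np.asarray(s, dtype=float) / 100.0)
    return ei


def generations(temp, params: ClimexParams) -> np.ndarray:
    """Potential generations per year: floor(annual degree-days above DV0 / PDD)."""
    temp = _weekly(temp, "temp")
    dd = 7.0 * np.sum(np.maximum(0.0, temp - params.DV0), axis=0)
    return np.floor(dd / params.PDD).astype(int)


def run_single_scenario(
    climate: ClimateGrid, params: ClimexParams, topup: float, scenario: str
) -> SuitabilitySurface:
    temp = climate.tmean
    sm = soil_moisture_series(climate.rain, temp, topup, params)
    TI = temperature_index(temp, params)
    MI = moisture_index(sm, params)
    GI = growth_index(TI, MI)
    EI = ecoclimatic_index(GI, stress_indices(temp, sm, params))
    gens = generations(temp, params)
    return SuitabilitySurface(geom=climate.geom, GI=GI, EI=EI, generations=gens, scenario=scenario)


def run_scenarios(
    climate: ClimateGrid,
    params: ClimexParams,
    irrigation_mask: np.ndarray,
    topup: float = IRRIGATION_TOPUP_MM_DAY,
) -> SuitabilitySurface:
    """Rainfed + irrigated runs composited by the irrigation mask.

    Irrigated cell values are taken where the mask is true, rainfed values
    elsewhere, yielding the mashed-up suitability surface.
    """
    mask = np.asarray(irrigation_mask, dtype=bool)
    if mask.shape != climate.geom.shape:
        raise ValueError("irrigation mask shape does not match climate grid")
    rainfed = run_single_scenario(climate, params, 0.0, "rainfed")
    irrigated = run_single_scenario(climate, params, topup, "irrigated")
    return SuitabilitySurface(
        geom=climate.geom,
        GI=np.where(mask, irrigated.GI, rainfed.GI),
        EI=np.where(mask, irrigated.EI, rainfed.EI),
        generations=np.where(mask, irrigated.generations, rainfed.generations),
        scenario="composite",
    )
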