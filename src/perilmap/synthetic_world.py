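"""Seeded synthetic worlds with analytically known climate structure.

The generator builds an idealised planet covering a +/-40 degree latitude
window: weekly mean temperature falls linearly with |latitude| and oscillates
seasonally with an amplitude that grows with |latitude| (southern-hemisphere
phase shifted by 26 weeks); rainfall is constant per week within three
Hadley-style belts (wet tropics, subtropical deserts, moist temperate zone);
radiation is a smooth deterministic function of latitude and week.  Deserts
carry rectangular irrigated patches, a seeded fraction of cells carries maize
area, and rectangular region labels double as countries for record-cleaning
tests and as reporting regions.

Because the construction is closed-form, the set of cells that is climatically
optimal for the reference pest every week of the year (``truth_suitable_band``)
is known exactly and provides ground truth for the downstream suitability
engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import moisture_index, soil_moisture_series, temperature_index
from .grids import ClimateGrid, GridGeometry, N_WEEKS, write_ascii_grid
from .params import ClimexParams, faw_default

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "make_climate_world",
    "make_pest_params",
    "sample_occurrences",
    "write_world",
]

_SOURCES = ("survey_db", "literature", "field_reports")


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world; defaults are the standard test planet."""

    n_lon: int = 240
    n_lat: int = 120
    resolution: float = 40.0  # arc-minutes per cell; 240x120 spans +/-80 lon, +/-40 lat
    temp_equator_mean: float = 27.0  # degC
    temp_lapse: float = 0.45  # degC per degree |latitude|
    seasonal_amplitude_slope: float = 0.25  # degC amplitude per degree |latitude|
    diurnal_range: float = 8.0  # degC
    rain_tropical: float = 50.0  # mm per week
    rain_temperate: float = 25.0
    rain_desert: float = 5.0
    band_edges: tuple[float, float] = (15.0, 25.0)  # |lat| bounds: tropics | desert | temperate
    irrigation_patches: tuple[tuple[int, int, int, int], ...] = (
        (84, 96, 40, 70),  # (row0, row1, col0, col1), half-open cell ranges
        (24, 36, 150, 185),
    )
    maize_fraction: float = 0.35
    n_region_lon: int = 6
    n_region_lat: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lon < 2 or self.n_lat < 2:
            raise ValueError("grid must be at least 2x2")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name in ("rain_tropical", "rain_temperate", "rain_desert"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        e1, e2 = self.band_edges
        if not (0.0 < e1 < e2):
            raise ValueError("band_edges must be increasing and positive")
        lat_half = self.n_lat * self.resolution / 60.0 / 2.0
        if e1 >= lat_half:
            raise ValueError("tropical belt edge must lie inside the latitude range")
        if not (0.0 <= self.maize_fraction <= 1.0):
            raise ValueError("maize_fraction must be in [0, 1]")
        for r0, r1, c0, c1 in self.irrigation_patches:
            if not (0 <= r0 < r1 <= self.n_lat and 0 <= c0 < c1 <= self.n_lon):
                raise ValueError(f"irrigation patch ({r0},{r1},{c0},{c1}) outside the grid")

    @property
    def geom(self) -> GridGeometry:
        cell = self.resolution / 60.0
        return GridGeometry(
            lon_min=-self.n_lon * cell / 2.0,
            lat_min=-self.n_lat * cell / 2.0,
            n_lon=self.n_lon,
            n_lat=self.n_lat,
            resolution=self.resolution,
        )

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["band_edges"] = list(self.band_edges)
        doc["irrigation_patches"] = [list(p) for p in self.irrigation_patches]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "band_edges" in doc:
            doc["band_edges"] = tuple(doc["band_edges"])
        if "irrigation_patches" in doc:
            doc["irrigation_patches"] = tuple(tuple(p) for p in doc["irrigation_patches"])
        return cls(**doc)


@dataclass
class SyntheticWorld:
    climate: ClimateGrid
    irrigation_mask: np.ndarray  # bool
    maize_area: np.ndarray  # hectares >= 0
    region_labels: np.ndarray  # string labels; also used as country labels
    truth_suitable_band: np.ndarray  # bool; optimal every week for reference params
    config: WorldConfig

    @property
    def geom(self) -> GridGeometry:
        return self.climate.geom

    def __post_init__(self) -> None:
        shape = self.geom.shape
        self.irrigation_mask = np.asarray(self.irrigation_mask, dtype=bool)
        self.maize_area = np.asarray(self.maize_area, dtype=float)
        self.truth_suitable_band = np.asarray(self.truth_suitable_band, dtype=bool)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        for name in ("irrigation_mask", "maize_area", "region_labels", "truth_suitable_band"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match climate grid {shape}")
        if np.any(self.maize_area < 0):
            raise ValueError("maize_area must be >= 0")


def _weekly_mean_temperature(cfg: WorldConfig, lat: np.ndarray) -> np.ndarray:
    """Closed-form weekly mean temperature, shape (52, n_lat)."""
    weeks = np.arange(N_WEEKS)[:, None]
    abs_lat = np.abs(lat)[None, :]
    amplitude = cfg.seasonal_amplitude_slope * abs_lat
    # southern hemisphere is phase-shifted by exactly 26 weeks
    phase = np.where(lat[None, :] >= 0, 0.0, N_WEEKS / 2.0)
    season = np.sin(2.0 * np.pi * (weeks + phase) / N_WEEKS)
    return cfg.temp_equator_mean - cfg.temp_lapse * abs_lat + amplitude * season


def _weekly_radiation(lat: np.ndarray) -> np.ndarray:
    """Deterministic insolation proxy (W m-2), shape (52, n_lat)."""
    weeks = np.arange(N_WEEKS)[:, None]
    lat_r = np.deg2rad(lat)[None, :]
    seasonal = np.sin(2.0 * np.pi * weeks / N_WEEKS) * np.sin(lat_r)
    return np.maximum(0.0, 340.0 * np.cos(lat_r) + 80.0 * seasonal)


def _belt_rain(cfg: WorldConfig, lat: np.ndarray) -> np.ndarray:
    abs_lat = np.abs(lat)
    e1, e2 = cfg.band_edges
    return np.select(
        [abs_lat < e1, abs_lat < e2],
        [cfg.rain_tropical, cfg.rain_desert],
        default=cfg.rain_temperate,
    )


def make_climate_world(config: WorldConfig, reference: ClimexParams | None = None) -> SyntheticWorld:
    """Build the full synthetic world from a configuration.

    The truth band contains the cells whose weekly mean temperature sits on
    the temperature optimum plateau [DV1, DV2] in all 52 weeks and whose
    rainfed soil moisture sits on the moisture plateau [SM1, SM2] in all 52
    weeks under ``reference`` (the default fall-armyworm block if omitted).
    """
    reference = reference or faw_default()
    geom = config.geom
    lat = geom.lat_centers
    rng = np.random.default_rng(config.seed)

    tmean_lat = _weekly_mean_temperature(config, lat)  # (52, n_lat)
    rad_lat = _weekly_radiation(lat)
    rain_lat = np.broadcast_to(_belt_rain(config, lat)[None, :], tmean_lat.shape)

    expand = lambda a: np.repeat(a[:, :, None], geom.n_lon, axis=2)
    tmean = expand(tmean_lat)
    climate = ClimateGrid(
        geom=geom,
        tmin=tmean - config.diurnal_range / 2.0,
        tmax=tmean + config.diurnal_range / 2.0,
        rain=expand(np.ascontiguousarray(rain_lat)),
        rad=expand(rad_lat),
    )

    irrigation = np.zeros(geom.shape, dtype=bool)
    for r0, r1, c0, c1 in config.irrigation_patches:
        irrigation[r0:r1, c0:c1] = True

    maize = np.zeros(geom.shape, dtype=float)
    carry = rng.random(geom.shape) < config.maize_fraction
    maize[carry] = rng.uniform(500.0, 5000.0, size=int(carry.sum()))

    regions = np.empty(geom.shape, dtype=object)
    row_block = math.ceil(geom.n_lat / config.n_region_lat)
    col_block = math.ceil(geom.n_lon / config.n_region_lon)
    for i in range(geom.n_lat):
        for j in range(geom.n_lon):
            regions[i, j] = f"R{i // row_block}{j // col_block}"

    sm = soil_moisture_series(climate.rain, climate.tmean, 0.0, reference)
    on_temp_plateau = (tmean >= reference.DV1) & (tmean <= reference.DV2)
    on_moist_plateau = (sm >= reference.SM1) & (sm <= reference.SM2)
    truth = on_temp_plateau.all(axis=0) & on_moist_plateau.all(axis=0)

    return SyntheticWorld(
        climate=climate,
        irrigation_mask=irrigation,
        maize_area=maize,
        region_labels=regions,
        truth_suitable_band=truth,
        config=config,
    )


def make_pest_params(
    n_pests: int,
    reference: ClimexParams | None = None,
    spread: float = 0.5,
    seed: int = 0,
    max_retries: int = 200,
) -> list[ClimexParams]:
    """Seeded perturbations of a reference parameter block.

    Each pest perturbs thresholds additively (temperature in degC, moisture in
    bucket fractions) and rates/PDD multiplicatively, scaled by ``spread``;
    draws violating the threshold-ordering invariants are resampled, and a
    block that cannot be built within ``max_retries`` draws raises.
    """
    if n_pests < 1:
        raise ValueError("n_pests must be >= 1")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    reference = reference or faw_default()
    rng = np.random.default_rng(seed)
    pests: list[ClimexParams] = []
    for i in range(n_pests):
        for _ in range(max_retries):
            try:
                pests.append(
                    reference.replace(
                        DV0=reference.DV0 + spread * rng.normal(0.0, 2.0),
                        DV1=reference.DV1 + spread * rng.normal(0.0, 2.0),
                        DV2=reference.DV2 + spread * rng.normal(0.0, 2.0),
                        DV3=reference.DV3 + spread * rng.normal(0.0, 2.0),
                        SM0=reference.SM0 + spread * rng.normal(0.0, 0.05),
                        SM1=reference.SM1 + spread * rng.normal(0.0, 0.05),
                        SM2=reference.SM2 + spread * rng.normal(0.0, 0.05),
                        SM3=reference.SM3 + spread * rng.normal(0.0, 0.05),
                        TTCS=reference.TTCS + spread * rng.normal(0.0, 2.0),
                        TTHS=reference.TTHS + spread * rng.normal(0.0, 2.0),
                        THCS=reference.THCS * float(np.exp(spread * rng.normal())),
                        THHS=reference.THHS * float(np.exp(spread * rng.normal())),
                        HDS=reference.HDS * float(np.exp(spread * rng.normal())),
                        HWS=reference.HWS * float(np.exp(spread * rng.normal())),
                        PDD=reference.PDD * float(np.exp(0.2 * spread * rng.normal())),
                        name=f"pest_{i:02d}",
                    )
                )
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                f"could not draw a valid parameter block for pest {i} "
                f"within {max_retries} retries (spread={spread})"
            )
    return pests


def sample_occurrences(
    surface,
    region_labels: np.ndarray,
    n: int,
    noise_rate: float = 0.0,
    duplicate_rate: float = 0.0,
    mislabel_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw contaminated occurrence records from a suitability surface.

    ``n`` base records are sampled cell-wise with probability proportional to
    EI; a ``noise_rate`` fraction of them is resampled uniformly over all
    cells.  ``ceil(duplicate_rate*n)`` exact-coordinate duplicates (under a
    different source) are appended and ``ceil(mislabel_rate*n)`` base records
    get a country label inconsistent with the region grid at their location.
    Ground-truth contamination flags are kept for testing.
    """
    for name, rate in (
        ("noise_rate", noise_rate),
        ("duplicate_rate", duplicate_rate),
        ("mislabel_rate", mislabel_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    columns = [
        "id", "lon", "lat", "country", "year", "source",
        "is_noise", "is_duplicate", "is_mislabelled",
    ]
    if n == 0:
        return pd.DataFrame(columns=columns)

    geom = surface.geom
    region_labels = np.asarray(region_labels, dtype=object)
    if region_labels.shape != geom.shape:
        raise ValueError("region_labels shape does not match surface")
    weights = np.clip(surface.EI, 0.0, None).ravel()
    total = weights.sum()
    if total <= 0 and noise_rate < 1.0:
        raise ValueError("no EI > 0 cells to sample from (noise_rate < 1)")

    rng = np.random.default_rng(seed)
    n_cells = weights.size
    if total > 0:
        cells = rng.choice(n_cells, size=n, p=weights / total)
    else:
        cells = np.zeros(n, dtype=int)
    is_noise = rng.random(n) < noise_rate
    cells[is_noise] = rng.integers(0, n_cells, size=int(is_noise.sum()))

    iy, ix = np.unravel_index(cells, geom.shape)
    cell = geom.cell_deg
    lon = geom.lon_min + (ix + rng.random(n)) * cell
    lat = geom.lat_min + (iy + rng.random(n)) * cell
    country = region_labels[iy, ix].copy()
    year = rng.integers(2008, 2022, size=n)
    source = rng.choice(_SOURCES, size=n, p=(0.7, 0.2, 0.1))

    is_mislabelled = np.zeros(n, dtype=bool)
    n_mis = math.ceil(mislabel_rate * n)
    if n_mis > 0:
        labels = np.unique(region_labels)
        if labels.size < 2:
            raise ValueError("mislabelling requires at least two region labels")
        picks = rng.choice(n, size=min(n_mis, n), replace=False)
        for k in picks:
            wrong = rng.choice(labels[labels != country[k]])
            country[k] = wrong
        is_mislabelled[picks] = True

    base = pd.DataFrame(
        {
            "id": [f"occ_{k:05d}" for k in range(n)],
            "lon": lon,
            "lat": lat,
            "country": country,
            "year": year,
            "source": source,
            "is_noise": is_noise,
            "is_duplicate": np.zeros(n, dtype=bool),
            "is_mislabelled": is_mislabelled,
        }
    )

    n_dup = math.ceil(duplicate_rate * n)
    if n_dup > 0:
        # duplicate clean-labelled records under a different source so the
        # planted contamination is recoverable by the coordinate+country rule
        pool = np.flatnonzero(~is_mislabelled)
        if pool.size == 0:
            pool = np.arange(n)
        src_idx = rng.choice(pool, size=n_dup, replace=True)
        dup = base.iloc[src_idx].copy().reset_index(drop=True)
        dup["id"] = [f"dup_{k:05d}" for k in range(n_dup)]
        dup["source"] = [
            _SOURCES[(list(_SOURCES).index(s) + 1) % len(_SOURCES)] for s in dup["source"]
        ]
        dup["is_duplicate"] = True
        base = pd.concat([base, dup], ignore_index=True)
    return base[columns]


def write_world(world: SyntheticWorld, outdir) -> dict[str, str]:
    """Serialise a world to disk; returns {artifact: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    geom = world.geom

    climate_path = outdir / "climate.nc"
    world.climate.to_netcdf(climate_path)
    paths["climate"] = str(climate_path)

    for name, grid in (
        ("irrigation_mask", world.irrigation_mask.astype(float)),
        ("maize_area", world.maize_area),
        ("truth_suitable_band", world.truth_suitable_band.astype(float)),
    ):
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, grid, geom)
        paths[name] = str(p)

    labels = sorted(set(world.region_labels.ravel().tolist()))
    code = {lab: i for i, lab in enumerate(labels)}
    coded = np.vectorize(code.get)(world.region_labels).astype(float)
    p = outdir / "region_labels.asc"
    write_ascii_grid(p, coded, geom)
    paths["region_labels"] = str(p)
    table = outdir / "region_labels.csv"
    pd.DataFrame({"code": [code[l] for l in labels], "label": labels}).to_csv(table, index=False)
    paths["region_table"] = str(table)

    cfg = outdir / "world_config.yaml"
    world.config.to_yaml(cfg)
    paths["config"] = str(cfg)
    return paths
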