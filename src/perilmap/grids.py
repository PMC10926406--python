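"""Regular lat-lon grid geometry, climate cubes and plain-text raster I/O.

All gridded quantities in this package live on a regular geographic grid with
a south-west origin: array index ``[ilat, ilon]`` where ``ilat = 0`` is the
southernmost row.  Cell membership uses half-open intervals, so a point on a
shared edge belongs to the cell to its north-east, and points on the extreme
north/east boundary of the grid are assigned to the last cell.

Single-band rasters are serialised as ESRI ASCII grids (``.asc``), a plain
text format readable by any GIS; multi-band weekly climate cubes go to NetCDF
through :mod:`xarray`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

N_WEEKS = 52
EARTH_RADIUS_KM = 6371.0

__all__ = [
    "N_WEEKS",
    "GridGeometry",
    "ClimateGrid",
    "write_ascii_grid",
    "read_ascii_grid",
]


@dataclass(frozen=True)
class GridGeometry:
    """Extent and shape of a regular lat-lon grid (south-west origin)."""

    lon_min: float
    lat_min: float
    n_lon: int
    n_lat: int
    resolution: float  # arc-minutes per cell (square cells)

    def __post_init__(self) -> None:
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid dimensions must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def cell_deg(self) -> float:
        return self.resolution / 60.0

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_lon * self.cell_deg

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_lat * self.cell_deg

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.cell_deg

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.cell_deg

    def cell_index(self, lon, lat, clip: bool = False):
        """Map coordinates to (ilat, ilon); half-open cells, SW origin.

        Points exactly on the north/east grid boundary fall in the last
        row/column.  With ``clip=False`` out-of-extent points get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix = np.floor((lon - self.lon_min) / self.cell_deg).astype(int)
        iy = np.floor((lat - self.lat_min) / self.cell_deg).astype(int)
        # boundary ownership: the far edge belongs to the last cell
        ix = np.where(lon == self.lon_max, self.n_lon - 1, ix)
        iy = np.where(lat == self.lat_max, self.n_lat - 1, iy)
        if clip:
            ix = np.clip(ix, 0, self.n_lon - 1)
            iy = np.clip(iy, 0, self.n_lat - 1)
        else:
            bad = (ix < 0) | (ix >= self.n_lon) | (iy < 0) | (iy >= self.n_lat)
            ix = np.where(bad, -1, ix)
            iy = np.where(bad, -1, iy)
        return iy, ix

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )

    def cell_areas_ha(self) -> np.ndarray:
        """Spherical cell areas in hectares, shape (n_lat, n_lon).

        A = R^2 * dlon * (sin(lat_top) - sin(lat_bottom)); constant along a
        latitude row.
        """
        d = np.deg2rad(self.cell_deg)
        lat_edges = np.deg2rad(self.lat_min + np.arange(self.n_lat + 1) * self.cell_deg)
        band = EARTH_RADIUS_KM**2 * d * np.diff(np.sin(lat_edges))  # km^2 per cell
        return np.repeat(band[:, None], self.n_lon, axis=1) * 100.0  # km^2 -> ha

    def refine(self, factor: int) -> "GridGeometry":
        """Geometry of the grid split into factor x factor child cells."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("factor must be a positive integer")
        return GridGeometry(
            lon_min=self.lon_min,
            lat_min=self.lat_min,
            n_lon=self.n_lon * int(factor),
            n_lat=self.n_lat * int(factor),
            resolution=self.resolution / factor,
        )


@dataclass
class ClimateGrid:
    """52-week climatological normals on a regular grid.

    Arrays are shaped ``(52, n_lat, n_lon)``: weekly minimum and maximum
    temperature (degC), rainfall (mm per week) and solar radiation (W m-2).
    """

    geom: GridGeometry
    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    rad: np.ndarray

    def __post_init__(self) -> None:
        expected = (N_WEEKS,) + self.geom.shape
        for name in ("tmin", "tmax", "rain", "rad"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != expected:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {expected}"
                )
            setattr(self, name, arr)
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin in at least one cell-week")
        if np.any(self.rain < 0):
            raise ValueError("negative rainfall")

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "week": np.arange(N_WEEKS),
            "lat": self.geom.lat_centers,
            "lon": self.geom.lon_centers,
        }
        dims = ("week", "lat", "lon")
        ds = xr.Dataset(
            {name: (dims, getattr(self, name)) for name in ("tmin", "tmax", "rain", "rad")},
            coords=coords,
        )
        ds.attrs.update(
            lon_min=self.geom.lon_min,
            lat_min=self.geom.lat_min,
            resolution_arcmin=self.geom.resolution,
        )
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimateGrid":
        geom = GridGeometry(
            lon_min=float(ds.attrs["lon_min"]),
            lat_min=float(ds.attrs["lat_min"]),
            n_lon=ds.sizes["lon"],
            n_lat=ds.sizes["lat"],
            resolution=float(ds.attrs["resolution_arcmin"]),
        )
        return cls(
            geom=geom,
            tmin=ds["tmin"].values,
            tmax=ds["tmax"].values,
            rain=ds["rain"].values,
            rad=ds["rad"].values,
        )

    @classmethod
    def from_netcdf(cls, path) -> "ClimateGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def write_ascii_grid(path, grid: np.ndarray, geom: GridGeometry, nodata: float = -9999.0) -> None:
    """Write a single band as an ESRI ASCII grid (rows north to south)."""
    grid = np.asarray(grid, dtype=float)
    if grid.shape != geom.shape:
        raise ValueError("grid shape does not match geometry")
    body = np.where(np.isnan(grid), nodata, grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {geom.n_lon}\n")
        fh.write(f"nrows {geom.n_lat}\n")
        fh.write(f"xllcorner {geom.lon_min:.10g}\n")
        fh.write(f"yllcorner {geom.lat_min:.10g}\n")
        fh.write(f"cellsize {geom.cell_deg:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, body[::-1], fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII grid back into (array, geometry); nodata -> NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)[::-1].copy()
    nodata = header.get("nodata_value", -9999.0)
    body[body == nodata] = np.nan
    geom = GridGeometry(
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        n_lon=int(header["ncols"]),
        n_lat=int(header["nrows"]),
        resolution=header["cellsize"] * 60.0,
    )
    return body, geom
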