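"""Occurrence-record cleaning, grid deduplication and range classification.

Pooled geo-coded occurrence compilations carry three kinds of defects that
must be removed before a climate-suitability assessment: records with missing
or impossible coordinates, records whose stated country disagrees with the
country at their coordinates (spatially inconsistent metadata), and the same
sighting reported through more than one source.  After cleaning, records are
thinned to at most one per climate-grid cell so that model-evaluation
statistics are not inflated by spatially redundant points.

Every step returns a :class:`CurationReport` whose per-source rows sum to the
totals, mirroring the original/cleaned/unique bookkeeping of a curation
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .grids import GridGeometry

__all__ = [
    "RangeClass",
    "CurationReport",
    "clean_records",
    "dedup_to_grid",
    "classify_range",
]

#: drop-reason codes, in the order they are applied
DROP_REASONS = (
    "missing_coords",
    "out_of_range_coords",
    "outside_coverage",
    "label_mismatch",
    "cross_source_duplicate",
    "grid_duplicate",
)


class RangeClass(str, Enum):
    """Occurrence range membership used in the niche analysis."""

    native_persistent = "native_persistent"
    historical_seasonal = "historical_seasonal"
    newly_invaded = "newly_invaded"


@dataclass
class CurationReport:
    """Original/cleaned/unique bookkeeping with per-source rows."""

    per_source: pd.DataFrame  # columns: source, n_original, n_cleaned, n_unique
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"source", "n_original", "n_cleaned", "n_unique"}
        if not required.issubset(self.per_source.columns):
            raise ValueError(f"per_source must have columns {sorted(required)}")
        bad = ~(
            (self.per_source.n_original >= self.per_source.n_cleaned)
            & (self.per_source.n_cleaned >= self.per_source.n_unique)
            & (self.per_source.n_unique >= 0)
        )
        if bad.any():
            raise ValueError("per-source counts must satisfy original >= cleaned >= unique >= 0")

    @property
    def n_original(self) -> int:
        return int(self.per_source.n_original.sum())

    @property
    def n_cleaned(self) -> int:
        return int(self.per_source.n_cleaned.sum())

    @property
    def n_unique(self) -> int:
        return int(self.per_source.n_unique.sum())

    def to_frame(self) -> pd.DataFrame:
        """Per-source table with a Total row appended."""
        total = pd.DataFrame(
            [
                {
                    "source": "Total",
                    "n_original": self.n_original,
                    "n_cleaned": self.n_cleaned,
                    "n_unique": self.n_unique,
                }
            ]
        )
        return pd.concat([self.per_source, total], ignore_index=True)

    @classmethod
    def from_counts(cls, rows: list[tuple[str, int, int, int]]) -> "CurationReport":
        """Build a report from (source, original, cleaned, unique) rows."""
        return cls(
            per_source=pd.DataFrame(
                rows, columns=["source", "n_original", "n_cleaned", "n_unique"]
            )
        )


def _per_source_counts(records: pd.DataFrame, kept: pd.DataFrame, unique: pd.DataFrame | None):
    sources = sorted(records["source"].astype(str).unique()) if len(records) else []
    rows = []
    for s in sources:
        rows.append(
            {
                "source": s,
                "n_original": int((records["source"] == s).sum()),
                "n_cleaned": int((kept["source"] == s).sum()),
                "n_unique": int((unique["source"] == s).sum()) if unique is not None
                else int((kept["source"] == s).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["source", "n_original", "n_cleaned", "n_unique"])


def clean_records(
    records: pd.DataFrame,
    label_grid: np.ndarray,
    geom: GridGeometry,
) -> tuple[pd.DataFrame, CurationReport]:
    """Drop defective records; return (retained records, report).

    Applied in order: missing coordinates; coordinates outside [-180, 180] x
    [-90, 90]; coordinates outside the label grid's coverage (a drop reason,
    not an error); stated country differing from the label grid at the
    record's cell; later records that duplicate an earlier one's coordinates
    (rounded to 4 decimals) and country.  Retained records are unchanged and
    keep their input order.
    """
    records = records.reset_index(drop=True)
    label_grid = np.asarray(label_grid, dtype=object)
    if label_grid.shape != geom.shape:
        raise ValueError("label grid shape does not match geometry")

    lon = pd.to_numeric(records.get("lon"), errors="coerce")
    lat = pd.to_numeric(records.get("lat"), errors="coerce")
    reasons = pd.Series([None] * len(records), dtype=object)

    missing = lon.isna() | lat.isna()
    reasons[missing] = "missing_coords"

    with np.errstate(invalid="ignore"):
        out_of_range = ~missing & ((lon.abs() > 180) | (lat.abs() > 90))
    reasons[out_of_range & reasons.isna()] = "out_of_range_coords"

    ok = reasons.isna()
    inside = np.zeros(len(records), dtype=bool)
    inside[ok] = geom.contains(lon[ok].to_numpy(), lat[ok].to_numpy())
    reasons[ok & ~inside] = "outside_coverage"

    ok = reasons.isna()
    if ok.any():
        iy, ix = geom.cell_index(lon[ok].to_numpy(), lat[ok].to_numpy(), clip=False)
        grid_label = label_grid[iy, ix]
        mismatch = grid_label != records.loc[ok, "country"].astype(str).to_numpy()
        idx = np.flatnonzero(ok.to_numpy())[mismatch]
        reasons.iloc[idx] = "label_mismatch"

    ok = reasons.isna()
    key = pd.Series(
        list(
            zip(
                lon.round(4).where(ok),
                lat.round(4).where(ok),
                records["country"].astype(str).where(ok),
            )
        )
    )
    dup = ok & key.duplicated(keep="first")
    reasons[dup] = "cross_source_duplicate"

    kept = records[reasons.isna()].copy()
    tally = {r: int((reasons == r).sum()) for r in DROP_REASONS if r != "grid_duplicate"}
    report = CurationReport(
        per_source=_per_source_counts(records, kept, None), drop_reasons=tally
    )
    return kept, report


def dedup_to_grid(
    records: pd.DataFrame, resolution: float
) -> tuple[pd.DataFrame, CurationReport]:
    """Keep at most one record per grid cell at ``resolution`` arc-minutes.

    Cells are half-open intervals anchored at (-180, -90); a record exactly on
    lon = 180 or lat = 90 maps to the last cell.  The earliest record in input
    order wins within a cell, so the operation is idempotent and order-stable.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    records = records.reset_index(drop=True)
    if records[["lon", "lat"]].isna().any().any():
        raise ValueError("dedup_to_grid requires valid coordinates on every record")
    world = GridGeometry(
        lon_min=-180.0,
        lat_min=-90.0,
        n_lon=int(round(360 * 60 / resolution)),
        n_lat=int(round(180 * 60 / resolution)),
        resolution=resolution,
    )
    iy, ix = world.cell_index(
        records["lon"].to_numpy(float), records["lat"].to_numpy(float), clip=True
    )
    cell = pd.Series(iy.astype(np.int64) * world.n_lon + ix.astype(np.int64))
    keep = ~cell.duplicated(keep="first")
    unique = records[keep].copy()
    report = CurationReport(
        per_source=_per_source_counts(records, records, unique),
        drop_reasons={"grid_duplicate": int((~keep).sum())},
    )
    return unique, report


def classify_range(
    records: pd.DataFrame, range_spec: dict[str, RangeClass | str]
) -> pd.DataFrame:
    """Assign each record a range class from its region/country label.

    ``range_spec`` maps region labels to a :class:`RangeClass`; an unmapped
    label raises, naming the offending label.  Returns a copy of the records
    with a ``range_class`` column.
    """
    records = records.copy()
    spec = {k: RangeClass(v) for k, v in range_spec.items()}
    labels = records["country"].astype(str)
    unmapped = sorted(set(labels) - set(spec))
    if unmapped:
        raise KeyError(f"labels not covered by range_spec: {unmapped}")
    records["range_class"] = labels.map(lambda l: spec[l].value)
    return records
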