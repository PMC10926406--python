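"""Multi-pest co-habitation overlay on the gridded maize extent.

Suitability surfaces for a portfolio of pests are reduced to binary
"habitation" indicators (climate-suitable or not), summed into per-cell
co-habitation counts, and intersected with a maize-area grid to report, per
region, the share of maize area at seasonal (GI > 0) and year-round (EI > 0)
risk from the focal pest and — conditional on the focal pest's year-round
suitability — the area shares co-suitable for exactly k additional pests.
A one-degree latitudinal banding of maize area by risk category complements
the regional table.

All shares are weighted by maize area in hectares (never by cell counts);
coarse suitability grids are aligned to the finer maize grid by replication
downscaling, which preserves categorical composition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SuitabilitySurface
from .grids import GridGeometry

__all__ = [
    "RISK_CATEGORIES",
    "MultiPerilStack",
    "downscale",
    "habitation",
    "cohabitation",
    "risk_categories",
    "regional_summary",
    "latitudinal_shares",
]

#: EI risk categories; the shared bin edges 5/34/62 belong to the upper category
RISK_CATEGORIES = ("none", "low", "lower_middle", "upper_middle", "high")
_RISK_EDGES = (5.0, 34.0, 62.0)


def downscale(grid: np.ndarray, geom: GridGeometry, factor: int) -> tuple[np.ndarray, GridGeometry]:
    """Replicate each parent cell into factor x factor children.

    Children carry the parent's value, so any area-weighted categorical
    composition is preserved exactly.  Works for numeric and label grids.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    grid = np.asarray(grid)
    child = np.repeat(np.repeat(grid, factor, axis=0), factor, axis=1)
    return child, geom.refine(factor)


def habitation(surface: SuitabilitySurface, persistence_only: bool = False) -> np.ndarray:
    """Binary climate-suitability: GI > 0 or EI > 0 (EI only in strict mode).

    The default implements the stated rule that cells with GI = EI = 0 are
    unsuitable and any non-zero value is suitable; ``persistence_only``
    restricts suitability to year-round persistence (EI > 0).
    """
    if persistence_only:
        return surface.EI > 0
    return (surface.GI > 0) | (surface.EI > 0)


def cohabitation(habitation_stack: np.ndarray) -> np.ndarray:
    """Cellwise sum of per-pest habitation bits; values in [0, P]."""
    stack = np.asarray(habitation_stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a (P, n_lat, n_lon) stack with P >= 1")
    return stack.astype(int).sum(axis=0)


def risk_categories(EI: np.ndarray) -> np.ndarray:
    """Categorise EI into none / low / lower_middle / upper_middle / high.

    none: EI = 0; low: 0 < EI < 5; lower_middle: [5, 34); upper_middle:
    [34, 62); high: [62, 100].  Out-of-range EI raises.
    """
    EI = np.asarray(EI, float)
    if np.any(EI < 0) or np.any(EI > 100):
        raise ValueError("EI out of [0, 100]")
    e1, e2, e3 = _RISK_EDGES
    return np.select(
        [EI == 0, EI < e1, EI < e2, EI < e3],
        [0, 1, 2, 3],
        default=4,
    )


@dataclass
class MultiPerilStack:
    """Aligned per-pest habitation bits + maize extent on one geometry.

    ``habitation`` holds the additional (non-focal) pests; the focal pest's
    full surface is kept separately for the conditional accounting.
    """

    geom: GridGeometry
    habitation: np.ndarray  # (P, n_lat, n_lon) bool
    pest_names: list[str]
    maize_area: np.ndarray  # hectares
    region_labels: np.ndarray
    faw_surface: SuitabilitySurface

    def __post_init__(self) -> None:
        shape = self.geom.shape
        self.habitation = np.asarray(self.habitation, dtype=bool)
        self.maize_area = np.asarray(self.maize_area, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        if self.habitation.ndim != 3 or self.habitation.shape[1:] != shape:
            raise ValueError("habitation stack must be (P, n_lat, n_lon) on the stack geometry")
        if len(self.pest_names) != self.habitation.shape[0]:
            raise ValueError("pest_names length must match the habitation stack")
        for name in ("maize_area", "region_labels"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match stack geometry")
        if self.faw_surface.geom.shape != shape:
            raise ValueError("focal surface must share the stack geometry")
        if np.any(self.maize_area < 0):
            raise ValueError("maize_area must be >= 0")

    @property
    def n_pests(self) -> int:
        return self.habitation.shape[0]

    @property
    def cohabitation(self) -> np.ndarray:
        return cohabitation(self.habitation)


def _round_preserving_sum(values: np.ndarray, decimals: int = 1) -> np.ndarray:
    """Largest-remainder rounding so the rounded shares keep their exact sum."""
    scale = 10**decimals
    scaled = np.asarray(values, float) * scale
    floored = np.floor(scaled)
    short = int(round(scaled.sum() - floored.sum()))
    order = np.argsort(scaled - floored)[::-1]
    floored[order[:short]] += 1
    return floored / scale


def regional_summary(stack: MultiPerilStack) -> pd.DataFrame:
    """Table of per-region maize risk and conditional co-suitability shares.

    Columns: region; maize area (Mha); % of maize area with focal GI > 0 and
    EI > 0; then, restricted to maize in focal-EI>0 cells, the maize-area
    share co-suitable for exactly k additional pests (k = 0..P).  Shares are
    maize-area weighted and reported to one decimal; a world Total row is
    appended.  Rows whose conditioning area is empty carry NaN shares.
    """
    maize = stack.maize_area
    has_maize = maize > 0
    labels = stack.region_labels
    unlabeled = has_maize & pd.isna(labels.astype(object))
    if unlabeled.any():
        iy, ix = np.argwhere(unlabeled)[0]
        raise ValueError(f"maize cell without region label at row {iy}, col {ix}")

    gi_pos = stack.faw_surface.GI > 0
    ei_pos = stack.faw_surface.EI > 0
    cohab = stack.cohabitation
    P = stack.n_pests

    def one_region(mask: np.ndarray, name: str) -> dict:
        area = maize[mask].sum()
        row: dict = {"region": name, "maize_area_mha": round(area / 1e6, 1)}
        if area > 0:
            row["pct_gi_pos"] = round(100.0 * maize[mask & gi_pos].sum() / area, 1)
            row["pct_ei_pos"] = round(100.0 * maize[mask & ei_pos].sum() / area, 1)
        else:
            row["pct_gi_pos"] = row["pct_ei_pos"] = np.nan
        cond = mask & ei_pos & has_maize
        cond_area = maize[cond].sum()
        if cond_area > 0:
            shares = np.array(
                [100.0 * maize[cond & (cohab == k)].sum() / cond_area for k in range(P + 1)]
            )
            shares = _round_preserving_sum(shares)
        else:
            shares = np.full(P + 1, np.nan)
        for k in range(P + 1):
            row[f"k{k}"] = shares[k]
        return row

    regions = sorted({str(l) for l in labels[has_maize].ravel()})
    rows = [one_region(labels == r, r) for r in regions]
    rows.append(one_region(np.ones_like(has_maize, dtype=bool), "Total"))
    return pd.DataFrame(rows)


def latitudinal_shares(
    EI: np.ndarray,
    maize_area: np.ndarray,
    geom: GridGeometry,
    band_width: float = 1.0,
) -> pd.DataFrame:
    """Maize-area share of the world total per latitudinal band and risk quartile.

    Bands are ``band_width``-degree strips (cells assigned by centre
    latitude).  Within each band the share is split by the EI quartile
    categories Q1 (EI < 5), Q2 [5, 34), Q3 [34, 62), Q4 (>= 62); all entries
    are percentages of the world's total maize area and sum to 100.
    """
    EI = np.asarray(EI, float)
    maize = np.asarray(maize_area, float)
    if EI.shape != geom.shape or maize.shape != geom.shape:
        raise ValueError("grids must match the geometry")
    total = maize.sum()
    if total <= 0:
        raise ValueError("no maize area")

    cats = risk_categories(EI)
    quartile = np.clip(cats, 1, 4)  # none folds into Q1 (EI < 5)
    lat = np.broadcast_to(geom.lat_centers[:, None], geom.shape)
    start = np.floor(geom.lat_min / band_width) * band_width
    band_idx = np.floor((lat - start) / band_width).astype(int)

    rows = []
    for b in range(band_idx.max() + 1):
        south = start + b * band_width
        in_band = band_idx == b
        row = {"lat_south": south, "lat_north": south + band_width}
        for q in (1, 2, 3, 4):
            row[f"q{q}"] = 100.0 * maize[in_band & (quartile == q)].sum() / total
        row["share"] = 100.0 * maize[in_band].sum() / total
        rows.append(row)
    return pd.DataFrame(rows)
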