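"""Environmental-niche construction and range-overlap metrics.

The analysis follows the COUE (centroid/overlap/unfilling/expansion) scheme:
variables are first ranked by a random-forest permutation importance and the
top k retained; a correlation PCA of the retained variables defines a
two-axis environment space; occurrence and background densities are kernel
smoothed onto a shared grid in that space; and the occupancy of one range is
compared with another through the expansion / stability / unfilling
proportions, with a density quantile delimiting marginal climates.

Importance here is the error increase when a predictor's values are permuted,
measured on an internal held-out split of the presence/background data.  The
reported MAD statistic is the median absolute deviation of the permutation
error increases taken about zero — i.e. the robust magnitude of the error
increase — which is the ordering used to rank variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "OverlapMetrics",
    "OccupancyGrid",
    "PCAxes",
    "rank_variables",
    "select_top",
    "loading_cutoff",
    "fit_pca",
    "occupancy_density",
    "overlap_metrics",
    "marginal_boundary",
    "shared_extent",
]

#: "zero occupancy" guard: density mass below this fraction of the total
ZERO_MASS = 1e-12


# --------------------------------------------------------------------------
# variable ranking


def rank_variables(
    env: pd.DataFrame,
    labels,
    n_trees: int = 500,
    n_repeats: int = 20,
    seed: int = 0,
    holdout: float = 0.3,
) -> pd.DataFrame:
    """Permutation-importance ranking of predictors.

    Fits a presence-vs-background random forest, then permutes each variable
    ``n_repeats`` times on a held-out split and records the increase in
    classification error.  Returns a table with columns ``variable``, ``mad``
    (median absolute error increase, the ordering statistic), ``median``
    (median error increase) and ``rank`` (1 = most important, MAD descending,
    ties broken by variable id).  Constant columns get importance 0 and are
    counted in ``table.attrs['n_constant']``.
    """
    X = env.to_numpy(dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain at least two classes")
    if np.isnan(X).any():
        raise ValueError("environment table contains missing values")
    variables = list(env.columns)
    constant = env.nunique().to_numpy() <= 1

    rng = np.random.default_rng(seed)
    X_fit, X_eval, y_fit, y_eval = train_test_split(
        X, y, test_size=holdout, random_state=int(rng.integers(2**31 - 1)), stratify=y
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
    )
    forest.fit(X_fit, y_fit)
    base_err = 1.0 - forest.score(X_eval, y_eval)

    mads = np.zeros(len(variables))
    medians = np.zeros(len(variables))
    for j, var in enumerate(variables):
        if constant[j]:
            continue
        increases = np.empty(n_repeats)
        X_perm = X_eval.copy()
        for r in range(n_repeats):
            X_perm[:, j] = rng.permutation(X_eval[:, j])
            increases[r] = (1.0 - forest.score(X_perm, y_eval)) - base_err
        X_perm[:, j] = X_eval[:, j]
        mads[j] = np.median(np.abs(increases))  # MAD about zero
        medians[j] = np.median(increases)

    table = pd.DataFrame({"variable": variables, "mad": mads, "median": medians})
    order = table.sort_values(["mad", "variable"], ascending=[False, True], kind="stable")
    table["rank"] = pd.Series(np.arange(1, len(table) + 1), index=order.index)
    table.attrs["n_constant"] = int(constant.sum())
    return table


def select_top(importance: pd.DataFrame, k: int) -> list[str]:
    """Top-k variable ids by rank (stable ties already resolved in ranking)."""
    if not 1 <= k <= len(importance):
        raise ValueError(f"k must be in [1, {len(importance)}]")
    return importance.sort_values("rank").head(k)["variable"].tolist()


def loading_cutoff(k: int) -> float:
    """Rule-of-thumb cutoff sqrt(1/k) for designating high-ranked loadings."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.sqrt(1.0 / k))


# --------------------------------------------------------------------------
# PCA environment space


@dataclass
class PCAxes:
    """Correlation-PCA axes fitted on an environment table."""

    variables: list[str]
    loadings: pd.DataFrame  # p x 2, columns PC1/PC2, unit-norm orthogonal
    explained: np.ndarray  # variance fractions, all components, sums to 1
    scores: np.ndarray  # fitted records projected on (PC1, PC2)
    mean_: np.ndarray
    scale_: np.ndarray
    _components: np.ndarray = field(repr=False, default=None)

    def transform(self, env: pd.DataFrame) -> np.ndarray:
        """Project new records (same variables) onto (PC1, PC2)."""
        X = env[self.variables].to_numpy(dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self._components[:2].T


def fit_pca(env: pd.DataFrame) -> PCAxes:
    """Correlation PCA (standardised variables) with a fixed sign convention.

    Components are ordered by explained variance; the largest-magnitude
    loading of each component is made positive so loadings tables are
    reproducible.  A zero-variance variable raises, naming the variable.
    """
    if len(env) < 3:
        raise ValueError("PCA requires at least 3 rows")
    X = env.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("environment table contains missing values")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(scale == 0)
    if dead.size:
        raise ValueError(f"zero-variance variable: {env.columns[dead[0]]!r}")
    Z = (X - mean) / scale

    pca = PCA(svd_solver="full")
    scores_all = pca.fit_transform(Z)
    components = pca.components_.copy()  # rows = components, unit-norm
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores_all[:, i] = -scores_all[:, i]

    loadings = pd.DataFrame(
        components[:2].T, index=list(env.columns), columns=["PC1", "PC2"]
    )
    return PCAxes(
        variables=list(env.columns),
        loadings=loadings,
        explained=pca.explained_variance_ratio_.copy(),
        scores=scores_all[:, :2],
        mean_=mean,
        scale_=scale,
        _components=components,
    )


# --------------------------------------------------------------------------
# kernel occupancy


@dataclass
class OccupancyGrid:
    """Kernel occupancy of one range on a shared R x R grid in PC space."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    occ_density: np.ndarray  # occurrence kernel density, sums to 1
    bg_density: np.ndarray  # background availability density, sums to 1
    z: np.ndarray  # ratio-corrected occupancy, sums to 1
    availability: np.ndarray  # bool, background mass above the zero guard
    bandwidth: tuple[float, float]


def shared_extent(*score_sets: np.ndarray, pad: float = 0.10) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of pooled scores, padded by ``pad`` per side."""
    pooled = np.vstack([np.asarray(s, float) for s in score_sets])
    lo = pooled.min(axis=0)
    hi = pooled.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo = lo - pad * span
    hi = hi + pad * span
    return float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1])


def _silverman(x: np.ndarray) -> float:
    # d=2 rule: sigma * n^(-1/6)
    return float(np.std(x, ddof=1) * len(x) ** (-1.0 / 6.0))


def _kde_grid(points: np.ndarray, xc: np.ndarray, yc: np.ndarray, bw: tuple[float, float]) -> np.ndarray:
    """Separable Gaussian KDE evaluated on the grid, normalised to sum 1."""
    dx = (xc[None, :] - points[:, 0][:, None]) / bw[0]
    dy = (yc[None, :] - points[:, 1][:, None]) / bw[1]
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    grid = ky.T @ kx  # [iy, ix]
    total = grid.sum()
    if total <= 0:
        raise ValueError("kernel density vanished on the analysis grid")
    return grid / total


def occupancy_density(
    scores: np.ndarray,
    bg_scores: np.ndarray,
    R: int = 100,
    bandwidth: float | tuple[float, float] | None = None,
    extent: tuple[float, float, float, float] | None = None,
) -> OccupancyGrid:
    """Ratio-corrected kernel occupancy of a range in PC space.

    Occurrence and background scores are kernel-smoothed onto a shared R x R
    grid spanning the background extent padded 10% (or an explicit
    ``extent``).  Occupancy is the occurrence density divided by the
    background availability density where the background is positive (0
    elsewhere), renormalised to sum 1 — correcting for unevenly available
    environment.  ``bandwidth`` defaults to Silverman's rule per axis; a
    scalar overrides both axes (required when scores are degenerate).
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    bg_scores = np.atleast_2d(np.asarray(bg_scores, float))
    if R < 10:
        raise ValueError("R must be >= 10")
    if len(scores) < 5:
        raise ValueError("need at least 5 occurrence scores")
    if len(bg_scores) == 0:
        raise ValueError("background scores must be non-empty")

    if bandwidth is None:
        bw = (_silverman(scores[:, 0]), _silverman(scores[:, 1]))
        if min(bw) <= 0:
            raise ValueError(
                "degenerate occurrence scores: bandwidth rule gives 0 "
                "(pass an explicit bandwidth)"
            )
        bw_bg = (_silverman(bg_scores[:, 0]), _silverman(bg_scores[:, 1]))
        if min(bw_bg) <= 0:
            raise ValueError("degenerate background scores")
    else:
        b = (float(bandwidth), float(bandwidth)) if np.isscalar(bandwidth) else tuple(bandwidth)
        if min(b) <= 0:
            raise ValueError("bandwidth must be positive")
        bw = bw_bg = b

    if extent is None:
        extent = shared_extent(bg_scores)
    xmin, xmax, ymin, ymax = extent
    xc = xmin + (np.arange(R) + 0.5) * (xmax - xmin) / R
    yc = ymin + (np.arange(R) + 0.5) * (ymax - ymin) / R

    occ = _kde_grid(scores, xc, yc, bw)
    bg = _kde_grid(bg_scores, xc, yc, bw_bg)
    availability = bg > ZERO_MASS
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(availability, occ / np.where(availability, bg, 1.0), 0.0)
    total = z.sum()
    if total <= 0:
        raise ValueError("occupancy has no mass over the available environment")
    return OccupancyGrid(
        x_centers=xc,
        y_centers=yc,
        occ_density=occ,
        bg_density=bg,
        z=z / total,
        availability=availability,
        bandwidth=bw,
    )


# --------------------------------------------------------------------------
# overlap metrics


@dataclass(frozen=True)
class OverlapMetrics:
    """COUE proportions; expansion + stability = 1 by construction."""

    expansion: float
    stability: float
    unfilling: float

    def __post_init__(self) -> None:
        for name in ("expansion", "stability", "unfilling"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name} = {v} outside [0, 1]")


def overlap_metrics(
    z_native: np.ndarray,
    z_invaded: np.ndarray,
    bg_native: np.ndarray,
    bg_invaded: np.ndarray,
) -> OverlapMetrics:
    """Expansion / stability / unfilling between two occupancy grids.

    Expansion is the share of invaded occupancy (within the environment
    available to both ranges) that falls where native occupancy is zero;
    stability is its complement.  Unfilling is the share of native occupancy
    (within the environment available to the invaded range) falling where
    invaded occupancy is zero.  "Zero" means below 1e-12 of total mass.
    """
    z_native = np.asarray(z_native, float)
    z_invaded = np.asarray(z_invaded, float)
    analysed = np.asarray(bg_native, bool) & np.asarray(bg_invaded, bool)
    if not (z_native.shape == z_invaded.shape == analysed.shape):
        raise ValueError("grids must share shape")
    if z_native.sum() <= 0 or z_invaded.sum() <= 0:
        raise ValueError("all-zero occupancy grid")

    nat_zero = z_native <= ZERO_MASS * z_native.sum()
    inv_zero = z_invaded <= ZERO_MASS * z_invaded.sum()

    inv_mass = z_invaded[analysed].sum()
    if inv_mass <= 0:
        raise ValueError("invaded occupancy has no mass on the shared environment")
    expansion = z_invaded[analysed & nat_zero].sum() / inv_mass

    avail_inv = np.asarray(bg_invaded, bool)
    nat_mass = z_native[avail_inv].sum()
    if nat_mass <= 0:
        raise ValueError("native occupancy has no mass on the invaded environment")
    unfilling = z_native[avail_inv & inv_zero].sum() / nat_mass

    expansion = float(np.clip(expansion, 0.0, 1.0))
    return OverlapMetrics(
        expansion=expansion,
        stability=1.0 - expansion,
        unfilling=float(np.clip(unfilling, 0.0, 1.0)),
    )


def marginal_boundary(density: np.ndarray, q: float = 0.25) -> np.ndarray:
    """Mask of cells at or above the q-quantile of positive density values.

    Delimits marginal climates in the environment space; a larger q gives a
    subset mask.  Ties sit inside the mask (>= threshold).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    density = np.asarray(density, float)
    if not np.isclose(density.sum(), 1.0, atol=1e-6):
        raise ValueError("density must sum to 1")
    positive = density[density > 0]
    if positive.size == 0:
        raise ValueError("density has no positive cells")
    threshold = np.quantile(positive, q)
    return density >= threshold
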