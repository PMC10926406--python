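"""Downscaling, habitation rules, co-habitation and share accounting."""

import numpy as np
import pandas as pd
import pytest

from perilmap.engine import SuitabilitySurface
from perilmap.grids import GridGeometry
from perilmap.overlay import (
    MultiPerilStack,
    cohabitation,
    downscale,
    habitation,
    latitudinal_shares,
    regional_summary,
    risk_categories,
)


def _surface(geom, GI, EI):
    return SuitabilitySurface(
        geom=geom,
        GI=np.asarray(GI, float),
        EI=np.asarray(EI, float),
        generations=np.zeros(geom.shape, int),
        scenario="composite",
    )


@pytest.fixture
def geom22():
    return GridGeometry(lon_min=0.0, lat_min=0.0, n_lon=2, n_lat=2, resolution=600.0)


class TestDownscale:
    def test_children_equal_parent(self, geom22):
        grid = np.array([[1.0, 2.0], [3.0, 4.0]])
        child, fine = downscale(grid, geom22, 2)
        assert child.shape == (4, 4)
        assert fine.resolution == geom22.resolution / 2
        np.testing.assert_array_equal(child[:2, :2], 1.0)
        np.testing.assert_array_equal(child[2:, 2:], 4.0)

    def test_child_areas_sum_to_parent_area(self, geom22):
        _, fine = downscale(np.zeros((2, 2)), geom22, 3)
        parent = geom22.cell_areas_ha()
        child = fine.cell_areas_ha()
        for iy in range(2):
            for ix in range(2):
                block = child[3 * iy : 3 * iy + 3, 3 * ix : 3 * ix + 3]
                assert block.sum() == pytest.approx(parent[iy, ix], rel=1e-12)

    def test_matches_index_mapping_oracle(self):
        geom = GridGeometry(lon_min=-5, lat_min=-5, n_lon=7, n_lat=5, resolution=120.0)
        rng = np.random.default_rng(4)
        grid = rng.normal(size=geom.shape)
        child, _ = downscale(grid, geom, 3)
        for iy in range(child.shape[0]):
            for ix in range(child.shape[1]):
                assert child[iy, ix] == grid[iy // 3, ix // 3]

    def test_non_integer_factor_raises(self, geom22):
        with pytest.raises(ValueError):
            downscale(np.zeros((2, 2)), geom22, 1.5)


class TestHabitationRules:
    def test_stated_rule_and_strict_mode(self, geom22):
        s = _surface(geom22, GI=[[0.0, 30.0], [0.0, 50.0]], EI=[[0.0, 0.0], [0.0, 20.0]])
        np.testing.assert_array_equal(habitation(s), [[False, True], [False, True]])
        np.testing.assert_array_equal(
            habitation(s, persistence_only=True), [[False, False], [False, True]]
        )

    def test_random_surfaces_match_elementwise_rule(self):
        geom = GridGeometry(lon_min=0, lat_min=0, n_lon=10, n_lat=10, resolution=60.0)
        rng = np.random.default_rng(0)
        GI = rng.choice([0.0, 10.0, 60.0], size=geom.shape)
        EI = np.minimum(GI, rng.choice([0.0, 5.0, 60.0], size=geom.shape))
        s = _surface(geom, GI, EI)
        hab = habitation(s)
        for iy in range(10):
            for ix in range(10):
                assert hab[iy, ix] == (GI[iy, ix] > 0 or EI[iy, ix] > 0)


class TestCohabitation:
    def test_extremes(self):
        stack = np.ones((12, 3, 3), bool)
        np.testing.assert_array_equal(cohabitation(stack), 12)
        np.testing.assert_array_equal(cohabitation(np.zeros((12, 3, 3), bool)), 0)

    def test_random_stack_matches_per_cell_loop(self):
        rng = np.random.default_rng(13)
        stack = rng.random((12, 8, 9)) < 0.4
        co = cohabitation(stack)
        for iy in range(8):
            for ix in range(9):
                assert co[iy, ix] == sum(stack[p, iy, ix] for p in range(12))
        assert co.min() >= 0 and co.max() <= 12


class TestRiskCategories:
    @pytest.mark.parametrize(
        "ei,expected",
        [(0.0, 0), (0.1, 1), (4.99, 1), (5.0, 2), (33.9, 2), (34.0, 3), (62.0, 4), (70.0, 4), (100.0, 4)],
    )
    def test_bin_edges_belong_to_upper_category(self, ei, expected):
        assert risk_categories(np.array([ei]))[0] == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            risk_categories(np.array([101.0]))

    def test_partition_is_total(self):
        ei = np.linspace(0, 100, 1001)
        cats = risk_categories(ei)
        assert set(np.unique(cats)) == {0, 1, 2, 3, 4}


def _toy_stack(maize, counts, P, geom, regions=None, faw_ei=None):
    """Build a stack whose co-habitation per cell equals `counts`."""
    shape = geom.shape
    counts = np.asarray(counts)
    hab = np.zeros((P,) + shape, bool)
    for p in range(P):
        hab[p] = counts > p
    if faw_ei is None:
        faw_ei = np.full(shape, 50.0)
    faw = _surface(geom, GI=np.asarray(faw_ei, float), EI=np.asarray(faw_ei, float))
    if regions is None:
        regions = np.full(shape, "R", dtype=object)
    return MultiPerilStack(
        geom=geom,
        habitation=hab,
        pest_names=[f"p{k}" for k in range(P)],
        maize_area=np.asarray(maize, float),
        region_labels=np.asarray(regions, dtype=object),
        faw_surface=faw,
    )


class TestRegionalSummary:
    def test_degenerate_single_count(self, geom22):
        stack = _toy_stack(np.full((2, 2), 10.0), np.full((2, 2), 3), P=11, geom=geom22)
        table = regional_summary(stack)
        row = table[table.region == "R"].iloc[0]
        assert row["k3"] == 100.0
        assert sum(row[f"k{k}"] for k in range(12) if k != 3) == 0.0

    def test_four_cell_hand_toy(self, geom22):
        """Areas 1,2,3,4 ha with counts 0,0,9,10 -> 30/30/40 at k=0/9/10."""
        maize = np.array([[1.0, 2.0], [3.0, 4.0]])
        counts = np.array([[0, 0], [9, 10]])
        stack = _toy_stack(maize, counts, P=11, geom=geom22)
        row = regional_summary(stack).iloc[0]
        assert row["k0"] == 30.0
        assert row["k9"] == 30.0
        assert row["k10"] == 40.0

    def test_shares_sum_to_100_on_random_input(self):
        geom = GridGeometry(lon_min=-30, lat_min=-30, n_lon=12, n_lat=12, resolution=300.0)
        rng = np.random.default_rng(3)
        maize = rng.uniform(0, 100, geom.shape) * (rng.random(geom.shape) < 0.6)
        counts = rng.integers(0, 12, geom.shape)
        regions = np.where(rng.random(geom.shape) < 0.5, "A", "B").astype(object)
        ei = rng.choice([0.0, 40.0], size=geom.shape, p=[0.3, 0.7])
        stack = _toy_stack(maize, counts, P=11, geom=geom, regions=regions, faw_ei=ei)
        table = regional_summary(stack)
        kcols = [f"k{k}" for k in range(12)]
        for _, row in table.iterrows():
            if not np.isnan(row["k0"]):
                assert abs(sum(row[c] for c in kcols) - 100.0) <= 0.2

    def test_invariant_to_region_relabeling_and_cell_order(self):
        geom = GridGeometry(lon_min=0, lat_min=0, n_lon=6, n_lat=6, resolution=300.0)
        rng = np.random.default_rng(9)
        maize = rng.uniform(0, 50, geom.shape)
        counts = rng.integers(0, 5, geom.shape)
        regions = np.where(rng.random(geom.shape) < 0.5, "north", "south").astype(object)
        a = regional_summary(_toy_stack(maize, counts, P=4, geom=geom, regions=regions))
        renamed = np.where(regions == "north", "zzz", "aaa").astype(object)
        b = regional_summary(_toy_stack(maize, counts, P=4, geom=geom, regions=renamed))
        a_row = a[a.region == "north"].drop(columns="region").iloc[0]
        b_row = b[b.region == "zzz"].drop(columns="region").iloc[0]
        pd.testing.assert_series_equal(a_row, b_row, check_names=False)

    def test_unlabeled_maize_cell_raises_with_location(self, geom22):
        regions = np.array([["R", None], ["R", "R"]], dtype=object)
        with pytest.raises(ValueError, match="row 0, col 1"):
            regional_summary(
                _toy_stack(np.full((2, 2), 1.0), np.zeros((2, 2), int), 2, geom22, regions)
            )


class TestLatitudinalShares:
    def test_all_maize_in_one_band(self):
        geom = GridGeometry(lon_min=0, lat_min=0, n_lon=4, n_lat=4, resolution=60.0)
        maize = np.zeros(geom.shape)
        maize[2, :] = 10.0  # lat band [2, 3)
        ei = np.full(geom.shape, 70.0)
        table = latitudinal_shares(ei, maize, geom)
        hot = table[table.lat_south == 2.0].iloc[0]
        assert hot["share"] == pytest.approx(100.0)
        assert hot["q4"] == pytest.approx(100.0)
        assert table["share"].sum() == pytest.approx(100.0)

    def test_tropical_maize_concentrates_q4_at_low_latitudes(self, small_world, small_surface):
        table = latitudinal_shares(small_surface.EI, small_world.maize_area, small_world.geom)
        mid = (table.lat_south + table.lat_north) / 2
        tropical_q4 = table.q4[(mid.abs() < 13)].sum()
        temperate_q4 = table.q4[(mid.abs() > 28)].sum()
        assert tropical_q4 > temperate_q4

    def test_total_share_sums_to_100(self, small_world, small_surface):
        table = latitudinal_shares(small_surface.EI, small_world.maize_area, small_world.geom)
        assert table["share"].sum() == pytest.approx(100.0, abs=0.2)
        assert table[["q1", "q2", "q3", "q4"]].to_numpy().sum() == pytest.approx(100.0, abs=0.2)


def test_downscale_then_summarize_preserves_shares(geom22):
    """Replication downscaling leaves area-weighted shares unchanged."""
    maize = np.array([[1.0, 2.0], [3.0, 4.0]])
    counts = np.array([[0, 0], [9, 10]])
    coarse = regional_summary(_toy_stack(maize, counts, P=11, geom=geom22)).iloc[0]
    fine_geom = geom22.refine(2)
    maize_f, _ = downscale(maize / 4.0, geom22, 2)
    counts_f, _ = downscale(counts, geom22, 2)
    fine = regional_summary(_toy_stack(maize_f, counts_f, P=11, geom=fine_geom)).iloc[0]
    for k in range(12):
        assert fine[f"k{k}"] == coarse[f"k{k}"]
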