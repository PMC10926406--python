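"""Variable ranking, PCA space, kernel occupancy and overlap identities."""

import numpy as np
import pandas as pd
import pytest

from perilmap import niche


def _planted_env(n=400, p_decoys=10, seed=0):
    """Labels generated as a threshold on X plus noise; decoys are pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p_decoys + 1))
    y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
    cols = ["signal"] + [f"decoy{k}" for k in range(p_decoys)]
    return pd.DataFrame(X, columns=cols), y


class TestRankVariables:
    def test_planted_signal_ranked_first(self):
        env, y = _planted_env(seed=3)
        table = niche.rank_variables(env, y, n_trees=200, n_repeats=10, seed=1)
        assert table.set_index("variable").loc["signal", "rank"] == 1

    def test_noise_column_indistinguishable_from_zero(self):
        env, y = _planted_env(seed=5)
        env["noise_twin"] = env["decoy0"].to_numpy()  # duplicated pure-noise column
        table = niche.rank_variables(env, y, n_trees=200, n_repeats=20, seed=2, holdout=0.3)
        m = int(0.3 * len(env))
        bound = 2.576 * np.sqrt(0.25 / m)  # 99% normal bound on an error difference
        med = table.set_index("variable").loc["noise_twin", "median"]
        assert abs(med) <= bound

    def test_deterministic_under_seed(self):
        env, y = _planted_env(seed=7)
        a = niche.rank_variables(env, y, n_trees=100, n_repeats=5, seed=9)
        b = niche.rank_variables(env, y, n_trees=100, n_repeats=5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_column_importance_zero_with_warning_count(self):
        env, y = _planted_env(seed=2)
        env["flat"] = 1.0
        table = niche.rank_variables(env, y, n_trees=100, n_repeats=5, seed=0)
        assert table.set_index("variable").loc["flat", "mad"] == 0.0
        assert table.attrs["n_constant"] == 1

    def test_single_class_rejected(self):
        env, _ = _planted_env(seed=1)
        with pytest.raises(ValueError, match="two classes"):
            niche.rank_variables(env, np.zeros(len(env)), seed=0)


class TestSelectTop:
    def test_all_and_subset(self):
        table = pd.DataFrame(
            {"variable": ["a", "b", "c"], "mad": [0.3, 0.1, 0.2], "median": [0.3, 0.1, 0.2]}
        )
        table["rank"] = table["mad"].rank(ascending=False).astype(int)
        assert niche.select_top(table, 3) == ["a", "c", "b"]
        assert niche.select_top(table, 1) == ["a"]

    def test_mad_tie_broken_lexicographically(self):
        env = pd.DataFrame({"b": [1.0, 2, 3, 4], "a": [1.0, 2, 3, 4], "c": [4.0, 3, 2, 1]})
        y = [0, 0, 1, 1]
        table = niche.rank_variables(env, y, n_trees=50, n_repeats=4, seed=0, holdout=0.5)
        ranks = table.set_index("variable")["rank"]
        tied = table.groupby("mad")["variable"].apply(list)
        for group in tied:
            ordered = sorted(group)
            assert [v for v in table.sort_values("rank").variable if v in group] == ordered

    def test_k_out_of_range(self):
        table = pd.DataFrame({"variable": ["a"], "mad": [0.1], "median": [0.1], "rank": [1]})
        with pytest.raises(ValueError):
            niche.select_top(table, 2)


class TestPCA:
    def test_perfectly_correlated_pair_gives_pc1_everything(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        env = pd.DataFrame({"a": x, "b": 2 * x + 1})
        axes = niche.fit_pca(env)
        assert axes.explained[0] == pytest.approx(1.0)
        assert axes.explained.sum() == pytest.approx(1.0)

    def test_independent_variables_share_variance_equally(self):
        rng = np.random.default_rng(4)
        env = pd.DataFrame(rng.normal(size=(20000, 4)), columns=list("abcd"))
        axes = niche.fit_pca(env)
        np.testing.assert_allclose(axes.explained, 0.25, atol=0.02)

    def test_loadings_match_dense_eigendecomposition(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(300, 3))
        env = pd.DataFrame(
            {
                "a": base[:, 0],
                "b": 0.6 * base[:, 0] + 0.8 * base[:, 1],
                "c": base[:, 2] - 0.3 * base[:, 0],
            }
        )
        axes = niche.fit_pca(env)
        Z = (env - env.mean()) / env.std(ddof=1)
        corr = np.corrcoef(Z.to_numpy().T)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(2):
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(axes.loadings.iloc[:, k].to_numpy(), v, atol=1e-8)
        np.testing.assert_allclose(axes.explained, evals / evals.sum(), atol=1e-8)

    def test_orthonormal_loading_columns(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        L = niche.fit_pca(env).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(2), atol=1e-10)

    def test_zero_variance_variable_named(self):
        env = pd.DataFrame({"ok": [1.0, 2, 3], "dead": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="dead"):
            niche.fit_pca(env)


class TestOccupancy:
    def test_point_mass_concentrates_within_two_bandwidths(self):
        rng = np.random.default_rng(2)
        bg = rng.uniform(-10, 10, size=(2000, 2))
        pts = np.zeros((5, 2))
        bw = 0.5
        occ = niche.occupancy_density(pts, bg, R=200, bandwidth=bw)
        xx, yy = np.meshgrid(occ.x_centers, occ.y_centers)
        # closed form: bivariate Gaussian mass within a k-sigma disc is 1-exp(-k^2/2)
        disc2 = (xx**2 + yy**2) <= (2 * bw) ** 2
        assert occ.occ_density[disc2].sum() == pytest.approx(1 - np.exp(-2), abs=0.02)
        disc3 = (xx**2 + yy**2) <= (3.1 * bw) ** 2
        assert occ.occ_density[disc3].sum() >= 0.99
        assert occ.z[disc3].sum() >= 0.98  # wide uniform background: z tracks occ

    def test_occurrences_like_background_give_flat_occupancy(self):
        rng = np.random.default_rng(6)
        bg = rng.normal(size=(4000, 2))
        pts = rng.normal(size=(2000, 2))
        occ = niche.occupancy_density(pts, bg, R=40, bandwidth=0.6)
        core = occ.bg_density > occ.bg_density.max() * 0.05
        ratio = occ.z[core].max() / occ.z[core].min()
        assert ratio < 5.0

    def test_densities_sum_to_one(self):
        rng = np.random.default_rng(3)
        occ = niche.occupancy_density(
            rng.normal(size=(50, 2)), rng.normal(size=(500, 2)), R=60
        )
        assert occ.occ_density.sum() == pytest.approx(1.0)
        assert occ.bg_density.sum() == pytest.approx(1.0)
        assert occ.z.sum() == pytest.approx(1.0)

    def test_degenerate_and_invalid_inputs(self):
        rng = np.random.default_rng(0)
        bg = rng.normal(size=(100, 2))
        with pytest.raises(ValueError, match="at least 5"):
            niche.occupancy_density(np.zeros((2, 2)), bg)
        with pytest.raises(ValueError, match="degenerate"):
            niche.occupancy_density(np.zeros((6, 2)), bg)  # Silverman bw = 0
        with pytest.raises(ValueError, match="R must be"):
            niche.occupancy_density(rng.normal(size=(10, 2)), bg, R=5)


def _gaussian_grid(R, cx, cy, s, floor=1e-6):
    x = np.linspace(-3, 3, R)
    xx, yy = np.meshgrid(x, x)
    z = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s**2))
    z[z < floor * z.max()] = 0.0
    return z / z.sum()


class TestOverlapMetrics:
    def test_identical_ranges(self):
        z = _gaussian_grid(50, 0, 0, 0.5)
        avail = np.ones_like(z, bool)
        m = niche.overlap_metrics(z, z, avail, avail)
        assert (m.expansion, m.stability, m.unfilling) == (0.0, 1.0, 0.0)

    def test_disjoint_supports(self):
        z1 = np.zeros((20, 20))
        z2 = np.zeros((20, 20))
        z1[:5, :5] = 1.0
        z2[10:, 10:] = 1.0
        z1 /= z1.sum()
        z2 /= z2.sum()
        avail = np.ones_like(z1, bool)
        m = niche.overlap_metrics(z1, z2, avail, avail)
        assert (m.expansion, m.stability, m.unfilling) == (1.0, 0.0, 1.0)

    def test_offset_gaussians_match_cell_sum_oracle(self):
        z_nat = _gaussian_grid(100, -0.8, 0.0, 0.5)
        z_inv = _gaussian_grid(100, 0.8, 0.3, 0.6)
        bg_nat = z_nat >= 0  # full availability
        bg_inv = np.ones_like(z_inv, bool)
        m = niche.overlap_metrics(z_nat, z_inv, bg_nat, bg_inv)
        # brute-force cell loops
        eps_n = 1e-12 * z_nat.sum()
        eps_i = 1e-12 * z_inv.sum()
        num = den = unf_num = unf_den = 0.0
        for i in range(100):
            for j in range(100):
                den += z_inv[i, j]
                if z_nat[i, j] <= eps_n:
                    num += z_inv[i, j]
                unf_den += z_nat[i, j]
                if z_inv[i, j] <= eps_i:
                    unf_num += z_nat[i, j]
        assert m.expansion == pytest.approx(num / den, abs=1e-10)
        assert m.stability == pytest.approx(1 - num / den, abs=1e-10)
        assert m.unfilling == pytest.approx(unf_num / unf_den, abs=1e-10)
        assert m.expansion + m.stability == pytest.approx(1.0, abs=1e-12)
        assert 0 < m.expansion < 1 and 0 < m.unfilling < 1

    def test_scale_invariance_before_renormalisation(self):
        z_nat = _gaussian_grid(40, -0.5, 0, 0.6)
        z_inv = _gaussian_grid(40, 0.5, 0, 0.6)
        avail = np.ones_like(z_nat, bool)
        a = niche.overlap_metrics(z_nat, z_inv, avail, avail)
        b = niche.overlap_metrics(z_nat * 7.3, z_inv * 0.2, avail, avail)
        assert b.expansion == pytest.approx(a.expansion, abs=1e-12)
        assert b.stability == pytest.approx(a.stability, abs=1e-12)
        assert b.unfilling == pytest.approx(a.unfilling, abs=1e-12)

    def test_all_zero_occupancy_raises(self):
        z = _gaussian_grid(20, 0, 0, 0.5)
        avail = np.ones_like(z, bool)
        with pytest.raises(ValueError, match="all-zero"):
            niche.overlap_metrics(np.zeros_like(z), z, avail, avail)


class TestMarginalBoundary:
    def test_uniform_density_keeps_all_positive_cells(self):
        z = np.zeros((10, 10))
        z[2:8, 2:8] = 1.0
        z /= z.sum()
        for q in (0.1, 0.25, 0.5):
            np.testing.assert_array_equal(niche.marginal_boundary(z, q), z > 0)

    def test_small_q_keeps_all_positive_cells(self):
        z = _gaussian_grid(30, 0, 0, 0.8)
        mask = niche.marginal_boundary(z, 1e-9)
        np.testing.assert_array_equal(mask, z > 0)

    def test_mask_shrinks_as_q_rises(self):
        z = _gaussian_grid(50, 0, 0, 0.7)
        areas = [niche.marginal_boundary(z, q).sum() for q in (0.1, 0.25, 0.5)]
        assert areas[0] > areas[1] > areas[2]
        # subset property, not just area
        m1 = niche.marginal_boundary(z, 0.25)
        m2 = niche.marginal_boundary(z, 0.5)
        assert np.all(m1[m2])

    def test_invalid_quantile(self):
        z = _gaussian_grid(20, 0, 0, 0.5)
        for q in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                niche.marginal_boundary(z, q)


def test_loading_cutoff_rule_of_thumb():
    assert niche.loading_cutoff(4) == pytest.approx(0.5)
    assert round(niche.loading_cutoff(13), 2) == 0.28
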