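"""Environmental-space niche densities, overlap metrics and truncation index."""

import numpy as np
import pytest

from thermorange import niche_metrics as nm


def grid_from_z(z, z_env=None):
    z = np.asarray(z, dtype=float)
    z = z / z.sum() if z.sum() > 0 else z
    if z_env is None:
        z_env = np.full_like(z, 1.0 / z.size)
    else:
        z_env = np.asarray(z_env, dtype=float)
        z_env = z_env / z_env.sum()
    edges = np.linspace(0.0, 1.0, z.shape[0] + 1)
    return nm.NicheDensityGrid(z=z, z_env=z_env, x_edges=edges, y_edges=edges)


class TestEnvPCA:
    def test_perfectly_correlated_variables_load_on_pc1(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        data = np.column_stack([x, 2.0 * x + 1.0 + rng.normal(size=200) * 1e-6])
        scores, model = nm.env_pca(data)
        assert model.explained_variance_ratio[0] > 0.999

    def test_scores_match_eigendecomposition_oracle(self):
        data = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 3.0], [5.0, 4.0]])
        scores, model = nm.env_pca(data)
        xs = (data - data.mean(0)) / data.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(xs.T @ xs / (len(data) - 1))
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        oracle = xs @ evecs[:, :2]
        # the decomposition is unique up to per-axis sign; align before comparing
        for k in range(2):
            if np.sign(oracle[0, k]) != np.sign(scores[0, k]):
                oracle[:, k] *= -1
        np.testing.assert_allclose(scores, oracle, atol=1e-10)

    def test_sign_flip_of_input_does_not_change_variance(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(50, 4))
        _, m1 = nm.env_pca(data)
        flipped = data.copy()
        flipped[:, 2] *= -1.0
        _, m2 = nm.env_pca(flipped)
        np.testing.assert_allclose(m1.explained_variance_ratio, m2.explained_variance_ratio, atol=1e-12)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            nm.env_pca(np.ones((10, 3)))

    def test_transform_consistency(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(60, 5))
        scores, model = nm.env_pca(data)
        np.testing.assert_allclose(model.transform(data), scores, atol=1e-10)


class TestDensityGrid:
    def test_density_sums_to_one(self):
        rng = np.random.default_rng(3)
        bg = rng.normal(size=(500, 2))
        occ = rng.normal(size=(60, 2)) * 0.5
        grid = nm.density_grid(bg, occ, resolution=50)
        assert grid.z.sum() == pytest.approx(1.0, abs=1e-9)
        assert grid.z_env.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mode_at_tight_cluster(self):
        rng = np.random.default_rng(4)
        bg = rng.uniform(-1, 1, size=(400, 2))
        occ = np.full((30, 2), 0.5) + rng.normal(scale=0.01, size=(30, 2))
        grid = nm.density_grid(bg, occ, resolution=40)
        idx = np.unravel_index(np.argmax(grid.z), grid.z.shape)
        xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
        assert abs(xc[idx[0]] - 0.5) < 0.1 and abs(yc[idx[1]] - 0.5) < 0.1

    def test_uniform_occurrences_have_flat_corrected_density(self):
        rng = np.random.default_rng(5)
        bg = rng.uniform(0, 1, size=(2000, 2))
        occ = rng.uniform(0.01, 0.99, size=(10_000, 2))
        grid = nm.density_grid(bg, occ, resolution=20)
        ratio = nm._corrected_density(grid)
        inner = ratio[3:-3, 3:-3]
        assert inner.std() / inner.mean() < 0.5

    def test_too_few_occurrences_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            nm.density_grid(rng.normal(size=(100, 2)), rng.normal(size=(4, 2)))

    def test_outside_occurrences_clipped_with_warning(self):
        rng = np.random.default_rng(7)
        bg = rng.uniform(0, 1, size=(200, 2))
        occ = np.vstack([rng.uniform(0, 1, size=(9, 2)), [[5.0, 5.0]]])
        with pytest.warns(UserWarning):
            nm.density_grid(bg, occ, resolution=20)


class TestNicheESU:
    def test_identical_grids(self):
        rng = np.random.default_rng(8)
        z = rng.random((20, 20))
        g = grid_from_z(z)
        m = nm.niche_esu(g, g)
        assert m.expansion == 0.0
        assert m.stability == 1.0
        assert m.unfilling == 0.0

    def test_disjoint_occupied_cells(self):
        z1 = np.zeros((10, 10))
        z2 = np.zeros((10, 10))
        z1[1:4, 1:4] = 1.0
        z2[6:9, 6:9] = 1.0
        m = nm.niche_esu(grid_from_z(z1), grid_from_z(z2))
        assert m.expansion == pytest.approx(1.0)
        assert m.unfilling == pytest.approx(1.0)

    def test_hand_built_grids_match_brute_force(self):
        rng = np.random.default_rng(9)
        z1 = rng.random((10, 10)) ** 3
        z2 = rng.random((10, 10)) ** 3
        g1, g2 = grid_from_z(z1), grid_from_z(z2)
        m = nm.niche_esu(g1, g2)
        # independent cell-by-cell sums
        mask = nm.availability_mask(g1) & nm.availability_mask(g2)
        occ1 = nm.occupied_mask(g1)
        occ2 = nm.occupied_mask(g2)
        num = den = 0.0
        for i in range(10):
            for j in range(10):
                if mask[i, j] and occ2[i, j]:
                    den += g2.z[i, j]
                    if not occ1[i, j]:
                        num += g2.z[i, j]
        assert m.expansion == pytest.approx(num / den, abs=1e-12)
        assert m.expansion + m.stability == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        z1 = np.zeros((6, 6)); z1[0, 0] = 1.0
        z2 = np.zeros((6, 6)); z2[5, 5] = 1.0
        e1 = np.zeros((6, 6)); e1[0, :2] = 1.0
        e2 = np.zeros((6, 6)); e2[5, 4:] = 1.0
        with pytest.raises(ValueError):
            nm.niche_esu(grid_from_z(z1, e1), grid_from_z(z2, e2))


class TestSchoenersD:
    def test_matches_half_sum_complement(self):
        rng = np.random.default_rng(10)
        z1, z2 = rng.random((8, 8)), rng.random((8, 8))
        g1, g2 = grid_from_z(z1), grid_from_z(z2)
        p1 = (g1.z / g1.z_env); p1 /= p1.sum()
        p2 = (g2.z / g2.z_env); p2 /= p2.sum()
        expected = 1.0 - 0.5 * np.abs(p1 - p2).sum()
        assert nm.schoeners_d(g1, g2) == pytest.approx(expected, abs=1e-12)

    def test_identical_distributions_give_one(self):
        g = grid_from_z(np.random.default_rng(11).random((8, 8)))
        assert nm.schoeners_d(g, g) == pytest.approx(1.0)


class TestRandomization:
    def _ranges(self, seed=12, shift=0.0):
        rng = np.random.default_rng(seed)
        bg1 = rng.normal(size=(300, 2))
        bg2 = rng.normal(size=(300, 2)) + shift
        occ1 = rng.normal(scale=0.5, size=(40, 2))
        occ2 = rng.normal(scale=0.5, size=(40, 2)) + shift
        return occ1, occ2, bg1, bg2

    def test_identical_ranges_not_significantly_different(self):
        occ1, occ2, bg1, bg2 = self._ranges(shift=0.0)
        res = nm.niche_randomization_test(occ1, occ2, bg1, bg2, mode="equivalency",
                                          n_reps=99, seed=1, resolution=40)
        assert res.p_value > 0.05

    def test_seeded_determinism(self):
        occ1, occ2, bg1, bg2 = self._ranges()
        a = nm.niche_randomization_test(occ1, occ2, bg1, bg2, mode="similarity",
                                        n_reps=99, seed=3, resolution=30)
        b = nm.niche_randomization_test(occ1, occ2, bg1, bg2, mode="similarity",
                                        n_reps=99, seed=3, resolution=30)
        assert a.p_value == b.p_value and a.d_observed == b.d_observed

    def test_shifted_ranges_detected_as_different(self):
        occ1, occ2, bg1, bg2 = self._ranges(shift=1.5)
        res = nm.niche_randomization_test(occ1, occ2, bg1, bg2, mode="equivalency",
                                          n_reps=99, seed=2, resolution=40)
        assert res.p_value <= 0.05


class TestMetricsInvariance:
    def test_resolution_invariance_on_smooth_densities(self):
        rng = np.random.default_rng(13)
        bg = rng.normal(size=(800, 2))
        occ1 = rng.normal(loc=(-0.5, 0.0), scale=0.6, size=(150, 2))
        occ2 = rng.normal(loc=(0.5, 0.0), scale=0.6, size=(150, 2))
        values = []
        for r in (50, 100, 200):
            g1 = nm.density_grid(bg, occ1, resolution=r)
            g2 = nm.density_grid(bg, occ2, resolution=r)
            m = nm.niche_esu(g1, g2)
            values.append((m.expansion, m.unfilling))
        for a, b in zip(values, values[1:]):
            assert abs(a[0] - b[0]) <= 0.05
            assert abs(a[1] - b[1]) <= 0.05


class TestPNTI:
    def test_interior_occupied_region_scores_zero(self):
        avail = np.ones((12, 12), dtype=bool)
        occ = np.zeros((12, 12), dtype=bool)
        occ[4:8, 4:8] = True
        assert nm.pnti(occ, avail) == 0.0

    def test_occupied_equals_available_scores_one(self):
        avail = np.zeros((12, 12), dtype=bool)
        avail[3:9, 3:9] = True
        assert nm.pnti(avail.copy(), avail) == 1.0

    def test_half_perimeter_case(self):
        # available: left 8 columns; occupied: a 4x4 block whose left edge
        # abuts the availability margin at column 0
        avail = np.zeros((12, 12), dtype=bool)
        avail[:, :8] = True
        occ = np.zeros((12, 12), dtype=bool)
        occ[4:8, 0:4] = True
        # independent count: boundary cells of occ, truncated ones touch
        # outside-available cells (incl. the grid edge)
        boundary = []
        for i in range(12):
            for j in range(12):
                if not occ[i, j]:
                    continue
                nbrs = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
                if any(not (0 <= a < 12 and 0 <= b < 12) or not occ[a, b] for a, b in nbrs):
                    truncated = any(
                        not (0 <= a < 12 and 0 <= b < 12) or not avail[a, b] for a, b in nbrs
                    ) or not avail[i, j]
                    boundary.append(truncated)
        expected = sum(boundary) / len(boundary)
        assert nm.pnti(occ, avail) == pytest.approx(expected)

    def test_empty_occupied_rejected(self):
        with pytest.raises(ValueError):
            nm.pnti(np.zeros((5, 5), dtype=bool), np.ones((5, 5), dtype=bool))
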