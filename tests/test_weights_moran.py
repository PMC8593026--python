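"""Spatial weights and Moran statistics against independent brute-force oracles."""

import numpy as np
import pytest

from urbannpp import (
    build_weights,
    global_morans_i,
    lisa_classify,
    local_morans_i,
    permutation_test_global,
)
from urbannpp.weights import lattice_weights
from conftest import (
    brute_force_global_moran,
    brute_force_local_moran,
    make_lattice_grid,
)


class TestWeights:
    def test_rook_neighbor_counts_on_3x3(self):
        w = lattice_weights(3, 3, scheme="rook", standardization="binary")
        card = w.cardinalities
        assert card[4] == 4                      # center
        assert sorted(card[[0, 2, 6, 8]]) == [2, 2, 2, 2]   # corners

    def test_queen_center_has_eight_neighbors(self):
        w = lattice_weights(3, 3, scheme="queen", standardization="binary")
        assert w.cardinalities[4] == 8

    def test_row_standardized_rows_sum_to_one(self):
        w = lattice_weights(4, 5, scheme="queen", standardization="row")
        np.testing.assert_allclose(np.asarray(w.W.sum(axis=1)).ravel(), 1.0)

    def test_no_self_neighbors(self):
        w = lattice_weights(4, 4)
        assert w.W.diagonal().sum() == 0

    def test_contiguity_symmetric_before_standardization(self):
        w = lattice_weights(5, 4, scheme="queen", standardization="binary")
        assert (w.W != w.W.T).nnz == 0

    def test_knn_weights(self):
        grid = make_lattice_grid(4, 4)
        w = build_weights(grid, scheme="knn", standardization="binary", k=3)
        np.testing.assert_array_equal(w.cardinalities, 3)

    def test_all_isolated_rejected(self):
        grid = make_lattice_grid(1, 3)
        grid.table["row"] = [0, 10, 20]   # rip cells apart on the lattice
        with pytest.raises(ValueError, match="isolated"):
            build_weights(grid, scheme="queen")


class TestGlobalMoran:
    def test_null_expectation(self):
        w = lattice_weights(1, 5, scheme="rook")
        res = global_morans_i([1.0, 3.0, 2.0, 5.0, 4.0], w)
        assert res.E_I == pytest.approx(-0.25)

    def test_checkerboard_is_perfectly_negative(self):
        w = lattice_weights(2, 2, scheme="rook", standardization="row")
        values = np.array([1.0, -1.0, -1.0, 1.0])
        assert global_morans_i(values, w).I == pytest.approx(-1.0, abs=1e-14)

    @pytest.mark.parametrize("scheme", ["queen", "rook"])
    @pytest.mark.parametrize("standardization", ["row", "binary"])
    def test_matches_double_loop_oracle(self, scheme, standardization):
        rng = np.random.default_rng(42)
        for nrows, ncols in [(3, 3), (4, 6), (8, 8)]:
            w = lattice_weights(nrows, ncols, scheme=scheme,
                                standardization=standardization)
            dense = w.W.toarray()
            for _ in range(5):
                y = rng.normal(size=nrows * ncols)
                assert global_morans_i(y, w).I == pytest.approx(
                    brute_force_global_moran(y, dense), abs=1e-10)

    def test_constant_field_rejected(self):
        w = lattice_weights(3, 3)
        with pytest.raises(ValueError, match="zero variance"):
            global_morans_i(np.ones(9), w)

    def test_too_few_cells_rejected(self):
        w = lattice_weights(1, 2, scheme="rook")
        with pytest.raises(ValueError, match="at least 3"):
            global_morans_i([1.0, 2.0], w)

    def test_smooth_field_detected_as_positively_autocorrelated(self):
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(3)
        field = gaussian_filter(rng.normal(size=(15, 15)), sigma=2.0).ravel()
        w = lattice_weights(15, 15)
        res = permutation_test_global(field, w, n_perm=999, seed=0)
        assert res.I > 0
        assert res.p_perm <= 0.01


class TestPermutation:
    def test_extreme_field_hits_permutation_floor(self):
        grid_vals = np.add.outer(np.arange(10.0), np.arange(10.0)).ravel()
        w = lattice_weights(10, 10)
        res = permutation_test_global(grid_vals, w, n_perm=999, seed=1)
        assert res.p_perm == pytest.approx(1 / 1000)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=36)
        w = lattice_weights(6, 6)
        a = permutation_test_global(y, w, n_perm=199, seed=5)
        b = permutation_test_global(y, w, n_perm=199, seed=5)
        assert a.p_perm == b.p_perm and a.perm_mean == b.perm_mean

    def test_permutation_mean_near_null_expectation(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=100)
        w = lattice_weights(10, 10)
        res = permutation_test_global(y, w, n_perm=999, seed=2)
        se = res.perm_sd / np.sqrt(res.n_perm)
        assert abs(res.perm_mean - res.E_I) < 4 * se

    def test_small_n_perm_rejected(self):
        w = lattice_weights(3, 3)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test_global(np.arange(9.0), w, n_perm=10)


class TestLocalMoran:
    def test_sum_identity_with_global(self):
        rng = np.random.default_rng(21)
        for scheme in ("queen", "rook"):
            for std in ("row", "binary"):
                w = lattice_weights(6, 7, scheme=scheme, standardization=std)
                y = rng.normal(size=42)
                res = local_morans_i(y, w, n_perm=99, seed=0)
                I = global_morans_i(y, w).I
                assert np.nansum(res.I_i) == pytest.approx(I * w.W0, abs=1e-8)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(33)
        w = lattice_weights(5, 5)
        y = rng.normal(size=25)
        res = local_morans_i(y, w, n_perm=99, seed=0)
        np.testing.assert_allclose(res.I_i, brute_force_local_moran(y, w.W.toarray()),
                                   rtol=0, atol=1e-10)

    def test_checkerboard_center_value(self):
        w = lattice_weights(3, 3, scheme="rook", standardization="row")
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
        res = local_morans_i(y, w, n_perm=99, seed=0)
        z = y - y.mean()
        s2 = (z ** 2).sum() / 9
        expected = z[4] / s2 * z[[1, 3, 5, 7]].mean()
        assert res.I_i[4] == pytest.approx(expected, abs=1e-12)

    def test_island_cell_flagged_undefined(self):
        grid = make_lattice_grid(1, 4)
        grid.table.loc[3, "row"] = 10     # isolate the last cell
        w = build_weights(grid, scheme="rook")
        res = local_morans_i([1.0, 2.0, 4.0, 8.0], w, n_perm=99, seed=0)
        assert np.isnan(res.I_i[3]) and np.isnan(res.p_i[3])
        classes = lisa_classify(res)
        assert classes[3] == "NS"


class TestLisaClassification:
    def test_quadrant_rules(self):
        from urbannpp.moran import LisaResult
        lisa = LisaResult(
            I_i=np.array([1.0, 1.0, -1.0, -1.0, 0.5]),
            p_i=np.array([0.01, 0.01, 0.01, 0.01, 0.5]),
            z=np.array([2.0, -2.0, -2.0, 2.0, 1.0]),
            lag=np.array([1.5, -1.5, 1.5, -1.5, 1.0]),
            E_i=np.zeros(5), n_perm=99, seed=0,
        )
        np.testing.assert_array_equal(lisa_classify(lisa, alpha=0.05),
                                      ["HH", "LL", "LH", "HL", "NS"])

    def test_p_equal_alpha_is_not_significant(self):
        from urbannpp.moran import LisaResult
        lisa = LisaResult(I_i=np.array([1.0]), p_i=np.array([0.05]),
                          z=np.array([1.0]), lag=np.array([1.0]),
                          E_i=np.zeros(1), n_perm=99, seed=0)
        assert lisa_classify(lisa, alpha=0.05)[0] == "NS"

    def test_core_clusters_on_synthetic_city(self, default_city_grid):
        """LST clusters HH and NPP clusters LL inside the urban core."""
        grid = default_city_grid
        w = build_weights(grid)
        core = grid.table["beta_t1"].to_numpy() > 0.5
        for var, cls in (("lst_t1", "HH"), ("npp_t1", "LL")):
            res = local_morans_i(grid.table[var].to_numpy(), w, n_perm=199, seed=3)
            classes = lisa_classify(res, alpha=0.05)
            share_core = (classes[core] == cls).mean()
            share_out = (classes[~core] == cls).mean()
            assert share_core > 0.5
            assert share_core > share_out
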