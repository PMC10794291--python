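"""LCFSD core: cluster filtering, windows, binning, occupancy, slopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lcfsd import (
    HeightImage,
    LcfsdParams,
    dimension_distribution,
    fit_dimension,
    lcfsd_map,
    occupancy_count,
    remove_small_clusters,
)
from lcfsd.core import extract_connected_window, rescale_and_bin


def brute_force_voxel_count(levels: np.ndarray, L: int) -> int:
    """Independent oracle: materialize the L x L x L cube and count voxels."""
    h = levels.shape[0]
    c, half = h // 2, L // 2
    sub = levels[c - half:c + half + 1, c - half:c + half + 1]
    cube = np.zeros((L, L, L), dtype=bool)
    for a in range(L):
        for b in range(L):
            cube[a, b, : min(int(sub[a, b]), L)] = True
    return int(cube.sum())


class TestParams:
    def test_defaults_match_application_rules(self):
        p = LcfsdParams()
        assert p.h == 17
        assert p.scales == (3, 5, 7, 9, 11, 13, 15, 17)
        assert p.min_cluster_size == 6
        # 17 pixels at 0.369 um/px is the stated 6.3 um window
        assert round(p.window_physical_size, 1) == 6.3

    @pytest.mark.parametrize("kw", [dict(w=0), dict(min_cluster_size=0),
                                    dict(scales=(3, 4)), dict(scales=(19,)),
                                    dict(global_max_F=-1.0),
                                    dict(global_max_F="nope")])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            LcfsdParams(**kw)


class TestHeightImage:
    @pytest.mark.parametrize("bad", [np.full((4, 4), -1.0),
                                     np.full((4, 4), np.nan),
                                     np.zeros((4, 4, 3))])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            HeightImage(bad)


class TestRemoveSmallClusters:
    def test_boundary_of_the_cluster_rule(self):
        img = np.zeros((20, 20))
        img[2, 2:7] = 1.0          # 5-pixel cluster: removed
        img[10, 2:8] = 1.0         # 6-pixel cluster: kept
        out = remove_small_clusters(img, 6)
        assert out[2, 2:7].sum() == 0
        assert np.array_equal(out[10, 2:8], np.ones(6))

    def test_diagonal_pixels_count_as_one_cluster(self):
        img = np.zeros((12, 12))
        for k in range(6):
            img[k, k] = 1.0        # 8-connected diagonal chain of 6
        out = remove_small_clusters(img, 6)
        assert out.sum() == 6.0

    def test_all_zero_image_passes_through(self):
        img = np.zeros((8, 8))
        assert np.array_equal(remove_small_clusters(img, 6), img)


class TestConnectedWindow:
    def test_fully_nonzero_window_is_fully_connected(self):
        img = np.ones((20, 20))
        win = extract_connected_window(img, (10, 10), 8)
        assert win.connected_mask.all()
        assert win.connected_mask.sum() == 289

    def test_isolated_center(self):
        img = np.zeros((20, 20))
        img[10, 10] = 1.0
        win = extract_connected_window(img, (10, 10), 8)
        assert win.connected_mask.sum() == 1
        assert win.connected_mask[8, 8]

    def test_diagonal_neighbor_joins_component(self):
        img = np.zeros((20, 20))
        img[10, 10] = img[11, 11] = 1.0
        win = extract_connected_window(img, (10, 10), 8)
        assert win.connected_mask.sum() == 2

    def test_disconnected_far_pixels_excluded(self):
        img = np.zeros((20, 20))
        img[10, 10] = 1.0
        img[10, 13] = 1.0          # two zero pixels away: not connected
        win = extract_connected_window(img, (10, 10), 8)
        assert win.connected_mask.sum() == 1

    def test_zero_center_and_edge_rejected(self):
        img = np.ones((20, 20))
        img[10, 10] = 0.0
        with pytest.raises(ValueError):
            extract_connected_window(img, (10, 10), 8)
        with pytest.raises(ValueError):
            extract_connected_window(img, (3, 10), 8)


class TestRescaleAndBin:
    def _window(self, value):
        img = np.full((20, 20), value)
        return extract_connected_window(img, (10, 10), 8)

    def test_maximum_maps_to_top_level(self):
        lev = rescale_and_bin(self._window(2.0), F=2.0, h=17)
        assert np.all(lev == 17)

    def test_half_maximum_rounds_up(self):
        lev = rescale_and_bin(self._window(1.0), F=2.0, h=17)
        assert np.all(lev == 9)  # ceil(17 * 0.5) = 9

    def test_background_is_level_zero(self):
        img = np.zeros((20, 20))
        img[10, 10] = 1.0
        win = extract_connected_window(img, (10, 10), 8)
        lev = rescale_and_bin(win, F=1.0, h=17)
        assert lev[8, 8] == 17 and lev.sum() == 17

    def test_F_below_window_max_rejected(self):
        with pytest.raises(ValueError):
            rescale_and_bin(self._window(2.0), F=1.0, h=17)


class TestOccupancyCount:
    def test_filled_cube(self):
        assert occupancy_count(np.full((17, 17), 17), 5) == 125

    def test_flat_sheet(self):
        assert occupancy_count(np.full((17, 17), 1), 5) == 25

    def test_single_column_clipped_at_L(self):
        lev = np.zeros((17, 17), dtype=int)
        lev[8, 8] = 17
        assert occupancy_count(lev, 7) == 7

    def test_even_or_out_of_range_L_rejected(self):
        lev = np.ones((17, 17), dtype=int)
        for L in (4, 1, 19):
            with pytest.raises(ValueError):
                occupancy_count(lev, L)

    def test_matches_brute_force_voxel_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            lev = rng.integers(0, 18, size=(17, 17))
            for L in (3, 5, 7, 9, 11, 13, 15, 17):
                assert occupancy_count(lev, L) == brute_force_voxel_count(lev, L)

    def test_monotone_in_L(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            lev = rng.integers(0, 18, size=(17, 17))
            counts = [occupancy_count(lev, L) for L in (3, 5, 7, 9, 11, 13, 15, 17)]
            assert np.all(np.diff(counts) >= 0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hnp.arrays(np.int64, (17, 17), elements=st.integers(0, 17)),
           st.sampled_from([3, 5, 7, 9, 11, 13, 15, 17]))
    def test_bounds_and_oracle_property(self, lev, L):
        n = occupancy_count(lev, L)
        assert 0 <= n <= L**3
        assert n == brute_force_voxel_count(lev, L)


class TestFitDimension:
    @pytest.mark.parametrize("exponent", [1.0, 2.0, 3.0])
    def test_exact_power_laws(self, exponent):
        L = np.array([3, 5, 7, 9, 11, 13, 15, 17], dtype=float)
        assert fit_dimension(L, L**exponent) == pytest.approx(exponent, abs=1e-12)

    def test_flat_counts_give_zero_slope(self):
        L = np.array([3, 5, 7])
        assert fit_dimension(L, np.array([10, 10, 10])) == pytest.approx(0.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_dimension(np.array([3, 5]), np.array([4, 0]))


class TestLcfsdMap:
    def test_solid_image_has_dimension_three(self):
        m = lcfsd_map(np.full((40, 40), 5.0), LcfsdParams(), F=5.0)
        assert m.valid_mask[8:-8, 8:-8].all()
        assert not m.valid_mask[:8].any()
        assert np.allclose(m.sample, 3.0)

    def test_one_level_image_has_dimension_two(self):
        m = lcfsd_map(np.ones((40, 40)), LcfsdParams(), F=17.0)
        assert np.allclose(m.sample, 2.0)

    def test_isolated_pixels_leave_empty_map(self):
        img = np.zeros((40, 40))
        img[::5, ::5] = 1.0  # all clusters of size 1
        with pytest.warns(UserWarning):
            m = lcfsd_map(img, LcfsdParams())
        assert not m.valid_mask.any()

    def test_engines_agree_on_random_images(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            img = rng.random((48, 48)) * (rng.random((48, 48)) < 0.6)
            a = lcfsd_map(img, LcfsdParams(), engine="numba")
            b = lcfsd_map(img, LcfsdParams(), engine="numpy")
            assert np.array_equal(a.valid_mask, b.valid_mask)
            assert np.allclose(a.dims[a.valid_mask], b.dims[b.valid_mask])

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            lcfsd_map(np.ones((10, 10)), LcfsdParams())

    def test_explicit_F_below_image_max_rejected(self):
        with pytest.raises(ValueError):
            lcfsd_map(np.full((20, 20), 2.0), LcfsdParams(), F=1.0)


class TestDimensionDistribution:
    def test_identical_values_give_single_mode(self):
        d = dimension_distribution(np.full(50, 2.0))
        assert d.mode_count == 1

    def test_bimodal_mixture_detected(self):
        rng = np.random.default_rng(0)
        sample = np.concatenate([rng.normal(1.0, 0.05, 400),
                                 rng.normal(2.5, 0.05, 400)])
        d = dimension_distribution(sample, bandwidth=0.1)
        assert d.mode_count == 2

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        d = dimension_distribution(rng.normal(2.0, 0.3, 500))
        area = np.trapezoid(d.density, d.grid)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            dimension_distribution(np.array([]))
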