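"""Spot detection, region extraction, Pearson statistics, and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from nanomap.correlate import (
    CorrelationParams,
    CorrelationResult,
    RegionOutOfBoundsError,
    ZeroVarianceError,
    cell_correlation,
    condition_summary,
    detect_spots,
    extract_region_pair,
    pearson_r,
    random_region_set,
)


def _gauss_field(shape, centers, amps, sigma=1.5, background=10.0):
    img = np.full(shape, background)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (r, c), a in zip(centers, amps):
        img += a * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
    return img


class TestDetectSpots:
    PX = 0.1

    def test_constant_image_finds_nothing(self):
        img = np.full((64, 64), 5.0)
        params = CorrelationParams(threshold=6.0, threshold_mode="absolute", edge_exclusion_um=0.0)
        spots = detect_spots(img, np.ones((64, 64), bool), params, self.PX)
        assert len(spots) == 0

    def test_default_edge_exclusion_is_two_microns(self):
        assert CorrelationParams().edge_exclusion_um == 2.0

    def test_five_gaussians_found_at_their_centers(self):
        # oracle: per-punctum argmax over a disc around the true center
        centers = [(15, 15), (15, 48), (40, 30), (50, 55), (55, 10)]
        img = _gauss_field((64, 64), centers, [100] * 5)
        params = CorrelationParams(threshold=50.0, threshold_mode="absolute",
                                   edge_exclusion_um=0.0, min_peak_sep_um=0.3)
        spots = detect_spots(img, np.ones((64, 64), bool), params, self.PX)
        assert len(spots) == 5
        for true_c in centers:
            d = np.linalg.norm(spots.coords - np.asarray(true_c), axis=1)
            assert d.min() <= 1.0

    def test_edge_exclusion_enforced_by_distance_transform(self):
        centers = [(5, 32), (32, 32)]  # first one is 5 px = 0.5 um from the edge
        img = _gauss_field((64, 64), centers, [100, 100])
        mask = np.ones((64, 64), bool)
        params = CorrelationParams(threshold=50.0, threshold_mode="absolute",
                                   edge_exclusion_um=1.0)
        spots = detect_spots(img, mask, params, self.PX)
        dist_um = ndimage.distance_transform_edt(np.pad(mask, 1, constant_values=False))[1:-1, 1:-1] * self.PX
        assert len(spots) == 1
        for (r, c), _ in spots:
            assert dist_um[int(r), int(c)] >= 1.0

    def test_min_separation_keeps_brighter_peak(self):
        img = np.zeros((40, 40))
        img[20, 20], img[20, 23] = 80.0, 100.0  # 3 px apart < 5 px separation
        params = CorrelationParams(threshold=10.0, threshold_mode="absolute",
                                   edge_exclusion_um=0.0, min_peak_sep_um=0.5)
        spots = detect_spots(img, np.ones((40, 40), bool), params, self.PX)
        assert len(spots) == 1
        assert tuple(spots.coords[0]) == (20.0, 23.0)

    def test_plateau_broken_by_lowest_row_major_index(self):
        img = np.zeros((20, 20))
        img[10, 10] = img[10, 11] = 50.0  # two-pixel plateau
        params = CorrelationParams(threshold=10.0, threshold_mode="absolute",
                                   edge_exclusion_um=0.0, min_peak_sep_um=0.0)
        spots = detect_spots(img, np.ones((20, 20), bool), params, self.PX)
        assert len(spots) == 1
        assert tuple(spots.coords[0]) == (10.0, 10.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_spots(np.zeros((8, 8)), np.zeros((8, 8), bool), CorrelationParams(), self.PX)

    def test_sorted_by_descending_intensity(self):
        centers = [(10, 10), (10, 40), (40, 10), (40, 40)]
        img = _gauss_field((51, 51), centers, [40, 90, 70, 55])
        params = CorrelationParams(threshold=20.0, threshold_mode="absolute",
                                   edge_exclusion_um=0.0)
        spots = detect_spots(img, np.ones((51, 51), bool), params, self.PX)
        assert np.all(np.diff(spots.intensities) <= 0)


class TestExtractRegion:
    def test_side_arithmetic_forced_odd(self):
        # 4 um at 0.1 um/px = 40 px, rounded up to 41
        assert CorrelationParams(region_size_um=4.0).region_side_px(0.1) == 41
        # 4 um at 0.107 um/px = 37.4 -> 37 (already odd)
        assert CorrelationParams(region_size_um=4.0).region_side_px(0.107) == 37

    def test_matched_coordinates_and_centering(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(100, 100))
        b = rng.uniform(size=(100, 100))
        a[50, 60] = 10.0  # brightest pixel
        params = CorrelationParams(region_size_um=2.0)
        pair = extract_region_pair(a, b, (50, 60), params, 0.1)
        side = params.region_side_px(0.1)
        assert pair.region_A.shape == pair.region_B.shape == (side, side)
        np.testing.assert_array_equal(pair.region_B, b[50 - side // 2 : 50 + side // 2 + 1,
                                                       60 - side // 2 : 60 + side // 2 + 1])
        assert pair.region_A[side // 2, side // 2] == pair.region_A.max()

    def test_border_crossing_is_an_error_not_truncation(self):
        img = np.zeros((50, 50))
        with pytest.raises(RegionOutOfBoundsError):
            extract_region_pair(img, img, (2, 25), CorrelationParams(region_size_um=2.0), 0.1)


class TestPearson:
    def test_self_correlation_and_sign_flip(self, rng):
        x = rng.normal(size=(7, 7))
        assert pearson_r(x, x) == pytest.approx(1.0, abs=1e-12)
        assert pearson_r(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_example(self):
        # direct product-moment evaluation on a 4-point pair gives 0.6
        assert pearson_r(np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3])) == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r(np.ones((5, 5)), np.random.default_rng(0).normal(size=(5, 5)))

    def test_matches_double_loop_oracle_on_random_regions(self, rng):
        for _ in range(20):
            a = rng.normal(size=(5, 5))
            b = rng.normal(size=(5, 5))
            # independent oracle: explicit double-loop product-moment formula
            n = a.size
            ma = sum(a[i, j] for i in range(5) for j in range(5)) / n
            mb = sum(b[i, j] for i in range(5) for j in range(5)) / n
            num = sum((a[i, j] - ma) * (b[i, j] - mb) for i in range(5) for j in range(5))
            da = sum((a[i, j] - ma) ** 2 for i in range(5) for j in range(5))
            db = sum((b[i, j] - mb) ** 2 for i in range(5) for j in range(5))
            expected = num / (da**0.5 * db**0.5)
            assert pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_in_unit_interval(self, seed):
        g = np.random.default_rng(seed)
        a, b = g.normal(size=25), g.normal(size=25)
        assert -1.0 <= pearson_r(a, b) <= 1.0


class TestNullRegions:
    def test_same_seed_reproduces_centers(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(128, 128))
        b = rng.uniform(size=(128, 128))
        mask = np.ones((128, 128), bool)
        params = CorrelationParams(region_size_um=2.0, edge_exclusion_um=1.0)
        s1 = random_region_set(a, b, mask, 10, params, 0.1, seed=42)
        s2 = random_region_set(a, b, mask, 10, params, 0.1, seed=42)
        assert [p.center_px for p in s1] == [p.center_px for p in s2]
        assert all(p.kind == "null" for p in s1)

    def test_null_floor_sits_far_below_spot_correlation(self, simulate_pair):
        # Monte-Carlo over 20 seeds on sparse colocalized fields: the
        # randomized null is a small nonspecific floor (random regions
        # occasionally catch a shared punctum) while spot-centered
        # correlation is large
        spot_means, null_means = [], []
        from nanomap.synthetic import (
            SimulationConfig, make_cell_mask, render_channel_pair, sample_truth_spots,
        )
        for seed in range(20):
            cfg = SimulationConfig(image_shape_px=(512, 512), n_spots=12,
                                   coloc_fraction=0.8, amp_corr=0.8, seed=seed)
            mask = make_cell_mask((512, 512), 0.9, 0.08, seed=seed + 400)
            spots = sample_truth_spots(mask, 12, 2.0, cfg.edge_margin_um,
                                       cfg.pixel_size_um, seed=seed + 500)
            a, b, _ = render_channel_pair(spots, cfg)
            res = cell_correlation(
                a, b, mask,
                CorrelationParams(seed=seed + 600, threshold=180.0, threshold_mode="absolute"),
            )
            spot_means.append(res.mean_r)
            null_means.append(res.null_mean_r)
        assert abs(np.mean(null_means)) < 0.1
        assert np.mean(spot_means) > np.mean(null_means) + 0.3

    def test_no_valid_center_is_explicit_failure(self):
        mask = np.zeros((64, 64), bool)
        mask[30:34, 30:34] = True  # far too small for the edge exclusion
        with pytest.raises(ValueError, match="no valid center"):
            random_region_set(np.zeros((64, 64)), np.zeros((64, 64)), mask, 5,
                              CorrelationParams(), 0.1)


class TestCellCorrelation:
    def test_identical_channels_give_mean_r_one(self, simulate_pair):
        a, _, _, mask = simulate_pair(1.0, 1.0, seed=51, n_spots=40)
        res = cell_correlation(a, a, mask, CorrelationParams(seed=1))
        assert res.n_spots > 10
        assert res.mean_r == pytest.approx(1.0, abs=1e-9)

    def test_null_matches_spot_count(self, simulate_pair):
        a, b, _, mask = simulate_pair(0.5, 0.8, seed=52, n_spots=60)
        res = cell_correlation(a, b, mask, CorrelationParams(seed=2))
        assert len(res.null_per_region_r) == res.n_spots > 0

    def test_edge_exclusion_invariant_on_accepted_spots(self, simulate_pair):
        a, b, _, mask = simulate_pair(0.5, 0.8, seed=53, n_spots=60)
        params = CorrelationParams(seed=3)
        res = cell_correlation(a, b, mask, params)
        dist_um = ndimage.distance_transform_edt(np.pad(mask, 1, constant_values=False))[1:-1, 1:-1] * a.pixel_size_um
        for r, c in res.spot_centers:
            assert dist_um[r, c] >= params.edge_exclusion_um

    def test_all_r_in_unit_interval_and_mean_consistent(self, simulate_pair):
        a, b, _, mask = simulate_pair(0.6, 0.7, seed=54, n_spots=80)
        res = cell_correlation(a, b, mask, CorrelationParams(seed=4))
        assert np.all(res.per_spot_r >= -1) and np.all(res.per_spot_r <= 1)
        assert res.mean_r == pytest.approx(res.per_spot_r.mean())


class TestConditionSummary:
    @staticmethod
    def _result(values, cell_id, condition):
        return CorrelationResult(
            per_spot_r=np.asarray(values, dtype=float),
            null_per_region_r=np.zeros(len(values)),
            cell_id=cell_id,
            condition=condition,
        )

    def test_printed_mean_worked_example(self):
        # two condition means of 0.36 and 0.15 give a 2.4-fold change
        results = [self._result([0.36], "c1", "EGF"), self._result([0.15], "c2", "Ctrl")]
        table, folds = condition_summary(results)
        assert folds["EGF_vs_Ctrl"] == pytest.approx(2.4)

    def test_identical_conditions_fold_one(self):
        results = [self._result([0.5, 0.5], "c1", "A"), self._result([0.5, 0.5], "c2", "B")]
        _, folds = condition_summary(results)
        assert folds["A_vs_B"] == pytest.approx(1.0)

    def test_cell_is_the_aggregation_unit(self):
        # two cells with very different spot counts contribute equally
        results = [
            self._result([1.0] * 100, "big", "X"),
            self._result([0.0], "small", "X"),
        ]
        table, _ = condition_summary(results)
        assert table.loc["X", "mean_r"] == pytest.approx(0.5)  # not the pooled 100/101
        assert table.loc["X", "pooled_mean_r"] == pytest.approx(100 / 101)
        assert table.loc["X", "n_cells"] == 2 and table.loc["X", "n_spots"] == 101

    def test_empty_cells_are_excluded(self):
        empty = CorrelationResult(per_spot_r=np.empty(0), null_per_region_r=np.empty(0),
                                  cell_id="e", condition="X")
        results = [self._result([0.4, 0.6], "c", "X"), empty]
        table, _ = condition_summary(results)
        assert table.loc["X", "n_cells"] == 1

    def test_all_empty_is_an_error(self):
        empty = CorrelationResult(per_spot_r=np.empty(0), null_per_region_r=np.empty(0))
        with pytest.raises(ValueError):
            condition_summary([empty])
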