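"""Structure areas, occupancy, size summaries, and fold changes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nanomap.morphometry import (
    SegmentationMask,
    fold_change,
    occupancy_percent,
    round_sig,
    size_summary,
    structure_areas,
)
from nanomap.synthetic import ClassParams, StructureSimConfig, make_structure_mask


def _flood_fill_components(binary):
    """Independent 8-connectivity oracle: iterative flood fill."""
    visited = np.zeros_like(binary, dtype=bool)
    comps = []
    h, w = binary.shape
    for i in range(h):
        for j in range(w):
            if binary[i, j] and not visited[i, j]:
                stack, comp = [(i, j)], 0
                visited[i, j] = True
                while stack:
                    r, c = stack.pop()
                    comp += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not visited[rr, cc]:
                                visited[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return sorted(comps)


class TestStructureAreas:
    def test_area_scale_arithmetic(self):
        # 10,000 px component at 1.2 nm/px -> 14,400 nm^2
        labels = np.ones((150, 150), dtype=np.uint8)
        labels[10:110, 10:110] = 2  # 100x100 = 10,000 px flat structure
        rec = structure_areas(SegmentationMask(labels, nm_per_px=1.2))
        assert len(rec) == 1
        assert rec.area_px.iloc[0] == 10_000
        assert rec.area_nm2.iloc[0] == pytest.approx(14_400.0)

    def test_empty_mask_empty_records(self):
        rec = structure_areas(SegmentationMask(np.ones((20, 20), dtype=np.uint8)))
        assert rec.empty

    def test_diagonal_blobs_merge_under_8_connectivity(self):
        labels = np.ones((20, 20), dtype=np.uint8)
        labels[5:8, 5:8] = 2
        labels[8:11, 8:11] = 2  # touches only at the (7,7)/(8,8) corner
        rec = structure_areas(SegmentationMask(labels))
        assert len(rec) == 1
        assert sorted(rec.area_px) == _flood_fill_components(labels == 2)

    def test_mixed_classes_against_flood_fill_oracle(self, rng):
        labels = np.ones((60, 60), dtype=np.uint8)
        for label in (2, 3, 4):
            for _ in range(3):
                r, c = rng.integers(2, 50, 2)
                labels[r : r + rng.integers(2, 6), c : c + rng.integers(2, 6)] = label
        rec = structure_areas(SegmentationMask(labels))
        for label, cls in [(2, "flat"), (3, "dome"), (4, "sphere")]:
            got = sorted(rec.loc[rec.class_name == cls, "area_px"])
            assert got == _flood_fill_components(labels == label)

    def test_class_outside_membrane_footprint_rejected(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[2:4, 2:4] = 2
        membrane = np.zeros((10, 10), bool)  # structures not on the membrane
        with pytest.raises(ValueError, match="outside the membrane"):
            SegmentationMask(labels, membrane_mask=membrane)


class TestOccupancy:
    def test_no_structures_zero_percent(self):
        occ = occupancy_percent(SegmentationMask(np.ones((30, 30), dtype=np.uint8)))
        row = occ.iloc[0]
        assert row.occupancy_flat == row.occupancy_dome == row.occupancy_sphere == 0.0
        assert row.occupancy_all == 0.0

    def test_half_membrane_is_fifty_percent(self):
        labels = np.ones((10, 10), dtype=np.uint8)
        labels[:5, :] = 2
        assert occupancy_percent(SegmentationMask(labels)).iloc[0].occupancy_flat == pytest.approx(50.0)

    def test_pixel_count_oracle(self):
        labels = np.ones((100, 100), dtype=np.uint8)
        labels[:25, :10] = 2  # 250 flat px over 10,000 membrane px
        assert occupancy_percent(SegmentationMask(labels)).iloc[0].occupancy_flat == pytest.approx(2.5)

    def test_conservation_and_bounds(self, rng):
        labels = np.ones((80, 80), dtype=np.uint8)
        flat_idx = rng.choice(6400, size=500, replace=False)
        labels.ravel()[flat_idx[:300]] = 2
        labels.ravel()[flat_idx[300:450]] = 3
        labels.ravel()[flat_idx[450:]] = 4
        row = occupancy_percent(SegmentationMask(labels)).iloc[0]
        total = row.occupancy_flat + row.occupancy_dome + row.occupancy_sphere
        assert row.occupancy_all == pytest.approx(total)
        for v in (row.occupancy_flat, row.occupancy_dome, row.occupancy_sphere, row.occupancy_all):
            assert 0.0 <= v <= 100.0

    def test_zero_membrane_is_explicit_failure(self):
        with pytest.raises(ValueError, match="membrane"):
            occupancy_percent(SegmentationMask(np.zeros((10, 10), dtype=np.uint8)))

    def test_generator_round_trip_is_exact(self):
        cfg = StructureSimConfig(
            membrane_area_px=120_000,
            flat=ClassParams(3, 1_500.0, 0.3),
            dome=ClassParams(2, 1_000.0, 0.3),
            sphere=ClassParams(2, 600.0, 0.3),
            seed=7,
        )
        mask, truth = make_structure_mask(cfg)
        seg = SegmentationMask(mask, nm_per_px=cfg.nm_per_px)
        rec = structure_areas(seg)
        assert sorted(rec.area_px) == sorted(truth.area_px)
        membrane_area = int((mask >= 1).sum())
        expected_flat = 100.0 * truth.loc[truth.class_name == "flat", "area_px"].sum() / membrane_area
        assert occupancy_percent(seg).iloc[0].occupancy_flat == pytest.approx(expected_flat, abs=1e-12)


class TestSizeSummary:
    def test_single_record_ci_undefined(self):
        rec = pd.DataFrame({"class_name": ["flat"], "condition": ["ctrl"], "area_nm2": [123.0]})
        row = size_summary(rec).iloc[0]
        assert row["median"] == row["mean"] == 123.0
        assert math.isnan(row.ci95_lo) and math.isnan(row.ci95_hi)

    def test_permutation_invariance(self, rng):
        v = rng.lognormal(10, 0.4, 50)
        rec = pd.DataFrame({"class_name": "flat", "condition": "ctrl", "area_nm2": v})
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(size_summary(rec), size_summary(shuffled))

    def test_ci_matches_t_formula(self, rng):
        # oracle: mean +/- t_{0.975, n-1} * SE evaluated directly
        v = rng.lognormal(10, 0.3, 100)
        rec = pd.DataFrame({"class_name": "flat", "condition": "x", "area_nm2": v})
        row = size_summary(rec).iloc[0]
        se = v.std(ddof=1) / math.sqrt(len(v))
        tcrit = sps.t.ppf(0.975, len(v) - 1)
        assert row.ci95_lo == pytest.approx(v.mean() - tcrit * se, abs=1e-9)
        assert row.ci95_hi == pytest.approx(v.mean() + tcrit * se, abs=1e-9)


class TestFoldChange:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [(3.2, 0.66, 4.8), (3.2, 1.48, 2.2), (0.36, 0.15, 2.4)],
    )
    def test_worked_examples_round_to_two_sig_figs(self, treated, control, expected):
        assert fold_change(treated, control).rounded == pytest.approx(expected)

    def test_identity(self):
        fc = fold_change(0.7, 0.7)
        assert fc.raw == fc.rounded == 1.0 and fc.direction == "unchanged"

    def test_direction_recorded(self):
        assert fold_change(1.0, 2.0).direction == "decrease"
        assert fold_change(2.0, 1.0).direction == "increase"

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)
        with pytest.raises(ValueError):
            fold_change(1.0, -2.0)

    def test_round_sig(self):
        assert round_sig(4.848, 2) == 4.8
        assert round_sig(0.0123, 2) == 0.012
        assert round_sig(987.0, 2) == 990.0
        assert round_sig(0.0, 2) == 0.0


class TestScaleInvariance:
    def test_upsampling_preserves_occupancy_and_area(self):
        labels = np.ones((40, 40), dtype=np.uint8)
        labels[10:20, 10:18] = 2
        k = 3
        up = np.kron(labels, np.ones((k, k), dtype=np.uint8))
        base = SegmentationMask(labels, nm_per_px=1.2)
        fine = SegmentationMask(up, nm_per_px=1.2 / k)
        assert occupancy_percent(base).iloc[0].occupancy_flat == pytest.approx(
            occupancy_percent(fine).iloc[0].occupancy_flat
        )
        assert structure_areas(base).area_nm2.iloc[0] == pytest.approx(
            structure_areas(fine).area_nm2.iloc[0]
        )
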