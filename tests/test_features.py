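"""Tests of morphological, intensity, texture and temporal features."""

import math

import numpy as np
import pandas as pd
import pytest
from helpers import disk_mask, glcm_oracle, make_disk_frame
from hypothesis import given, settings
from hypothesis import strategies as st

from spheroscreen.features import (
    aggregate_multi_spheroid,
    build_feature_table,
    compute_area,
    compute_circularity,
    compute_glcm_features,
    compute_mean_gray,
    compute_solidity,
    compute_temporal_features,
)


class TestArea:
    def test_single_pixel_unit_scale(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert compute_area(mask, 1.0) == 1.0

    def test_hundred_pixels_at_published_scale(self):
        mask = np.zeros((10, 12), bool)
        mask[:10, :10] = True
        assert compute_area(mask, 3.26) == pytest.approx(100 * 3.26**2)

    def test_disk_area_close_to_pi_r_squared(self):
        mask = disk_mask((128, 128), (64, 64), 50)
        assert compute_area(mask, 1.0) == pytest.approx(math.pi * 50**2, rel=0.05)

    def test_bad_pixel_size_raises(self):
        with pytest.raises(ValueError):
            compute_area(np.ones((2, 2), bool), 0.0)


class TestCircularity:
    def test_disk_close_to_one(self):
        assert compute_circularity(disk_mask((128, 128), (64, 64), 50)) == pytest.approx(
            1.0, abs=0.1
        )

    def test_square_close_to_pi_over_4(self):
        mask = np.zeros((80, 80), bool)
        mask[10:70, 10:70] = True
        assert compute_circularity(mask) == pytest.approx(math.pi / 4, abs=0.1)

    def test_bar_below_square(self):
        bar = np.zeros((5, 110), bool)
        bar[2, 5:105] = True
        square = np.zeros((80, 80), bool)
        square[10:70, 10:70] = True
        assert compute_circularity(bar) < compute_circularity(square)

    def test_disk_most_circular_among_equal_area_shapes(self):
        disk = disk_mask((128, 128), (64, 64), 40)
        square = np.zeros((128, 128), bool)
        s = int(round(math.sqrt(disk.sum())))
        square[:s, :s] = True
        ellipse = np.zeros((128, 192), bool)
        yy, xx = np.mgrid[0:128, 0:192]
        ellipse[((yy - 64) / 20.0) ** 2 + ((xx - 96) / 80.0) ** 2 <= 1] = True
        c_disk = compute_circularity(disk)
        assert c_disk > compute_circularity(square)
        assert c_disk > compute_circularity(ellipse)


class TestSolidity:
    def test_convex_disk_is_one(self):
        assert compute_solidity(disk_mask((128, 128), (64, 64), 50)) == pytest.approx(
            1.0, abs=0.02
        )

    def test_plus_sign_matches_hull_geometry(self):
        # plus of 5 squares (side s): convex hull is the 3s x 3s square minus
        # 4 corner triangles of area s^2/2 -> hull area 7 s^2, solidity 5/7
        s = 20
        mask = np.zeros((3 * s + 2, 3 * s + 2), bool)
        mask[s : 2 * s, :] = True
        mask[:, s : 2 * s] = True
        mask = mask[: 3 * s, : 3 * s]
        assert compute_solidity(mask) == pytest.approx(5 / 7, abs=0.03)

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            mask = np.zeros((40, 40), bool)
            pts = rng.integers(5, 35, size=(40, 2))
            mask[pts[:, 0], pts[:, 1]] = True
            assert compute_solidity(mask) <= 1.0 + 1e-12


class TestMeanGray:
    def test_uniform_image_is_zero(self):
        frame = np.full((64, 64), 99.0)
        mask = disk_mask((64, 64), (32, 32), 20)
        assert compute_mean_gray(frame, mask) == pytest.approx(0.0)

    def test_dark_disk_hand_value(self):
        mask = disk_mask((128, 128), (64, 64), 30)
        frame = np.where(mask, 40.0, 200.0)
        assert compute_mean_gray(frame, mask, edge_erosion_px=0) == pytest.approx(-160.0)

    def test_shift_invariant(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(0, 255, (64, 64))
        mask = disk_mask((64, 64), (32, 32), 15)
        a = compute_mean_gray(frame, mask)
        b = compute_mean_gray(frame + 37.5, mask)
        assert a == pytest.approx(b)

    def test_erosion_fallback_on_tiny_mask(self, caplog):
        mask = np.zeros((32, 32), bool)
        mask[10:12, 10:12] = True
        frame = np.where(mask, 10.0, 50.0)
        with caplog.at_level("WARNING"):
            val = compute_mean_gray(frame, mask, edge_erosion_px=3)
        assert val == pytest.approx(-40.0)


class TestGlcm:
    def test_hand_enumerated_two_by_two(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        h, e, c = compute_glcm_features(img, levels=2, angles=(0,))
        assert (h, e, c) == (pytest.approx(1.0), pytest.approx(0.5), pytest.approx(1.0))

    def test_constant_region_convention(self):
        h, e, c = compute_glcm_features(np.full((6, 6), 3.0))
        assert (h, e, c) == (1.0, 1.0, 0.0)

    def test_matrix_normalization_via_oracle_parity(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            img = rng.integers(0, 256, (12, 12)).astype(float)
            mask = disk_mask((12, 12), (6, 6), 5)
            got = compute_glcm_features(img, mask, levels=8)
            want = glcm_oracle(img, mask, levels=8)
            assert got == pytest.approx(want, abs=1e-12)

    def test_too_small_region_is_missing(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 3] = True
        out = compute_glcm_features(np.zeros((8, 8)), mask)
        assert all(math.isnan(v) for v in out)


class TestAggregation:
    def test_single_record_identity(self):
        rec = {"area": 100.0, "diameter": 11.3, "circularity": 0.9, "mean_gray": -50.0}
        assert aggregate_multi_spheroid([rec]) == rec

    def test_two_equal_areas(self):
        recs = [{"area": 100.0, "diameter": 0.0, "circularity": 0.8},
                {"area": 100.0, "diameter": 0.0, "circularity": 1.0}]
        out = aggregate_multi_spheroid(recs)
        assert out["area"] == pytest.approx(2 ** (2 / 3) * 100.0)
        assert out["circularity"] == pytest.approx(0.9)
        assert out["diameter"] == pytest.approx(2 * math.sqrt(out["area"] / math.pi))

    def test_three_unit_areas(self):
        recs = [{"area": 1.0, "diameter": 0.0}] * 3
        assert aggregate_multi_spheroid(recs)["area"] == pytest.approx(3 ** (2 / 3))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_multi_spheroid([])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        areas=st.lists(st.floats(1.0, 1e4), min_size=1, max_size=5),
        k=st.floats(0.1, 10.0),
    )
    def test_fusion_properties(self, areas, k):
        recs = [{"area": a} for a in areas]
        fused = aggregate_multi_spheroid(recs)["area"]
        assert fused >= max(areas) * (1 - 1e-9)
        if len(areas) == 1:
            assert fused == pytest.approx(sum(areas))
        scaled = aggregate_multi_spheroid([{"area": k * a} for a in areas])["area"]
        assert scaled == pytest.approx(k * fused, rel=1e-9)


class TestTemporal:
    def test_identical_records_zero_deltas(self):
        rec = {"mean_gray": -50.0, "area": 1000.0}
        out = compute_temporal_features({0.0: rec, 24.0: rec, 48.0: rec})
        assert all(v == 0.0 for v in out.values())

    def test_growth_and_delta_hand_values(self):
        out = compute_temporal_features(
            {
                0.0: {"mean_gray": -50.0, "area": 1000.0},
                24.0: {"mean_gray": -80.0, "area": 1200.0},
                48.0: {"mean_gray": -90.0, "area": 1500.0},
            }
        )
        assert out["growth_48_0"] == pytest.approx(0.5)
        assert out["delta_gray_24_0"] == pytest.approx(-30.0)
        assert out["delta_gray_48_24"] == pytest.approx(-10.0)

    def test_missing_timepoint_marks_nan(self):
        out = compute_temporal_features({0.0: {"mean_gray": -50.0, "area": 1000.0}})
        assert math.isnan(out["delta_gray_24_0"])


class TestBuildFeatureTable:
    @staticmethod
    def _features(n=10):
        rows = []
        for i in range(n):
            rows.append(
                {
                    "spheroid_id": f"s{i}",
                    "experiment_id": "exp1",
                    "concentration_um": 1.0,
                    "area_0h": 100.0,
                    "area_24h": 110.0 if i > 0 else np.nan,  # s0 misses 24 h
                    "area_48h": 120.0,
                }
            )
        return pd.DataFrame(rows)

    @staticmethod
    def _labels(n=10):
        return pd.DataFrame(
            {"spheroid_id": [f"s{i}" for i in range(n)],
             "class2": ["high" if i % 2 else "low" for i in range(n)]}
        )

    def test_missing_24h_row_excluded(self):
        table = build_feature_table(
            self._features(), self._labels(),
            selected_features=["area_0h", "area_24h", "area_48h"],
        )
        assert len(table.data) == 9

    def test_restricting_to_0_and_48h_keeps_all_rows(self):
        table = build_feature_table(
            self._features(), self._labels(),
            selected_features=["area_0h", "area_48h"],
        )
        assert len(table.data) == 10

    def test_empty_labels_raise(self):
        with pytest.raises(ValueError):
            build_feature_table(self._features(), self._labels(0))
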