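import numpy as np
import pytest

from woundquant import morpho, synth
from woundquant.detect import DetectionParams
from woundquant.roi import RegionOfInterest


@pytest.fixture(scope="module")
def shapes():
    return synth.shape_gallery()


class TestCellShapeMetrics:
    def test_disk_circularity_near_one(self, shapes):
        df = morpho.cell_shape_metrics(shapes["disk_r30"], 1.0)
        assert 0.95 <= df.circularity.iloc[0] <= 1.0
        assert df.area_um2.iloc[0] == pytest.approx(np.pi * 30**2, rel=0.02)

    def test_square_circularity_near_pi_over_four(self, shapes):
        df = morpho.cell_shape_metrics(shapes["square_40"], 1.0)
        assert 0.70 <= df.circularity.iloc[0] <= 0.85

    def test_elongated_bars_decreasing_circularity(self, shapes):
        circs = [
            morpho.cell_shape_metrics(shapes[f"bar_3x{k}"], 1.0).circularity.iloc[0]
            for k in (10, 20, 40)
        ]
        assert all(a > b for a, b in zip(circs, circs[1:]))

    def test_disk_maximizes_circularity_at_fixed_area(self, shapes):
        disk = morpho.cell_shape_metrics(shapes["disk_r30"], 1.0).circularity.iloc[0]
        others = [
            morpho.cell_shape_metrics(shapes[k], 1.0).circularity.iloc[0]
            for k in ("square_40", "bar_3x20", "bar_3x40")
        ]
        assert all(disk > o for o in others)

    def test_roi_restricts_cells_and_area_calibrated(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[5:10, 5:10] = 1
        labels[25:30, 25:30] = 2
        roi = RegionOfInterest(kind="circle", center_um=(15.0, 15.0), radius_um=12.0)
        df = morpho.cell_shape_metrics(labels, 2.0, roi)
        assert df.cell_id.tolist() == [1]
        assert df.area_um2.iloc[0] == 25 * 4.0

    def test_circularity_clamped_to_one(self, shapes):
        for name, mask in shapes.items():
            df = morpho.cell_shape_metrics(mask, 1.0)
            assert (df.circularity <= 1.0).all()


class TestHighFluorescenceVolume:
    ref = RegionOfInterest(kind="circle", center_um=(10.0, 10.0), radius_um=6.0)
    wound = RegionOfInterest(kind="circle", center_um=(40.0, 40.0), radius_um=10.0)

    def test_uniform_image_zero_volume(self):
        stack = np.full((4, 56, 56), 50.0)
        v = morpho.high_fluorescence_volume(stack, (1, 1, 1), self.ref, self.wound, 2.0)
        assert v == 0.0

    def test_bright_wound_full_volume(self):
        stack = np.full((4, 56, 56), 50.0)
        wmask = self.wound.mask((56, 56), (1, 1))
        stack[:, wmask] = 150.0
        v = morpho.high_fluorescence_volume(stack, (1, 1, 1), self.ref, self.wound, 2.0)
        assert v == 4 * int(wmask.sum())

    def test_matches_voxel_oracle_on_random_scene(self):
        rng = np.random.default_rng(9)
        stack = rng.uniform(0, 200, size=(3, 56, 56))
        thr = 2.0 * stack[:, self.ref.mask((56, 56), (1, 1))].mean()
        wmask = np.broadcast_to(self.wound.mask((56, 56), (1, 1)), stack.shape)
        oracle = int(np.sum((stack >= thr) & wmask))
        v = morpho.high_fluorescence_volume(stack, (1, 1, 1), self.ref, self.wound, 2.0)
        assert v == oracle

    def test_monotone_nonincreasing_in_factor(self):
        rng = np.random.default_rng(10)
        stack = rng.uniform(0, 200, size=(3, 56, 56))
        vols = [
            morpho.high_fluorescence_volume(stack, (1, 1, 1), self.ref, self.wound, f)
            for f in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_empty_reference_rejected(self):
        far = RegionOfInterest(kind="circle", center_um=(999.0, 999.0), radius_um=2.0)
        with pytest.raises(ValueError):
            morpho.high_fluorescence_volume(
                np.ones((2, 8, 8)), (1, 1, 1), far, self.wound, 2.0
            )


class TestPigmentation:
    def test_uniform_bright_field_zero_percent(self):
        roi = RegionOfInterest(kind="circle", center_um=(32.0, 32.0), radius_um=20.0)
        stack = np.full((3, 64, 64), 200.0)
        assert morpho.pigmentation_percent(stack, roi) == 0.0

    def test_half_covered_roi_within_two_points(self):
        pg = synth.pigment_scene(seed=5)
        roi = RegionOfInterest(
            kind="circle",
            center_um=tuple(map(float, pg["roi_center_px"])),
            radius_um=pg["roi_radius_px"],
        )
        pct = morpho.pigmentation_percent(pg["stack"], roi)
        assert pct == pytest.approx(pg["true_percent"], abs=2.0)

    @pytest.mark.parametrize("focus_slice", [0, 2, 4])
    def test_invariant_to_focus_slice(self, focus_slice):
        pg = synth.pigment_scene(seed=5, focus_slice=focus_slice)
        roi = RegionOfInterest(
            kind="circle",
            center_um=tuple(map(float, pg["roi_center_px"])),
            radius_um=pg["roi_radius_px"],
        )
        pct = morpho.pigmentation_percent(pg["stack"], roi)
        assert pct == pytest.approx(pg["true_percent"], abs=2.0)

    def test_empty_roi_rejected(self):
        roi = RegionOfInterest(kind="circle", center_um=(500.0, 500.0), radius_um=3.0)
        with pytest.raises(ValueError):
            morpho.pigmentation_percent(np.ones((2, 16, 16)), roi)


class TestIntensityRatio:
    def _rois(self, fr):
        t = RegionOfInterest(
            kind="circle",
            center_um=tuple(map(float, fr["target_center_px"])),
            radius_um=fr["roi_radius_px"] - 2,
        )
        c = RegionOfInterest(
            kind="circle",
            center_um=tuple(map(float, fr["control_center_px"])),
            radius_um=fr["roi_radius_px"] - 2,
        )
        return t, c

    def test_identical_rois_ratio_one(self):
        img = np.random.default_rng(3).uniform(10, 100, (64, 64))
        roi = RegionOfInterest(kind="circle", center_um=(32.0, 32.0), radius_um=10.0)
        assert morpho.intensity_ratio(img, roi, roi).ratio == pytest.approx(1.0)

    def test_fracture_fixture_ratio_two_exact(self):
        fr = synth.fracture_pair_scene(ratio=2.0)
        t, c = self._rois(fr)
        assert morpho.intensity_ratio(fr["image"], t, c).ratio == pytest.approx(2.0)

    def test_swapping_rois_inverts_ratio(self):
        img = np.random.default_rng(4).uniform(10, 100, (64, 64))
        a = RegionOfInterest(kind="circle", center_um=(20.0, 20.0), radius_um=8.0)
        b = RegionOfInterest(kind="circle", center_um=(44.0, 44.0), radius_um=8.0)
        r = morpho.intensity_ratio(img, a, b).ratio
        assert morpho.intensity_ratio(img, b, a).ratio == pytest.approx(1.0 / r)

    def test_scale_invariant_under_global_multiplication(self):
        fr = synth.fracture_pair_scene(ratio=2.0)
        t, c = self._rois(fr)
        r1 = morpho.intensity_ratio(fr["image"], t, c).ratio
        r2 = morpho.intensity_ratio(3.7 * fr["image"], t, c).ratio
        assert r2 == pytest.approx(r1)

    def test_zero_control_rejected(self):
        img = np.zeros((32, 32))
        img[4:8, 4:8] = 10
        t = RegionOfInterest(kind="circle", center_um=(6.0, 6.0), radius_um=2.0)
        c = RegionOfInterest(kind="circle", center_um=(24.0, 24.0), radius_um=2.0)
        with pytest.raises(ValueError):
            morpho.intensity_ratio(img, t, c)


class TestStainPositivePercent:
    roi = RegionOfInterest(kind="circle", center_um=(32.0, 32.0), radius_um=20.0)

    def test_blank_image_zero_percent(self):
        pct = morpho.stain_positive_percent(
            np.zeros((64, 64)), self.roi, DetectionParams(threshold_floor=10.0)
        )
        assert pct == 0.0

    def test_fully_stained_roi_hundred_percent(self):
        img = np.full((64, 64), 5.0)
        img[self.roi.mask((64, 64), (1, 1))] = 200.0
        pct = morpho.stain_positive_percent(img, self.roi, DetectionParams())
        assert pct == 100.0

    def test_half_stained_disk_within_two_points(self):
        mask = self.roi.mask((64, 64), (1, 1))
        img = np.full((64, 64), 5.0)
        img[mask & (np.indices((64, 64))[1] <= 32)] = 200.0
        pct = morpho.stain_positive_percent(img, self.roi, DetectionParams())
        half = 100.0 * (mask & (np.indices((64, 64))[1] <= 32)).sum() / mask.sum()
        assert pct == pytest.approx(half, abs=2.0)
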