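import numpy as np
import pytest

from woundquant import coloc, synth
from woundquant.detect import DetectionParams
from woundquant.roi import RegionOfInterest
from woundquant.stack import LabeledObjects


def _objs(labels, voxel_size=(1.0, 1.0, 1.0)):
    return LabeledObjects.from_labels(np.asarray(labels), voxel_size)


class TestMeasureInsideOutside:
    def test_full_containment(self):
        cells = np.zeros((4, 8, 8), dtype=int)
        cells[1:3, 1:6, 1:6] = 1
        cargo = np.zeros_like(cells)
        cargo[1, 2:4, 2:4] = 1
        res = coloc.measure_inside_outside(_objs(cargo), _objs(cells))
        assert res.total_cargo_volume_inside_um3 == 4.0
        assert res.total_cargo_volume_outside_um3 == 0.0
        assert res.percent_cells_with_cargo == 100.0

    def test_no_cells_everything_outside(self):
        cargo = np.zeros((2, 6, 6), dtype=int)
        cargo[0, 1:3, 1:3] = 1
        res = coloc.measure_inside_outside(_objs(cargo), _objs(np.zeros((2, 6, 6), int)))
        assert res.total_cargo_volume_inside_um3 == 0.0
        assert res.total_cargo_volume_outside_um3 == 4.0
        assert np.isnan(res.percent_cells_with_cargo)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            coloc.measure_inside_outside(
                _objs(np.zeros((2, 4, 4), int)), _objs(np.zeros((2, 5, 5), int))
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_voxel_intersection(self, seed):
        """Inside/outside split equals a brute-force voxel-by-voxel count."""
        rng = np.random.default_rng(seed)
        cells = (rng.random((6, 24, 24)) > 0.7).astype(int)
        cargo = (rng.random((6, 24, 24)) > 0.8).astype(int)
        from scipy import ndimage

        cl, _ = ndimage.label(cells)
        gl, _ = ndimage.label(cargo)
        res = coloc.measure_inside_outside(_objs(gl), _objs(cl))
        inside_oracle = int(np.sum((gl > 0) & (cl > 0)))
        outside_oracle = int(np.sum((gl > 0) & (cl == 0)))
        assert res.total_cargo_volume_inside_um3 == inside_oracle
        assert res.total_cargo_volume_outside_um3 == outside_oracle

    def test_synthetic_scene_inside_count_exact(self, cells_cargo):
        cells = _objs(cells_cargo["cell_labels"], cells_cargo["voxel_size"])
        cargo = _objs(cells_cargo["cargo_labels"], cells_cargo["voxel_size"])
        res = coloc.measure_inside_outside(cargo, cells)
        oracle = int(
            np.sum((cells_cargo["cargo_labels"] > 0) & (cells_cargo["cell_labels"] > 0))
        )
        assert res.total_cargo_volume_inside_um3 == oracle

    def test_invariant_to_cell_relabeling(self, cells_cargo):
        cells_lab = cells_cargo["cell_labels"]
        perm = np.concatenate([[0], np.random.default_rng(1).permutation(cells_lab.max()) + 1])
        cells_a = _objs(cells_lab)
        cells_b = _objs(perm[cells_lab])
        cargo = _objs(cells_cargo["cargo_labels"])
        ra = coloc.measure_inside_outside(cargo, cells_a)
        rb = coloc.measure_inside_outside(cargo, cells_b)
        assert ra.n_cells_with_cargo == rb.n_cells_with_cargo
        assert ra.total_cargo_volume_inside_um3 == rb.total_cargo_volume_inside_um3


class TestPercentCellsPositive:
    def _scene(self):
        cells = np.zeros((32, 64), dtype=int)
        marker = np.full((32, 64), 5.0)
        for i in range(10):
            y, x = 8 + 16 * (i // 5), 6 + 12 * (i % 5)
            cells[y - 2 : y + 3, x - 2 : x + 3] = i + 1
            if i < 7:
                marker[y, x] = 200.0
        return _objs(cells), marker

    def test_direct_ratio(self):
        cells, marker = self._scene()
        pct = coloc.percent_cells_positive(
            cells, marker, DetectionParams(threshold_floor=50.0)
        )
        assert pct == pytest.approx(70.0)

    def test_no_marker_gives_zero(self):
        cells, _ = self._scene()
        pct = coloc.percent_cells_positive(
            cells, np.full((32, 64), 5.0), DetectionParams(threshold_floor=50.0)
        )
        assert pct == 0.0

    def test_empty_roi_flagged_nan(self):
        cells, marker = self._scene()
        far = RegionOfInterest(kind="circle", center_um=(1000.0, 1000.0), radius_um=5.0)
        assert np.isnan(
            coloc.percent_cells_positive(
                cells, marker, DetectionParams(threshold_floor=50.0), far
            )
        )

    def test_roi_membership_matches_distance_oracle(self):
        """Circle membership equals a brute-force centroid-distance test."""
        cells, marker = self._scene()
        roi = RegionOfInterest(kind="circle", center_um=(16.0, 30.0), radius_um=18.0)
        cent = cells.centroids_um()[:, 1:]
        oracle_in = (
            np.hypot(cent[:, 0] - 16.0, cent[:, 1] - 30.0) <= 18.0
        )
        n, _ = coloc.count_objects(cells, roi)
        assert n == int(oracle_in.sum())


class TestCountObjects:
    def test_empty_labels(self):
        n, v = coloc.count_objects(_objs(np.zeros((4, 4, 4), int)))
        assert (n, v) == (0, 0.0)

    def test_whole_image_counts_all(self, spheres_scene):
        objs = _objs(spheres_scene["labels"], spheres_scene["voxel_size"])
        n, v = coloc.count_objects(objs)
        assert n == 3
        assert v == pytest.approx(spheres_scene["true_volumes_um3"].sum())


class TestTimecourse:
    def _mask(self):
        lab = np.zeros((8, 8), dtype=int)
        lab[2:6, 2:6] = 1
        return _objs(lab)

    def test_constant_signal_rectangle_auc(self):
        masks = [self._mask() for _ in range(5)]
        sig = np.full((5, 8, 8), 3.0)
        tc = coloc.per_cell_timecourse(masks, sig, time_interval_min=2.0)
        assert np.allclose(tc.population_mean, 3.0)
        assert tc.auc == pytest.approx(3.0 * 8.0)  # c · T

    def test_linear_ramp_triangle_auc(self):
        masks = [self._mask() for _ in range(5)]
        sig = np.stack([np.full((8, 8), v) for v in np.linspace(0, 10, 5)])
        tc = coloc.per_cell_timecourse(masks, sig, time_interval_min=1.0)
        assert tc.auc == pytest.approx(10.0 * 4.0 / 2.0)

    def test_small_cells_dropped_and_missing_frames_nan(self):
        big = self._mask()
        tiny = np.zeros((8, 8), dtype=int)
        tiny[0, 0] = 1
        masks = [big, _objs(tiny), big]
        sig = np.full((3, 8, 8), 2.0)
        tc = coloc.per_cell_timecourse(masks, sig, min_cell_area_um2=4.0)
        assert np.isnan(tc.population_mean[1])
        assert tc.population_mean[0] == 2.0

    def test_scripted_per_cell_intensities_recovered(self):
        """Population curve equals the average of generator-scripted values."""
        rng = np.random.default_rng(4)
        lab = np.zeros((16, 16), dtype=int)
        lab[2:6, 2:6], lab[9:13, 9:13] = 1, 2
        masks = [_objs(lab) for _ in range(6)]
        script = rng.uniform(10, 100, size=(6, 2))
        sig = np.zeros((6, 16, 16))
        for f in range(6):
            sig[f][lab == 1] = script[f, 0]
            sig[f][lab == 2] = script[f, 1]
        tc = coloc.per_cell_timecourse(masks, sig)
        assert np.allclose(tc.population_mean, script.mean(axis=1))

    def test_auc_additive_and_linear(self):
        masks = [self._mask() for _ in range(7)]
        rng = np.random.default_rng(8)
        vals = rng.uniform(1, 5, 7)
        sig = np.stack([np.full((8, 8), v) for v in vals])
        tc = coloc.per_cell_timecourse(masks, sig)
        tc2 = coloc.per_cell_timecourse(masks, 3.0 * sig)
        assert tc2.auc == pytest.approx(3.0 * tc.auc)
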