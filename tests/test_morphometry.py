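"""CT morphometry against closed forms and exhaustive brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from marrowlab.morphometry import (
    CTVolume,
    RoiSpec,
    apply_calibration,
    binarize,
    box_counts,
    bv_tv,
    calibrate,
    cross_sectional_areas,
    extract_phantom_pairs,
    fractal_dimension,
    mean_bmd,
    mil_tbn,
    place_roi,
)
from marrowlab.synthetic import LatticeSpec, VolumeGenSpec, generate_volume

VOX = (0.23, 0.23, 0.6)


# ---------------------------------------------------------------- oracles

def oracle_mil(mask, voxel_size, axis):
    """Walk every line voxel by voxel; count bone length and bone runs."""
    m = np.moveaxis(mask, axis, -1)
    n_bone = 0
    runs = 0
    for line in m.reshape(-1, m.shape[-1]):
        prev = False
        for v in line:
            if v:
                n_bone += 1
                if not prev:
                    runs += 1
            prev = bool(v)
    return n_bone * voxel_size[axis], runs


def oracle_box_counts(sl, sizes):
    """Enumerate every box explicitly."""
    ny, nx = sl.shape
    out = []
    for s in sizes:
        n = 0
        for y0 in range(0, ny, s):
            for x0 in range(0, nx, s):
                if sl[y0:y0 + s, x0:x0 + s].any():
                    n += 1
        out.append(n)
    return np.array(out)


# ------------------------------------------------------------ calibration

class TestCalibration:
    def test_identity_pair(self):
        m = calibrate([(0.0, 0.0), (100.0, 100.0)])
        assert m.slope == pytest.approx(1.0) and m.intercept == pytest.approx(0.0)

    def test_noiseless_known_line_recovered(self):
        hu = np.array([10.0, 50.0, 120.0, 300.0])
        rho = 0.8 * hu - 5.0
        m = calibrate(list(zip(hu, rho)))
        assert m.slope == pytest.approx(0.8)
        assert m.intercept == pytest.approx(-5.0)
        assert m.r_squared == pytest.approx(1.0)

    def test_generated_phantom_recovers_encoding(self):
        spec = VolumeGenSpec(calibration_slope=0.8, calibration_intercept=-5.0)
        vol, truth = generate_volume(spec)
        m = calibrate(extract_phantom_pairs(vol, truth.phantom_rois))
        assert m.slope == pytest.approx(0.8, rel=1e-9)
        assert m.intercept == pytest.approx(-5.0, rel=1e-9)

    def test_degenerate_rods_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            calibrate([(100.0, 0.0), (100.0, 200.0)])
        with pytest.raises(ValueError):
            calibrate([(100.0, 0.0)])

    def test_apply_calibration_affine(self):
        vol = CTVolume(values=np.full((4, 4, 4), 250.0), voxel_size=VOX)
        m = calibrate([(0.0, -5.0), (100.0, 75.0)])   # slope 0.8, intercept -5
        out = apply_calibration(vol, m)
        assert out.values == pytest.approx(195.0)
        assert out.voxel_size == vol.voxel_size


# -------------------------------------------------------------------- ROI

class TestRoi:
    def test_twelve_mm_window_is_52_voxels(self):
        vol = CTVolume(values=np.zeros((80, 80, 30)), voxel_size=VOX)
        roi = place_roi(vol, RoiSpec(n_slices=20))
        assert roi[0].stop - roi[0].start == 52   # 12 / 0.23 = 52.17 -> 52
        assert roi[1].stop - roi[1].start == 52
        assert roi[2].stop - roi[2].start == 20

    def test_exact_slice_count_selected(self):
        vol = CTVolume(values=np.zeros((80, 80, 20)), voxel_size=VOX)
        roi = place_roi(vol, RoiSpec(n_slices=20))
        assert (roi[2].start, roi[2].stop) == (0, 20)

    def test_too_many_slices_rejected(self):
        vol = CTVolume(values=np.zeros((80, 80, 10)), voxel_size=VOX)
        with pytest.raises(ValueError, match="slices"):
            place_roi(vol, RoiSpec(n_slices=20))

    def test_window_exceeding_bounds_reports_axis(self):
        vol = CTVolume(values=np.zeros((30, 80, 30)), voxel_size=VOX)
        with pytest.raises(ValueError, match="axis 0"):
            place_roi(vol, RoiSpec(n_slices=20))

    def test_mean_bmd_matches_brute_force(self, rng):
        vol = CTVolume(values=rng.uniform(0, 400, (30, 30, 25)), voxel_size=VOX)
        roi = place_roi(vol, RoiSpec(extent_mm=(4.0, 4.0), n_slices=10))
        vals = vol.values[roi]
        total = 0.0
        for v in vals.ravel():
            total += v
        assert mean_bmd(vol, roi) == pytest.approx(total / vals.size, abs=1e-12)

    def test_constant_roi_mean(self):
        vol = CTVolume(values=np.full((30, 30, 25), 121.5), voxel_size=VOX)
        roi = place_roi(vol, RoiSpec(extent_mm=(4.0, 4.0), n_slices=10))
        assert mean_bmd(vol, roi) == pytest.approx(121.5)


# ---------------------------------------------------- threshold and BV/TV

class TestBinarizeBvTv:
    def test_threshold_is_inclusive(self):
        vol = CTVolume(values=np.array([[[199.9, 200.0, 200.1]]]), voxel_size=VOX)
        assert binarize(vol).tolist() == [[[False, True, True]]]

    def test_all_marrow_is_background(self):
        vol = CTVolume(values=np.full((5, 5, 5), 120.0), voxel_size=VOX)
        assert not binarize(vol).any()

    def test_lattice_binarization_matches_generator_mask(self):
        spec = VolumeGenSpec(phantom_rows=0)
        vol, truth = generate_volume(spec)
        density = CTVolume(values=vol.values * spec.calibration_slope
                           + spec.calibration_intercept, voxel_size=VOX)
        assert np.array_equal(binarize(density), truth.bone_mask)

    def test_bv_tv_counting(self):
        assert bv_tv(np.ones((4, 4, 4), bool)) == 100.0
        plate = np.zeros((8, 4, 4), bool)
        plate[::4] = True
        assert bv_tv(plate) == 25.0

    @given(st.integers(0, 2**32 - 1))
    def test_bv_tv_matches_exhaustive_count(self, seed):
        m = np.random.default_rng(seed).random((6, 5, 4)) < 0.4
        count = sum(bool(v) for v in m.ravel())
        assert bv_tv(m) == 100.0 * count / m.size

    def test_threshold_monotonicity(self, rng):
        vol = CTVolume(values=rng.uniform(0, 400, (10, 10, 10)), voxel_size=VOX)
        values = [bv_tv(binarize(vol, t)) for t in (50, 150, 200, 250, 350)]
        assert np.all(np.diff(values) <= 0)


# ---------------------------------------------------------------- MIL/TbN

class TestMil:
    def _plate(self):
        m = np.zeros((16, 8, 8), bool)
        m[::4] = True    # 1 voxel on, 3 off along x
        return m

    def test_plate_closed_form(self):
        res = mil_tbn(self._plate(), VOX, directions=(0,))
        assert res.mil_mm[0] == pytest.approx(0.23)
        assert res.tbn == pytest.approx(0.25 / 0.23)

    def test_plate_parallel_direction_is_degenerate(self):
        res = mil_tbn(self._plate(), VOX, directions=(1,))
        # lines inside a plate never exit bone: MIL is the full line length
        assert res.mil_mm[1] == pytest.approx(8 * 0.23)

    def test_solid_or_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="both bone and marrow"):
            mil_tbn(np.ones((4, 4, 4), bool), VOX)
        with pytest.raises(ValueError, match="both bone and marrow"):
            mil_tbn(np.zeros((4, 4, 4), bool), VOX)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_line_walk(self, seed):
        m = np.random.default_rng(seed).random((7, 6, 5)) < 0.45
        if not m.any() or m.all():
            return
        res = mil_tbn(m, VOX)
        for axis in (0, 1, 2):
            length, runs = oracle_mil(m, VOX, axis)
            assert res.bone_length_mm[axis] == pytest.approx(length)
            assert res.n_intercepts[axis] == runs
            assert res.mil_mm[axis] == pytest.approx(length / runs)

    def test_resolution_consistency(self):
        # doubling voxel counts while halving voxel size preserves physics
        coarse = self._plate()
        fine = np.repeat(np.repeat(np.repeat(coarse, 2, 0), 2, 1), 2, 2)
        half_vox = tuple(v / 2 for v in VOX)
        r1 = mil_tbn(coarse, VOX, directions=(0,))
        r2 = mil_tbn(fine, half_vox, directions=(0,))
        assert r2.mil_mm[0] == pytest.approx(r1.mil_mm[0])
        assert r2.tbn == pytest.approx(r1.tbn)
        assert bv_tv(fine) == bv_tv(coarse)


# ---------------------------------------------------------------------- FD

class TestFractalDimension:
    def test_filled_plane_is_two(self):
        fd = fractal_dimension([np.ones((64, 64), bool)])
        assert fd == pytest.approx(2.0, abs=1e-9)

    def test_single_pixel_line_is_one(self):
        sl = np.zeros((64, 64), bool)
        sl[10, :] = True
        assert fractal_dimension([sl]) == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    def test_counts_match_exhaustive_enumeration(self, seed):
        sl = np.random.default_rng(seed).random((20, 17)) < 0.3
        if not sl.any():
            return
        sizes = (2, 3, 4, 8)
        assert np.array_equal(box_counts(sl, sizes), oracle_box_counts(sl, sizes))

    def test_fd_bounds_on_mixed_slices(self, rng):
        for _ in range(10):
            sl = rng.random((32, 32)) < rng.uniform(0.05, 0.9)
            if not sl.any():
                continue
            fd = fractal_dimension([sl], box_sizes=(2, 4, 8, 16))
            assert 1.0 - 1e-9 <= fd <= 2.0 + 1e-9

    def test_empty_slices_excluded_with_warning(self):
        good = np.ones((16, 16), bool)
        empty = np.zeros((16, 16), bool)
        with pytest.warns(RuntimeWarning, match="without bone"):
            fd = fractal_dimension([good, empty], box_sizes=(2, 4, 8))
        assert fd == pytest.approx(2.0, abs=1e-9)
        with pytest.raises(ValueError, match="no slice"):
            fractal_dimension([empty], box_sizes=(2, 4, 8))

    def test_too_few_box_sizes_rejected(self):
        with pytest.raises(ValueError, match="three box sizes"):
            fractal_dimension([np.ones((8, 8), bool)], box_sizes=(2, 4))


# ------------------------------------------------------------------- areas

class TestAreas:
    def test_rectangular_prism(self):
        mask = np.zeros((60, 60, 5), bool)
        mask[:50, :50, :] = True
        mean_a, min_a = cross_sectional_areas(mask, VOX)
        assert mean_a == pytest.approx(50 * 50 * 0.23 * 0.23 / 100)   # 1.3225 cm^2
        assert min_a == mean_a

    def test_stepped_mask_min_and_mean(self):
        # two slice populations at ~4.9 and ~9.7 cm^2
        side_small = int(round(np.sqrt(4.9 * 100) / 0.23))
        side_big = int(round(np.sqrt(9.7 * 100) / 0.23))
        mask = np.zeros((160, 160, 2), bool)
        mask[:side_small, :side_small, 0] = True
        mask[:side_big, :side_big, 1] = True
        a_small = side_small**2 * 0.23**2 / 100
        a_big = side_big**2 * 0.23**2 / 100
        mean_a, min_a = cross_sectional_areas(mask, VOX)
        assert min_a == pytest.approx(a_small)
        assert mean_a == pytest.approx((a_small + a_big) / 2)
        assert min_a == pytest.approx(4.9, rel=0.01)
        assert mean_a == pytest.approx((4.9 + 9.7) / 2, rel=0.01)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_per_slice_count(self, seed):
        m = np.random.default_rng(seed).random((9, 8, 6)) < 0.5
        if not m.any():
            return
        per_slice = []
        for k in range(m.shape[2]):
            n = sum(bool(v) for v in m[:, :, k].ravel())
            if n:
                per_slice.append(n * 0.23 * 0.23 / 100)
        mean_a, min_a = cross_sectional_areas(m, VOX)
        assert mean_a == pytest.approx(np.mean(per_slice))
        assert min_a == pytest.approx(min(per_slice))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cross_sectional_areas(np.zeros((4, 4, 4), bool), VOX)
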