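"""Morphometric indices against geometric closed forms and brute-force
re-computation on small masks."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trabmech import (BinaryVolume, BmdCalibration, ImageVolume,
                      RegionOfInterest, analyze_roi, binarize,
                      bone_volume_fraction, local_thickness,
                      surface_and_bsbv, trabecular_number,
                      trabecular_pattern_factor)
from trabmech.morphometry import (EmptyPhaseError, bmd_from_hu, otsu_threshold,
                                  surface_area, thickness_map)


class TestBinarize:
    def test_uniform_volume_all_foreground(self):
        vol = ImageVolume(np.full((5, 5, 5), 2000.0), 0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = binarize(vol, 1000.0)
        assert mask.mask.all()

    def test_threshold_above_max_gives_empty_mask_with_warning(self):
        vol = ImageVolume(np.full((5, 5, 5), 100.0), 0.1)
        with pytest.warns(UserWarning, match="degenerate"):
            mask = binarize(vol, 5000.0)
        assert not mask.mask.any()

    def test_threshold_recorded_in_provenance(self):
        vol = ImageVolume(np.random.default_rng(0).normal(1000, 500, (6, 6, 6)),
                          0.1)
        assert binarize(vol, 900.0).meta["threshold"] == 900.0

    @given(st.floats(min_value=-500, max_value=2500))
    @settings(max_examples=25, deadline=None)
    def test_raising_threshold_never_increases_bvtv(self, thr):
        vol = ImageVolume(
            np.random.default_rng(42).normal(1000, 600, (8, 8, 8)), 0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo = bone_volume_fraction(binarize(vol, thr))
            hi = bone_volume_fraction(binarize(vol, thr + 100.0))
        assert hi <= lo

    def test_otsu_separates_bimodal_phases(self):
        rng = np.random.default_rng(0)
        vox = np.where(rng.random((12, 12, 12)) < 0.3,
                       rng.normal(2000, 50, (12, 12, 12)),
                       rng.normal(0, 50, (12, 12, 12)))
        thr = otsu_threshold(ImageVolume(vox, 0.1))
        assert 150 < thr < 1850
        # thresholding at Otsu agrees with the generating phase labels
        # up to a few voxels in the mode tails
        assert np.count_nonzero((vox >= thr) != (vox > 1000)) <= 3


class TestBoneVolumeFraction:
    def test_solid_empty_half(self):
        solid = BinaryVolume(np.ones((4, 4, 4), bool), 0.1)
        empty = BinaryVolume(np.zeros((4, 4, 4), bool), 0.1)
        half = BinaryVolume(np.arange(4)[:, None, None] < 2
                            * np.ones((4, 4, 4), int), 0.1)
        assert bone_volume_fraction(solid) == 1.0
        assert bone_volume_fraction(empty) == 0.0
        assert bone_volume_fraction(half) == 0.5

    @given(st.integers(0, 2 ** 24 - 1))
    @settings(max_examples=25, deadline=None)
    def test_complement_sums_to_one(self, bits):
        mask = np.array([(bits >> i) & 1 for i in range(24)],
                        dtype=bool).reshape(2, 3, 4)
        bv = BinaryVolume(mask, 0.2)
        assert (bone_volume_fraction(bv)
                + bone_volume_fraction(bv.complement())) == pytest.approx(1.0)


class TestSurface:
    def test_digital_ball_within_5pct_of_sphere(self, ball_mask):
        surf, _ = surface_and_bsbv(ball_mask)
        r_mm = 10 * ball_mask.spacing
        assert surf == pytest.approx(4 * np.pi * r_mm ** 2, rel=0.05)

    def test_solid_cube_surface_near_closed_form(self):
        n, h = 32, 0.1
        cube = BinaryVolume(np.ones((n, n, n), bool), h)
        surf, bsbv = surface_and_bsbv(cube)
        side = n * h
        # edge rounding from the pre-smoothing loses a few percent
        assert surf == pytest.approx(6 * side ** 2, rel=0.08)
        assert bsbv == pytest.approx(6 / side, rel=0.08)

    def test_thick_plate_bsbv_near_closed_form(self):
        # finite plate L x L x w: S/V = (2 L^2 + 4 L w)/(L^2 w); the
        # face term 2/w dominates as L grows
        m = np.zeros((11, 60, 60), dtype=bool)
        m[3:8] = True  # w = 5 voxels = 0.5 mm, L = 6.0 mm
        _, bsbv = surface_and_bsbv(BinaryVolume(m, 0.1))
        L, w = 6.0, 0.5
        exact = (2 * L * L + 4 * L * w) / (L * L * w)
        assert bsbv == pytest.approx(exact, rel=0.08)
        assert abs(bsbv - 2 / w) / (2 / w) < 0.15  # face-dominated

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyPhaseError):
            surface_area(BinaryVolume(np.zeros((3, 3, 3), bool), 0.1))


class TestThickness:
    def test_plate_thickness_within_one_voxel(self, plate_mask):
        # 5-voxel plates at 0.1 mm spacing -> 0.5 mm
        assert local_thickness(plate_mask) == pytest.approx(0.5, abs=0.1)

    def test_plate_separation_within_one_voxel(self, plate_mask):
        # marrow gaps along z are runs of 2, 7 and 5 voxels; the
        # volume-weighted mean of the run widths is the expected Tb.Sp
        tb_sp = local_thickness(plate_mask, "background")
        gaps = np.array([2, 7, 5], dtype=float)
        expected = np.average(gaps * 0.1, weights=gaps)
        assert tb_sp == pytest.approx(expected, abs=0.1)

    def test_brute_force_sphere_search_matches_map(self):
        """Exhaustive largest-inscribed-sphere search on an 8^3 random
        mask reproduces the sweep-based thickness map exactly."""
        rng = np.random.default_rng(3)
        mask = BinaryVolume(rng.random((8, 8, 8)) < 0.5, 0.1)
        h = mask.spacing
        tm = thickness_map(mask, "foreground")
        from scipy import ndimage
        # sphere radii: distance to the phase boundary, with the ROI
        # border counting as boundary
        dt = ndimage.distance_transform_edt(
            np.pad(mask.mask, 1), sampling=h)[1:-1, 1:-1, 1:-1]
        coords = np.argwhere(mask.mask)
        brute = np.zeros(mask.shape)
        for p in coords:
            best = 0.0
            for c in coords:
                r = dt[tuple(c)]
                if np.linalg.norm((p - c) * h) <= r - 0.5 * h + 1e-9 * h:
                    best = max(best, 2.0 * r - h)
            brute[tuple(p)] = max(best, h)
        np.testing.assert_allclose(tm, brute, atol=1e-9)

    def test_empty_phase_raises(self):
        solid = BinaryVolume(np.ones((4, 4, 4), bool), 0.1)
        with pytest.raises(EmptyPhaseError):
            local_thickness(solid, "background")


class TestTrabecularNumber:
    def test_ratio_definition(self):
        assert trabecular_number(0.5, 0.5) == pytest.approx(1.0)
        assert trabecular_number(0.25, 0.5) == pytest.approx(0.5)

    def test_plate_lattice_matches_line_probe_count(self):
        """Tb.N equals the number of plates crossed per mm by a probe
        line along the lattice normal."""
        from trabmech import PhantomSpec, generate_phantom
        n, h, t = 48, 0.1, 5
        _, truth = generate_phantom(PhantomSpec(
            shape_voxels=(n, n, n), voxel_size=h, target_bvtv=0.25,
            element_thickness=t * h))
        bvtv = bone_volume_fraction(truth)
        tb_th = local_thickness(truth)
        tb_n = trabecular_number(bvtv, tb_th)
        line = truth.mask[:, 0, 0].astype(int)
        crossings = np.count_nonzero(np.diff(line) == 1) + line[0]
        probe_tb_n = crossings / (n * h)
        assert tb_n == pytest.approx(probe_tb_n, abs=1.0 / (n * h))

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            trabecular_number(0.5, 0.0)


class TestPatternFactor:
    def test_isolated_ball_is_convex_positive(self, ball_mask):
        assert trabecular_pattern_factor(ball_mask) > 0

    def test_connected_lattice_scores_below_ball(self, ball_mask):
        # grid-spanning orthogonal plate lattice: concave junctions
        m = np.zeros((24, 24, 24), dtype=bool)
        m[:, :, 2:6] = True
        m[:, 2:6, :] = True
        m[2:6, :, :] = True
        lattice = BinaryVolume(m, 0.1)
        assert (trabecular_pattern_factor(lattice)
                < trabecular_pattern_factor(ball_mask))

    def test_direct_recount_matches(self):
        """Recomputing S and V with an independent dilation (explicit
        6-neighbour shifting) gives the identical ratio."""
        rng = np.random.default_rng(9)
        mask = BinaryVolume(rng.random((16, 16, 16)) < 0.4, 0.1)
        tb_pf = trabecular_pattern_factor(mask)
        dil = mask.mask.copy()
        for ax in range(3):
            for shift in (1, -1):
                dil |= np.roll(
                    np.pad(mask.mask, 1), shift, axis=ax)[1:-1, 1:-1, 1:-1]
        s1 = surface_area(mask)
        s2 = surface_area(BinaryVolume(dil, 0.1))
        v1 = mask.mask.sum() * 0.1 ** 3
        v2 = dil.sum() * 0.1 ** 3
        assert tb_pf == pytest.approx((s1 - s2) / (v1 - v2), rel=1e-12)

    def test_grid_filling_mask_undefined(self):
        with pytest.raises(EmptyPhaseError):
            trabecular_pattern_factor(BinaryVolume(np.ones((4, 4, 4), bool),
                                                   0.1))


class TestBmd:
    def test_identity_calibration(self):
        vol = ImageVolume(np.full((4, 4, 4), 500.0), 0.1)
        mask = BinaryVolume(np.ones((4, 4, 4), bool), 0.1)
        assert bmd_from_hu(vol, mask, BmdCalibration(1.0, 0.0)) == 500.0

    def test_affine_calibration(self):
        vol = ImageVolume(np.full((4, 4, 4), 100.0), 0.1)
        mask = BinaryVolume(np.ones((4, 4, 4), bool), 0.1)
        assert bmd_from_hu(vol, mask, BmdCalibration(0.5, 10.0)) == 60.0

    def test_mixed_hu_equals_hand_computed_mean(self):
        rng = np.random.default_rng(2)
        vox = rng.normal(800, 300, (6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.5
        cal = BmdCalibration(0.7, -20.0)
        got = bmd_from_hu(ImageVolume(vox, 0.1), BinaryVolume(mask, 0.1), cal)
        assert got == pytest.approx((0.7 * vox[mask] - 20.0).mean())

    def test_empty_mask_undefined(self):
        vol = ImageVolume(np.zeros((3, 3, 3)), 0.1)
        with pytest.raises(EmptyPhaseError):
            bmd_from_hu(vol, BinaryVolume(np.zeros((3, 3, 3), bool), 0.1),
                        BmdCalibration(1.0))


class TestScaleEquivariance:
    def test_doubling_spacing_scales_indices(self, plate_mask):
        big = BinaryVolume(plate_mask.mask, 2 * plate_mask.spacing)
        assert local_thickness(big) == pytest.approx(
            2 * local_thickness(plate_mask), rel=1e-9)
        _, bsbv1 = surface_and_bsbv(plate_mask)
        _, bsbv2 = surface_and_bsbv(big)
        assert bsbv2 == pytest.approx(bsbv1 / 2, rel=1e-6)
        pf1 = trabecular_pattern_factor(plate_mask)
        pf2 = trabecular_pattern_factor(big)
        assert pf2 == pytest.approx(pf1 / 2, rel=1e-6)


class TestAnalyzeRoi:
    def test_solid_roi_flags_undefined_separation(self):
        vol = ImageVolume(np.full((8, 8, 8), 2000.0), 0.1)
        roi = RegionOfInterest("SA", (0, 0, 0), (8, 8, 8))
        res = analyze_roi(vol, roi, 1000.0)
        assert res.bvtv == 1.0
        assert np.isnan(res.tb_sp)
        assert np.isnan(res.tb_pf)

    def test_four_rois_labeled_rows(self):
        from trabmech import PhantomSpec, generate_phantom
        vol, _ = generate_phantom(PhantomSpec(shape_voxels=(16, 16, 16)))
        rois = [RegionOfInterest(lab, (0, 0, 0), (8, 8, 8), level="C3",
                                 side="left")
                for lab in ("SA", "SP", "IA", "IP")]
        rows = [analyze_roi(vol, r, 1000.0, BmdCalibration(0.35)) for r in rois]
        assert [r.label for r in rows] == ["SA", "SP", "IA", "IP"]
        assert all(r.level == "C3" and r.side == "left" for r in rows)
        assert all(np.isfinite(r.bmd) for r in rows)

    def test_roi_outside_volume_rejected(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), 0.1)
        roi = RegionOfInterest("IP", (4, 4, 4), (8, 8, 8))
        with pytest.raises(ValueError, match="exceeds"):
            analyze_roi(vol, roi, 100.0)

    def test_plate_phantom_parameters_near_closed_forms(self):
        from trabmech import PhantomSpec, generate_phantom
        n, h, t = 40, 0.125, 5
        vol, truth = generate_phantom(PhantomSpec(
            shape_voxels=(n, n, n), voxel_size=h, target_bvtv=0.25,
            element_thickness=t * h))
        roi = RegionOfInterest("SA", (0, 0, 0), (n, n, n))
        res = analyze_roi(vol, roi, 1000.0)
        assert res.bvtv == pytest.approx(bone_volume_fraction(truth),
                                         abs=1e-12)
        assert res.tb_th == pytest.approx(t * h, abs=h)
        # plates: BS/BV ~ 2/w up to rim effects
        assert res.bs_bv == pytest.approx(2 / (t * h), rel=0.2)
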