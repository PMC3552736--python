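"""Overlay separation, ratio recovery, interpolation and thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import specpaint as sp
from specpaint.colortable import RatioMap
from specpaint.grids import CsiGeometry, GridMismatchError


def _flat_ratio_map(values, spacing_fov=100.0):
    values = np.asarray(values, dtype=float)
    geom = CsiGeometry(
        fov_mm=(spacing_fov, spacing_fov),
        matrix=(values.shape[2], values.shape[1]),
        n_slices=values.shape[0],
        slice_thickness_mm=25.0,
        box_origin_mm=(0.0, 0.0, 0.0),
    )
    with np.errstate(invalid="ignore"):
        smax = np.nanmax(values.reshape(values.shape[0], -1), axis=1)
    return RatioMap(
        values=values, accepted=np.isfinite(values), slice_max=smax, geometry=geom
    )


class TestSeparateOverlay:
    def test_all_gray_has_empty_overlay(self):
        gray = np.full((8, 8, 3), 77, dtype=np.uint8)
        anatomy, overlay = sp.separate_overlay(gray)
        assert not overlay.any()
        np.testing.assert_array_equal(anatomy, 77)

    def test_saturated_block_detected_exactly(self):
        img = np.full((10, 10, 3), 100, dtype=np.uint8)
        img[2:5, 3:7] = (255, 0, 0)
        _, overlay = sp.separate_overlay(img)
        expected = np.zeros((10, 10), dtype=bool)
        expected[2:5, 3:7] = True
        np.testing.assert_array_equal(overlay, expected)

    def test_partition_exhaustive_and_disjoint(self, composites):
        comp = composites[3]
        anatomy, overlay = sp.separate_overlay(comp)
        # every pixel is in exactly one class by construction; overlay pixels
        # are zeroed in the anatomy channel
        assert anatomy.shape == overlay.shape
        assert np.all(anatomy[overlay] == 0)

    def test_phantom_overlay_footprint_matches_truth(self, truth, composites):
        s = 3
        _, overlay = sp.separate_overlay(composites[s])
        geom = truth.config.csi
        comp = composites[s]
        ny, nx = overlay.shape
        px = comp.pixel_origin_mm[0] + np.arange(nx) * comp.pixel_spacing_mm[0]
        py = comp.pixel_origin_mm[1] + np.arange(ny) * comp.pixel_spacing_mm[1]
        gx = np.floor((px - geom.box_origin_mm[0]) / geom.voxel_size_mm[0]).astype(int)
        gy = np.floor((py - geom.box_origin_mm[1]) / geom.voxel_size_mm[1]).astype(int)
        inx = (gx >= 0) & (gx < geom.matrix[0])
        iny = (gy >= 0) & (gy < geom.matrix[1])
        expected = np.zeros_like(overlay)
        for j in np.flatnonzero(iny):
            expected[j, inx] = truth.accepted[s, gy[j], gx[inx]]
        np.testing.assert_array_equal(overlay, expected)


class TestRecoverRatioMap:
    def test_no_overlay_anywhere_gives_all_rejected(self, truth):
        geom = truth.config.csi
        gray = np.full((40, 40, 3), 50, dtype=np.uint8)
        comps = [
            sp.CompositeSlice(
                rgb=gray,
                csi_slice_index=s,
                pixel_spacing_mm=(2.5, 2.5),
                pixel_origin_mm=(geom.box_origin_mm[0], geom.box_origin_mm[1]),
                source_anat_index=0,
            )
            for s in range(geom.n_slices)
        ]
        with pytest.warns(UserWarning):
            rm = sp.recover_ratio_map(
                comps, sp.default_table(), truth.slice_maxima, geom
            )
        assert not rm.accepted.any()

    def test_slice_count_mismatch_raises(self, truth, composites):
        with pytest.raises(GridMismatchError):
            sp.recover_ratio_map(
                composites[:-1],
                sp.default_table(),
                truth.slice_maxima[:-1],
                truth.config.csi,
            )

    def test_recovered_slice_maxima_match_sidecar(self, truth, recovered):
        """The slice maxima recomputed from recovery equal the inputs."""
        rec = recovered.recomputed_slice_maxima()
        np.testing.assert_allclose(rec, truth.slice_maxima, rtol=1e-3)

    def test_uniform_ratio_recovered_constant(self):
        """A uniform-ratio slice recovers to a constant field."""
        geom = CsiGeometry(
            fov_mm=(40, 40), matrix=(4, 4), n_slices=1,
            box_origin_mm=(0.0, 0.0, 0.0),
        )
        table = sp.default_table()
        from specpaint.colortable import hsv_to_rgb8

        u_true = 0.6
        rgb = np.empty((40, 40, 3), dtype=np.uint8)
        rgb[:] = hsv_to_rgb8(table.hue(u_true))
        comp = sp.CompositeSlice(
            rgb=rgb, csi_slice_index=0, pixel_spacing_mm=(1.0, 1.0),
            pixel_origin_mm=(0.5, 0.5), source_anat_index=0,
        )
        rm = sp.recover_ratio_map([comp], table, [2.0], geom)
        assert rm.accepted.all()
        spread = rm.values.max() - rm.values.min()
        assert spread <= 2.0 * (60.0 / 255.0) / 240.0 + 1e-9
        assert rm.values.mean() == pytest.approx(u_true * 2.0, abs=2e-3)


class TestRemapToAnatomy:
    def test_identity_on_csi_grid(self):
        vals = np.arange(8.0).reshape(1, 2, 4) + 1.0
        rm = _flat_ratio_map(vals, spacing_fov=100.0)
        geom = rm.geometry
        vx, vy, vz = geom.voxel_size_mm
        target = sp.VolumeImage(
            array=np.zeros((1, 2, 4)),
            spacing=(vx, vy, vz),
            origin=tuple(geom.voxel_center(0, 0, 0)),
        )
        out = sp.remap_to_anatomy(rm, target)
        np.testing.assert_allclose(out.array, vals)

    def test_midpoint_is_linear_average(self):
        vals = np.array([[[1.0, 3.0]]])
        rm = _flat_ratio_map(vals, spacing_fov=20.0)
        geom = rm.geometry
        c0 = geom.voxel_center(0, 0, 0)
        c1 = geom.voxel_center(1, 0, 0)
        mid = (c0 + c1) / 2
        target = sp.VolumeImage(
            array=np.zeros((1, 1, 1)), spacing=(1, 1, 1), origin=tuple(mid)
        )
        out = sp.remap_to_anatomy(rm, target)
        assert out.array[0, 0, 0] == pytest.approx(2.0)

    def test_outside_box_is_missing(self, truth, recovered):
        out = sp.remap_to_anatomy(recovered, truth.t1_gd)
        x, y, z = truth.t1_gd.voxel_centers()
        geom = truth.config.csi
        outside = x < geom.box_origin_mm[0] - 1.0
        assert np.all(np.isnan(out.array[outside]))

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_no_overshoot_vs_bilinear_oracle(self, seed):
        """Interpolated values stay inside the 4 surrounding voxel values."""
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 3, size=(1, 5, 5))
        rm = _flat_ratio_map(vals, spacing_fov=50.0)
        geom = rm.geometry
        pt = rng.uniform(0.0, 3.9, size=2)  # fractional (i, j)
        world = geom.voxel_center(pt[0], pt[1], 0)
        target = sp.VolumeImage(
            array=np.zeros((1, 1, 1)), spacing=(1, 1, 1), origin=tuple(world)
        )
        out = float(sp.remap_to_anatomy(rm, target).array[0, 0, 0])
        i0, j0 = int(pt[0]), int(pt[1])
        corners = vals[0, j0 : j0 + 2, i0 : i0 + 2]
        assert corners.min() - 1e-9 <= out <= corners.max() + 1e-9
        # brute-force bilinear oracle
        wx, wy = pt[0] - i0, pt[1] - j0
        oracle = (
            corners[0, 0] * (1 - wx) * (1 - wy)
            + corners[0, 1] * wx * (1 - wy)
            + corners[1, 0] * (1 - wx) * wy
            + corners[1, 1] * wx * wy
        )
        assert out == pytest.approx(oracle, abs=1e-9)

    def test_disjoint_geometry_raises(self):
        vals = np.ones((1, 2, 2))
        rm = _flat_ratio_map(vals, spacing_fov=20.0)
        target = sp.VolumeImage(
            array=np.zeros((2, 2, 2)), spacing=(1, 1, 1), origin=(500.0, 500.0, 500.0)
        )
        with pytest.raises(GridMismatchError):
            sp.remap_to_anatomy(rm, target)


class TestSegmentThreshold:
    def test_threshold_zero_selects_accepted_footprint(self, recovered):
        mask = sp.segment_threshold(recovered.values, 0.0)
        np.testing.assert_array_equal(mask, np.isfinite(recovered.values))

    def test_missing_never_in_mask(self):
        arr = np.array([[[np.nan, 2.5], [1.0, 2.0]]])
        mask = sp.segment_threshold(arr, 2.0)
        np.testing.assert_array_equal(mask, [[[False, True], [False, True]]])

    def test_monotone_in_threshold(self, recovered):
        hi = sp.segment_threshold(recovered.values, 2.5)
        lo = sp.segment_threshold(recovered.values, 2.0)
        assert np.all(lo[hi])  # mask(2.5) subset of mask(2.0)

    def test_only_suprathreshold_slices_contribute(self, truth, recovered):
        mask = sp.segment_threshold(recovered.values, 2.0)
        for s in range(truth.config.csi.n_slices):
            if truth.slice_maxima[s] < 2.0 - 6e-3:
                assert not mask[s].any()


class TestBurnRoi:
    def test_empty_mask_promotes_grayscale(self):
        anat = np.arange(16, dtype=np.uint8).reshape(4, 4) * 10
        rgb = sp.burn_roi(anat, np.zeros((4, 4), dtype=bool))
        for c in range(3):
            np.testing.assert_array_equal(rgb[..., c], anat)

    def test_full_mask_is_all_red(self):
        anat = np.full((4, 4), 90, dtype=np.uint8)
        rgb = sp.burn_roi(anat, np.ones((4, 4), dtype=bool))
        assert np.all(rgb.reshape(-1, 3) == (255, 0, 0))

    def test_separate_overlay_recovers_mask(self):
        rng = np.random.default_rng(7)
        anat = rng.integers(0, 200, size=(16, 16)).astype(np.uint8)
        mask = rng.random((16, 16)) > 0.7
        rgb = sp.burn_roi(anat, mask)
        _, overlay = sp.separate_overlay(rgb)
        np.testing.assert_array_equal(overlay, mask)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            sp.burn_roi(np.zeros((4, 4)), np.zeros((5, 5), dtype=bool))


class TestEndToEnd:
    def test_segmentation_dice_vs_truth(self, truth, recovered):
        """Full chain reproduces the true Cho/NAA >= 2 region (Dice >= 0.95)."""
        ratio_anat = sp.remap_to_anatomy(recovered, truth.t1_gd)
        seg = sp.segment_threshold(ratio_anat, 2.0)
        ref = truth.true_mask(2.0)
        inter = (seg.array & ref.array).sum()
        dice = 2 * inter / (seg.array.sum() + ref.array.sum())
        assert dice >= 0.95

    def test_threshold_first_variant_matches_csi_mask_blocks(self, truth, recovered):
        """The blocky threshold-first ROI agrees with the CSI-level mask at
        every CSI voxel center."""
        res = sp.segment_ratio_map(
            recovered, truth.t1_gd, threshold=2.0, threshold_first=True
        )
        csi_mask = sp.segment_threshold(recovered.values, 2.0)
        geom = truth.config.csi
        t1 = truth.t1_gd
        for s in range(geom.n_slices):
            for vj, vi in np.argwhere(recovered.accepted[s]):
                world = geom.voxel_center(vi, vj, s)
                i, j, k = np.round(t1.world_to_index(world)).astype(int)
                if 0 <= k < t1.array.shape[0]:
                    assert bool(res.roi.array[k, j, i]) == bool(csi_mask[s, vj, vi])

    def test_interpolation_threshold_order_consistent_on_centers(
        self, truth, recovered
    ):
        """Segmenting the interpolated field agrees with CSI-level
        segmentation at CSI voxel centers."""
        geom = truth.config.csi
        csi_mask = sp.segment_threshold(recovered.values, 2.0)
        ratio_anat = sp.remap_to_anatomy(recovered, truth.t1_gd)
        anat_mask = sp.segment_threshold(ratio_anat, 2.0)
        t1 = truth.t1_gd
        agree = total = 0
        for s in range(geom.n_slices):
            for vj in range(geom.matrix[1]):
                for vi in range(geom.matrix[0]):
                    if not recovered.accepted[s, vj, vi]:
                        continue
                    world = geom.voxel_center(vi, vj, s)
                    idx = np.round(t1.world_to_index(world)).astype(int)
                    i, j, k = idx
                    if not (
                        0 <= k < t1.array.shape[0]
                        and 0 <= j < t1.array.shape[1]
                        and 0 <= i < t1.array.shape[2]
                    ):
                        continue
                    total += 1
                    if bool(anat_mask.array[k, j, i]) == bool(csi_mask[s, vj, vi]):
                        agree += 1
        assert total > 0
        assert agree / total >= 0.99
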