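"""Margin expansion and target-volume construction."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

import specpaint as sp


def _brute_force_expand(arr, spacing, margin):
    """O(n^2) oracle: voxel centers within margin of any set voxel."""
    set_pts = np.argwhere(arr) * np.array(spacing)
    out = np.zeros_like(arr)
    for idx in np.ndindex(arr.shape):
        p = np.array(idx) * np.array(spacing)
        d2 = ((set_pts - p) ** 2).sum(axis=1)
        out[idx] = (d2 <= margin**2 + 1e-9).any()
    return out


class TestExpandMargin:
    def test_zero_margin_is_identity(self, small_mask):
        out = sp.expand_margin(small_mask, 0.0)
        np.testing.assert_array_equal(out.array, small_mask.array)

    def test_isotropic_3mm_ball_has_123_voxels(self, small_mask):
        """Lattice points with squared distance <= 9 around one voxel: 123."""
        out = sp.expand_margin(small_mask, 3.0)
        enumerated = sum(
            1
            for i, j, k in itertools.product(range(-4, 5), repeat=3)
            if i * i + j * j + k * k <= 9
        )
        assert enumerated == 123
        assert out.array.sum() == enumerated

    def test_anisotropic_expansion_matches_brute_force(self):
        arr = np.zeros((9, 21, 21), dtype=bool)
        arr[4, 10, 10] = True
        mask = sp.BinaryMask(array=arr, spacing=(1.0, 1.0, 2.5), modality="MASK")
        out = sp.expand_margin(mask, 3.0)
        # through-plane (2.5 mm slices): reaches +/- 1 slice only
        zs = np.flatnonzero(out.array.any(axis=(1, 2))) - 4
        assert set(zs) == {-1, 0, 1}
        # in-plane: +/- 3 voxels
        xs = np.flatnonzero(out.array.any(axis=(0, 1))) - 10
        assert set(xs) == set(range(-3, 4))
        # spacing order: (z, y, x) sampling for the (k, j, i) array
        oracle = _brute_force_expand(arr, (2.5, 1.0, 1.0), 3.0)
        np.testing.assert_array_equal(out.array, oracle)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_mask_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.random((6, 10, 10)) > 0.9
        if not arr.any():
            arr[0, 0, 0] = True
        mask = sp.BinaryMask(array=arr, spacing=(1.2, 0.8, 2.0), modality="MASK")
        out = sp.expand_margin(mask, 2.5)
        oracle = _brute_force_expand(arr, (2.0, 0.8, 1.2), 2.5)
        np.testing.assert_array_equal(out.array, oracle)

    def test_monotone_in_margin(self, small_mask):
        a = sp.expand_margin(small_mask, 2.0)
        b = sp.expand_margin(small_mask, 4.0)
        assert np.all(b.array[a.array])
        assert np.all(a.array[small_mask.array])

    def test_composition_bounded_by_single_expansion(self, small_mask):
        """expand(expand(m,a),b) is inside expand(m,a+b) exactly (triangle
        inequality on voxel centers) and misses it by at most one voxel
        diagonal, since the intermediate set is quantized to centers."""
        big = sp.BinaryMask(
            array=np.zeros((17, 17, 17), dtype=bool), spacing=(1, 1, 1)
        )
        big.array[8, 8, 8] = True
        once = sp.expand_margin(big, 5.0)
        twice = sp.expand_margin(sp.expand_margin(big, 3.0), 2.0)
        assert np.all(once.array[twice.array])  # twice subset of once
        shrunk = sp.expand_margin(big, 5.0 - np.sqrt(3.0))
        assert np.all(twice.array[shrunk.array])  # misses by < one diagonal

    def test_large_sphere_volume_ratio(self):
        """expand(sphere r, m) volume approaches the analytic ((r+m)/r)^3."""
        n = 59
        arr = np.zeros((n, n, n), dtype=bool)
        c = n // 2
        zz, yy, xx = np.ogrid[:n, :n, :n]
        r = 20.0
        arr[(xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= r**2] = True
        mask = sp.BinaryMask(array=arr, spacing=(1, 1, 1))
        m = 8.0
        out = sp.expand_margin(mask, m)
        ratio = out.array.sum() / arr.sum()
        assert ratio == pytest.approx(((r + m) / r) ** 3, rel=0.025)

    def test_empty_input_warns_and_stays_empty(self):
        mask = sp.BinaryMask(array=np.zeros((4, 4, 4), dtype=bool), spacing=(1, 1, 1))
        with pytest.warns(UserWarning):
            out = sp.expand_margin(mask, 5.0)
        assert not out.array.any()

    def test_edge_clipping_warns(self, small_mask):
        with pytest.warns(UserWarning, match="edge"):
            sp.expand_margin(small_mask, 8.0)


class TestBuildTargetSet:
    def _mask(self, arr, spacing=(2.0, 2.0, 2.0)):
        return sp.BinaryMask(array=arr, spacing=spacing, modality="MASK")

    def test_zero_margins_reduce_to_gtvs(self):
        gtv = np.zeros((10, 10, 10), dtype=bool)
        gtv[4:6, 4:6, 4:6] = True
        mrsi = np.zeros_like(gtv)
        mrsi[5:7, 5:7, 5:7] = True
        # with no GTV1/CE union contribution, PTV2 reduces to GTV2
        spec = sp.MarginSpec(ctv1_margin=0, ctv2_margin=0, ptv_margin=0)
        targets = sp.build_target_set(
            self._mask(gtv), self._mask(np.zeros_like(gtv)), self._mask(mrsi), spec
        )
        np.testing.assert_array_equal(targets["ptv1"].array, gtv)
        np.testing.assert_array_equal(
            targets["ptv2"].array, mrsi | gtv  # CTV2 includes the CE lesion
        )

    def test_union_absorbs_nested_edema(self):
        gtv = np.zeros((12, 12, 12), dtype=bool)
        gtv[5:7, 5:7, 5:7] = True
        edema = np.zeros_like(gtv)
        edema[5:8, 5:8, 5:8] = True  # inside the 17 mm expansion
        targets = sp.build_target_set(
            self._mask(gtv), self._mask(edema), self._mask(np.zeros_like(gtv))
        )
        expanded = sp.expand_margin(self._mask(gtv), 17.0)
        np.testing.assert_array_equal(targets["ctv1"].array, expanded.array)

    def test_phantom_nesting(self, truth, recovered):
        seg = sp.segment_threshold(
            sp.remap_to_anatomy(recovered, truth.t1_gd), 2.0
        )
        targets = sp.build_target_set(
            truth.structures["gtv1_ce"], truth.structures["edema_t2"], seg
        )
        # voxel-counting set inclusions
        assert np.all(targets["ptv2"].array[targets["gtv2"].array])
        assert np.all(targets["ctv2"].array[targets["gtv2"].array])
        assert np.all(targets["ptv1"].array[targets["ctv1"].array])
        assert np.all(targets["ctv1"].array[targets["gtv1"].array])

    def test_grid_mismatch_raises(self):
        a = self._mask(np.zeros((4, 4, 4), dtype=bool))
        b = self._mask(np.zeros((4, 4, 4), dtype=bool), spacing=(1, 1, 1))
        with pytest.raises(sp.grids.GridMismatchError):
            sp.build_target_set(a, b, a)


class TestNormalBrain:
    def _mask(self, arr):
        return sp.BinaryMask(array=arr, spacing=(1.0, 1.0, 1.0))

    def test_disjoint_ptv_leaves_brain_unchanged(self):
        brain = np.zeros((8, 8, 8), dtype=bool)
        brain[:4] = True
        ptv = np.zeros_like(brain)
        ptv[6:] = True
        out = sp.normal_brain(self._mask(brain), self._mask(ptv))
        np.testing.assert_array_equal(out.array, brain)

    def test_covering_ptv_empties_brain(self):
        brain = np.zeros((4, 4, 4), dtype=bool)
        brain[1:3] = True
        out = sp.normal_brain(self._mask(brain), self._mask(np.ones_like(brain)))
        assert not out.array.any()

    def test_volume_additivity(self):
        rng = np.random.default_rng(4)
        brain = rng.random((6, 6, 6)) > 0.4
        ptv = rng.random((6, 6, 6)) > 0.6
        bm, pm = self._mask(brain), self._mask(ptv)
        nb = sp.normal_brain(bm, pm)
        inter = (brain & ptv).sum() * bm.voxel_volume_cm3
        assert bm.volume_cm3 == pytest.approx(nb.volume_cm3 + inter)
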