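"""Recovering quantitative Cho/NAA maps from anatomic-metabolic composites.

Vendor MRSI snapshots fuse a grayscale anatomical underlay with a
pseudocolor metabolite overlay in one RGB image.  This module takes those
composites apart: achromatic pixels are anatomy, saturated pixels are
overlay; each overlay pixel's hue is inverted through the color table to a
normalized value, calibrated by the per-slice console maximum, interpolated
to anatomical resolution, and finally thresholded at Cho/NAA >= 2.00 to
yield the dose-painting target.

Order of operations: the continuous ratio field is interpolated first and
thresholded second (thresholding a field gives sub-voxel boundaries); the
alternative — threshold on the CSI grid, then resample the binary mask —
is available via ``threshold_first=True`` on :func:`segment_ratio_map`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colortable import (
    ColorTable,
    RatioMap,
    global_normalize,
    hue_to_normalized,
    rgb_to_hsv,
)
from .grids import BinaryMask, CsiGeometry, GridMismatchError, VolumeImage
from .phantom import CompositeSlice

__all__ = [
    "SegmentationResult",
    "separate_overlay",
    "recover_ratio_map",
    "remap_to_anatomy",
    "segment_threshold",
    "segment_ratio_map",
    "burn_roi",
    "DEFAULT_SATURATION_THRESHOLD",
]

# Pixels with HSV saturation below this are treated as grayscale underlay.
DEFAULT_SATURATION_THRESHOLD = 0.10


@dataclass
class SegmentationResult:
    """Ratio field at anatomical resolution plus its thresholded ROI."""

    ratio: VolumeImage
    roi: BinaryMask
    threshold: float


def separate_overlay(
    slice_: CompositeSlice | np.ndarray,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a composite into (grayscale anatomy, overlay pixel mask).

    Every pixel lands in exactly one class: saturation < threshold means
    underlay (gray value = HSV value channel, scaled to 8 bit), otherwise
    overlay.  The partition is exhaustive and disjoint by construction.
    """
    rgb = slice_.rgb if isinstance(slice_, CompositeSlice) else np.asarray(slice_)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (ny, nx, 3) RGB image")
    hue, sat, val = rgb_to_hsv(rgb[..., 0], rgb[..., 1], rgb[..., 2])
    overlay = sat >= saturation_threshold
    anatomy = np.round(val * 255.0).astype(np.uint8)
    anatomy = np.where(overlay, 0, anatomy).astype(np.uint8)
    return anatomy, overlay


def recover_ratio_map(
    slices: list[CompositeSlice],
    table: ColorTable,
    maxima,
    geom: CsiGeometry,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> RatioMap:
    """Invert composites back to absolute Cho/NAA on the CSI grid.

    For each CSI voxel the hues of its overlay pixels are summarized by the
    median (robust to anti-aliased block edges), inverted through the table
    to u, and calibrated by that slice's console-reported maximum.  CSI
    voxels with no overlay pixels are flagged rejected.
    """
    maxima = np.asarray(maxima, dtype=float)
    if len(slices) != geom.n_slices or maxima.shape != (geom.n_slices,):
        raise GridMismatchError(
            f"need one composite and one maximum per CSI slice "
            f"({geom.n_slices}), got {len(slices)} / {maxima.shape}"
        )
    n_s, n_j, n_i = geom.shape
    u_maps = np.full((n_s, n_j, n_i), np.nan)
    for comp in slices:
        s = comp.csi_slice_index
        if not 0 <= s < n_s:
            raise GridMismatchError(f"composite slice index {s} outside geometry")
        _, overlay = separate_overlay(comp, saturation_threshold)
        if not overlay.any():
            continue
        hue, _, _ = rgb_to_hsv(
            comp.rgb[..., 0], comp.rgb[..., 1], comp.rgb[..., 2]
        )
        # pixel -> CSI voxel index
        ny, nx = overlay.shape
        px = comp.pixel_origin_mm[0] + np.arange(nx) * comp.pixel_spacing_mm[0]
        py = comp.pixel_origin_mm[1] + np.arange(ny) * comp.pixel_spacing_mm[1]
        gx = np.floor((px - geom.box_origin_mm[0]) / geom.voxel_size_mm[0]).astype(int)
        gy = np.floor((py - geom.box_origin_mm[1]) / geom.voxel_size_mm[1]).astype(int)
        for vj in range(n_j):
            rows = np.flatnonzero(gy == vj)
            if rows.size == 0:
                continue
            for vi in range(n_i):
                cols = np.flatnonzero(gx == vi)
                if cols.size == 0:
                    continue
                block_overlay = overlay[np.ix_(rows, cols)]
                if not block_overlay.any():
                    continue
                block_hue = hue[np.ix_(rows, cols)][block_overlay]
                med = float(np.nanmedian(block_hue))
                u_maps[s, vj, vi] = hue_to_normalized(med, table)
    return global_normalize(u_maps, maxima, geometry=geom)


def remap_to_anatomy(
    ratio_map: RatioMap, target: VolumeImage
) -> VolumeImage:
    """Interpolate a CSI-grid ratio map onto an anatomical-resolution grid.

    In-plane the field is bilinear between CSI voxel centers (clamped to the
    outer ring of centers inside the box); through-plane each 25 mm CSI slab
    is treated as a constant slab — slab thickness is an order of magnitude
    larger than the anatomical slice spacing, so inter-slab interpolation
    would manufacture gradients the acquisition cannot support.  Voxels
    outside the CSI box are missing (NaN); missing CSI voxels contaminate
    every interpolated value they would contribute to.

    Bilinear interpolation is a convex combination, so output values never
    exceed the local data range (no overshoot).
    """
    geom = ratio_map.geometry
    x, y, z = target.voxel_centers()
    idx = geom.world_to_voxel(
        np.stack([x, y, z], axis=-1).reshape(-1, 3)
    ).reshape(x.shape + (3,))
    fi, fj, fs = idx[..., 0], idx[..., 1], idx[..., 2]
    n_s, n_j, n_i = geom.shape
    inside = (
        (fi >= -0.5) & (fi <= n_i - 0.5)
        & (fj >= -0.5) & (fj <= n_j - 0.5)
        & (fs >= -0.5) & (fs <= n_s - 0.5)
    )
    if not inside.any():
        raise GridMismatchError("CSI box does not intersect the target volume")

    # clamp to the ring of voxel centers; constant extrapolation over the
    # outer half-voxel that is inside the box but beyond the centers
    ci = np.clip(fi, 0.0, n_i - 1.0)
    cj = np.clip(fj, 0.0, n_j - 1.0)
    s_idx = np.clip(np.round(fs).astype(int), 0, n_s - 1)

    i0 = np.floor(ci).astype(int)
    j0 = np.floor(cj).astype(int)
    i1 = np.minimum(i0 + 1, n_i - 1)
    j1 = np.minimum(j0 + 1, n_j - 1)
    wx = ci - i0
    wy = cj - j0

    vals = ratio_map.values
    v00 = vals[s_idx, j0, i0]
    v01 = vals[s_idx, j0, i1]
    v10 = vals[s_idx, j1, i0]
    v11 = vals[s_idx, j1, i1]
    interp = (
        v00 * (1 - wx) * (1 - wy)
        + v01 * wx * (1 - wy)
        + v10 * (1 - wx) * wy
        + v11 * wx * wy
    )
    out = np.where(inside, interp, np.nan)
    return target.with_array(out, modality="RATIO")


def segment_threshold(
    ratio_field: VolumeImage | np.ndarray, threshold: float = 2.00
) -> BinaryMask | np.ndarray:
    """Mask of {Cho/NAA >= threshold}; missing values are never in the mask."""
    if isinstance(ratio_field, VolumeImage):
        arr = ratio_field.array
    else:
        arr = np.asarray(ratio_field, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = np.where(np.isfinite(arr), arr >= threshold, False)
    if isinstance(ratio_field, VolumeImage):
        return BinaryMask(
            array=mask,
            spacing=ratio_field.spacing,
            origin=ratio_field.origin,
            direction=ratio_field.direction,
            modality="MASK",
        )
    return mask


def segment_ratio_map(
    ratio_map: RatioMap,
    target: VolumeImage,
    threshold: float = 2.00,
    threshold_first: bool = False,
) -> SegmentationResult:
    """Interpolate a CSI ratio map to a target grid and threshold it.

    Default order is interpolate-then-threshold (sub-voxel ROI boundaries).
    ``threshold_first=True`` instead thresholds on the CSI grid and
    resamples the binary mask (a voxel belongs to the ROI when the blocky
    mask covers its center), for comparison with block-resolution contours.
    """
    ratio_anat = remap_to_anatomy(ratio_map, target)
    if threshold_first:
        csi_mask = segment_threshold(ratio_map.values, threshold).astype(float)
        blocky = remap_to_anatomy(
            RatioMap(
                values=np.where(np.isfinite(ratio_map.values), csi_mask, np.nan),
                accepted=ratio_map.accepted,
                slice_max=ratio_map.slice_max,
                geometry=ratio_map.geometry,
            ),
            target,
        )
        with np.errstate(invalid="ignore"):
            arr = np.where(np.isfinite(blocky.array), blocky.array >= 0.5, False)
        roi = BinaryMask(
            array=arr, spacing=target.spacing, origin=target.origin,
            direction=target.direction, modality="MASK",
        )
    else:
        roi = segment_threshold(ratio_anat, threshold)
    return SegmentationResult(ratio=ratio_anat, roi=roi, threshold=threshold)


def burn_roi(anatomy_slice: np.ndarray, mask_slice: np.ndarray) -> np.ndarray:
    """Highlight an ROI in pure red over a grayscale anatomical slice."""
    anatomy_slice = np.asarray(anatomy_slice)
    mask_slice = np.asarray(mask_slice, dtype=bool)
    if anatomy_slice.shape != mask_slice.shape:
        raise ValueError(
            f"shape mismatch: anatomy {anatomy_slice.shape} vs mask {mask_slice.shape}"
        )
    if anatomy_slice.dtype != np.uint8:
        lo, hi = float(anatomy_slice.min()), float(anatomy_slice.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        anatomy_slice = np.round((anatomy_slice - lo) * scale).astype(np.uint8)
    rgb = np.repeat(anatomy_slice[:, :, None], 3, axis=2)
    rgb[mask_slice] = (255, 0, 0)
    return rgb
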