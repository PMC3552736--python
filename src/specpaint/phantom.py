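"""Synthetic head phantom for end-to-end pipeline validation.

The generator produces everything the downstream stages consume, with known
ground truth: CT-like and MR-like anatomical volumes of a simplified head
(brain ellipsoid, skull shell, ventricles, an enhancing lesion with
surrounding edema), a continuous Cho/NAA ratio field sampled on the CSI
grid, voxel-rejection flags, a structure set (CE lesion, edema, brainstem,
optic chiasm, brain), vendor-style anatomic-metabolic composite snapshots,
and prescription dose grids with smooth falloff.

Everything is deterministic for a fixed config + seed, and the continuous
ratio field can be evaluated on any grid, which is what makes round-trip
and Dice comparisons against ground truth meaningful.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .colortable import ColorTable, default_table, hsv_to_rgb8
from .grids import BinaryMask, CsiGeometry, StructureSet, VolumeImage

log = logging.getLogger(__name__)

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "CompositeSlice",
    "LesionSizingError",
    "make_phantom",
    "render_composites",
    "make_dose",
]


class LesionSizingError(ValueError):
    """A configured lesion does not fit inside the CSI field of view."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic study.

    Geometry defaults follow a typical pre-RT glioblastoma protocol:
    anatomical MR at 0.90x0.90x3.00 mm, planning CT at 0.98x0.98x2.50 mm,
    and a 16x16x8 CSI box of 1 cm^3 voxels (100x100 mm^2 FOV, 25 mm slabs).
    """

    csi: CsiGeometry = field(default_factory=CsiGeometry)
    anat_spacing_mm: tuple[float, float, float] = (0.9, 0.9, 3.0)
    ct_spacing_mm: tuple[float, float, float] = (0.98, 0.98, 2.5)
    anat_fov_mm: tuple[float, float, float] = (180.0, 180.0, 225.0)
    lesion_center_mm: tuple[float, float, float] = (18.0, -6.0, -10.0)
    lesion_sigma_mm: tuple[float, float, float] = (14.0, 12.0, 16.0)
    # Metabolic abnormality: offset from the enhancing lesion (MRSI-positive
    # tissue need not coincide with contrast enhancement).
    metabolic_offset_mm: tuple[float, float, float] = (-6.0, 5.0, -15.0)
    metabolic_sigma_mm: tuple[float, float, float] = (16.0, 14.0, 30.0)
    ratio_background: float = 0.4
    ratio_peak: float = 2.65
    rejection_fraction: float = 0.15
    anat_noise_sigma: float = 0.0
    n_texture_blobs: int = 36

    def __post_init__(self) -> None:
        if self.ratio_peak < self.ratio_background or self.ratio_background < 0:
            raise ValueError("need 0 <= ratio_background <= ratio_peak")
        if not 0.0 <= self.rejection_fraction <= 1.0:
            raise ValueError("rejection_fraction must be in [0, 1]")
        # A lesion is "too large" when its ~95% support (4 sigma across)
        # exceeds the CSI in-plane field of view.
        if 4.0 * max(self.lesion_sigma_mm[:2]) > min(self.csi.fov_mm):
            raise LesionSizingError(
                "lesion does not fit in the CSI field of view "
                f"(4*sigma = {4 * max(self.lesion_sigma_mm[:2]):.1f} mm "
                f"> FOV {min(self.csi.fov_mm):.1f} mm)"
            )


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic case."""

    config: PhantomConfig
    seed: int
    ct: VolumeImage
    t1_gd: VolumeImage
    t2: VolumeImage
    ratio_field: np.ndarray  # true Cho/NAA on the CSI grid (n_slices, ny, nx)
    rejected: np.ndarray  # bool, same shape
    slice_maxima: np.ndarray  # per-slice max over *accepted* voxels
    structures: StructureSet
    # Continuous-truth evaluations on the anatomical grid:
    ratio_on_anatomy: VolumeImage  # NaN outside the CSI box
    texture_centers: np.ndarray = field(repr=False, default=None)

    @property
    def accepted(self) -> np.ndarray:
        return ~self.rejected

    def true_mask(self, threshold: float = 2.0) -> BinaryMask:
        """Ground-truth {Cho/NAA >= threshold} region on the anatomical grid."""
        arr = self.ratio_on_anatomy.array
        with np.errstate(invalid="ignore"):
            mask = np.where(np.isfinite(arr), arr >= threshold, False)
        return BinaryMask(
            array=mask,
            spacing=self.ratio_on_anatomy.spacing,
            origin=self.ratio_on_anatomy.origin,
            direction=self.ratio_on_anatomy.direction,
            modality="MASK",
        )


@dataclass
class CompositeSlice:
    """One vendor-style anatomic-metabolic snapshot (RGB over grayscale).

    The overlay colors CSI voxels as solid 6.25 mm blocks resampled onto the
    anatomical pixel grid; achromatic pixels are pure underlay.
    """

    rgb: np.ndarray  # (ny, nx, 3) uint8
    csi_slice_index: int
    pixel_spacing_mm: tuple[float, float]
    pixel_origin_mm: tuple[float, float]  # world (x, y) of pixel [0, 0] center
    source_anat_index: int
    no_overlay: bool = False

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[-1] != 3 or self.rgb.dtype != np.uint8:
            raise ValueError("rgb must be (ny, nx, 3) uint8")


# ---------------------------------------------------------------------------
# Continuous fields
# ---------------------------------------------------------------------------

def _gauss(x, y, z, center, sigma):
    cx, cy, cz = center
    sx, sy, sz = sigma
    return np.exp(
        -0.5 * (((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 + ((z - cz) / sz) ** 2)
    )


def _ratio_function(cfg: PhantomConfig):
    """Continuous true Cho/NAA field: background + one metabolic Gaussian."""
    center = tuple(
        c + o for c, o in zip(cfg.lesion_center_mm, cfg.metabolic_offset_mm)
    )
    amp = cfg.ratio_peak - cfg.ratio_background

    def ratio(x, y, z):
        return cfg.ratio_background + amp * _gauss(x, y, z, center, cfg.metabolic_sigma_mm)

    return ratio


def _make_grid(fov, spacing, modality) -> VolumeImage:
    n = tuple(int(round(f / s)) for f, s in zip(fov, spacing))
    origin = tuple(-f / 2 + s / 2 for f, s in zip(fov, spacing))
    arr = np.zeros((n[2], n[1], n[0]), dtype=float)
    return VolumeImage(array=arr, spacing=spacing, origin=origin, modality=modality)


def _anatomy_fields(cfg: PhantomConfig, vol: VolumeImage, rng_centers: np.ndarray):
    """Evaluate head-tissue membership fields on a volume's grid."""
    x, y, z = vol.voxel_centers()
    head = ((x / 82.0) ** 2 + (y / 86.0) ** 2 + (z / 108.0) ** 2) <= 1.0
    brain = ((x / 72.0) ** 2 + (y / 76.0) ** 2 + (z / 98.0) ** 2) <= 1.0
    skull = head & ~brain
    vent_l = (((x - 12) / 8.0) ** 2 + ((y - 6) / 18.0) ** 2 + ((z - 12) / 14.0) ** 2) <= 1.0
    vent_r = (((x + 12) / 8.0) ** 2 + ((y - 6) / 18.0) ** 2 + ((z - 12) / 14.0) ** 2) <= 1.0
    ventricles = (vent_l | vent_r) & brain
    brainstem = (
        ((x / 11.0) ** 2 + ((y - 12) / 11.0) ** 2 + ((z + 62) / 30.0) ** 2) <= 1.0
    ) & brain
    chiasm = (
        ((x / 9.0) ** 2 + ((y + 24) / 5.0) ** 2 + ((z + 40) / 4.0) ** 2) <= 1.0
    ) & brain

    lesion = _gauss(x, y, z, cfg.lesion_center_mm, cfg.lesion_sigma_mm)
    edema_sigma = tuple(1.8 * s for s in cfg.lesion_sigma_mm)
    edema = _gauss(x, y, z, cfg.lesion_center_mm, edema_sigma)

    # Smooth deterministic texture shared by both modalities: breaks the
    # head's symmetry so rigid registration has a unique optimum.
    texture = np.zeros_like(x)
    for cx, cy, cz, amp in rng_centers:
        texture += amp * _gauss(x, y, z, (cx, cy, cz), (9.0, 9.0, 9.0))
    texture *= brain

    return {
        "x": x, "y": y, "z": z,
        "head": head, "brain": brain, "skull": skull,
        "ventricles": ventricles, "brainstem": brainstem, "chiasm": chiasm,
        "lesion": lesion, "edema": edema, "texture": texture,
    }


def _texture_centers(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_texture_blobs
    centers = rng.uniform([-55, -60, -70], [55, 60, 70], size=(n, 3))
    amps = rng.uniform(-1.0, 1.0, size=(n, 1))
    return np.hstack([centers, amps])


def make_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomTruth:
    """Generate one synthetic case; bit-identical for identical config+seed."""
    cfg = config if config is not None else PhantomConfig()
    rng = np.random.default_rng(seed)
    tex = _texture_centers(cfg, rng)

    # -- anatomical volumes ------------------------------------------------
    t1 = _make_grid(cfg.anat_fov_mm, cfg.anat_spacing_mm, "MR")
    f = _anatomy_fields(cfg, t1, tex)
    t1_arr = (
        30.0
        + 470.0 * f["brain"]
        + 120.0 * f["skull"]
        - 320.0 * f["ventricles"]
        + 420.0 * f["lesion"] * f["brain"]
        + 160.0 * f["texture"]
    )
    t2_arr = (
        30.0
        + 370.0 * f["brain"]
        + 60.0 * f["skull"]
        + 350.0 * f["ventricles"]
        + 380.0 * f["edema"] * f["brain"]
        + 130.0 * f["texture"]
    )
    ct = _make_grid(cfg.anat_fov_mm, cfg.ct_spacing_mm, "CT")
    fc = _anatomy_fields(cfg, ct, tex)
    ct_arr = (
        -1000.0
        + 1040.0 * fc["head"]
        + 660.0 * fc["skull"]
        - 100.0 * fc["ventricles"]
        + 60.0 * fc["lesion"] * fc["brain"]
        + 180.0 * fc["texture"]
    )
    if cfg.anat_noise_sigma > 0:
        t1_arr = t1_arr + rng.normal(0, cfg.anat_noise_sigma, t1_arr.shape)
        t2_arr = t2_arr + rng.normal(0, cfg.anat_noise_sigma, t2_arr.shape)
        ct_arr = ct_arr + rng.normal(0, cfg.anat_noise_sigma, ct_arr.shape)
    t1 = t1.with_array(t1_arr)
    t2 = t1.with_array(t2_arr, modality="MR")
    ct = ct.with_array(ct_arr)

    # -- structures on the anatomical grid ----------------------------------
    def mask_of(arr) -> BinaryMask:
        return BinaryMask(
            array=arr, spacing=t1.spacing, origin=t1.origin,
            direction=t1.direction, modality="MASK",
        )

    ratio_fn = _ratio_function(cfg)
    # Anatomical-resolution ground truth honors the acquisition's geometry:
    # continuous in-plane, but evaluated at each 25 mm slab's center plane
    # (a slab acquisition carries no sub-slab z-information).
    slab_idx = np.clip(
        np.round(cfg.csi.world_to_voxel(
            np.stack([f["x"], f["y"], f["z"]], axis=-1).reshape(-1, 3)
        )[:, 2]).astype(int).reshape(f["z"].shape),
        0, cfg.csi.n_slices - 1,
    )
    z_slab = (
        cfg.csi.box_origin_mm[2]
        + (slab_idx + 0.5) * cfg.csi.slice_thickness_mm
    )
    ratio_anat = ratio_fn(f["x"], f["y"], z_slab)
    inside_box = _inside_csi_box(cfg.csi, f["x"], f["y"], f["z"])
    ratio_anat_masked = np.where(inside_box, ratio_anat, np.nan)

    structures = StructureSet(
        masks={
            "gtv1_ce": mask_of(f["lesion"] >= 0.5),
            "edema_t2": mask_of(f["edema"] >= 0.35),
            "gtv2_truth": mask_of(inside_box & (ratio_anat >= 2.0)),
            "brainstem": mask_of(f["brainstem"]),
            "chiasm": mask_of(f["chiasm"]),
            "brain": mask_of(f["brain"]),
        }
    )

    # -- CSI-grid truth ------------------------------------------------------
    geom = cfg.csi
    n_s, n_j, n_i = geom.shape
    ii, jj, ss = np.meshgrid(np.arange(n_i), np.arange(n_j), np.arange(n_s), indexing="ij")
    centers = np.stack(
        [
            geom.voxel_center(i, j, s)
            for i, j, s in zip(ii.ravel(), jj.ravel(), ss.ravel())
        ]
    )
    ratio_csi = ratio_fn(centers[:, 0], centers[:, 1], centers[:, 2]).reshape(
        n_i, n_j, n_s
    ).transpose(2, 1, 0)  # -> (s, j, i)

    rejected = _edge_rejection(geom, cfg.rejection_fraction, rng)
    accepted = ~rejected
    slice_maxima = np.array(
        [
            ratio_csi[s][accepted[s]].max() if accepted[s].any() else np.nan
            for s in range(n_s)
        ]
    )

    truth = PhantomTruth(
        config=cfg,
        seed=seed,
        ct=ct,
        t1_gd=t1,
        t2=t2,
        ratio_field=ratio_csi,
        rejected=rejected,
        slice_maxima=slice_maxima,
        structures=structures,
        ratio_on_anatomy=t1.with_array(ratio_anat_masked, modality="RATIO"),
        texture_centers=tex,
    )
    log.info(
        "phantom seed=%d: slice maxima %s", seed, np.round(slice_maxima, 3).tolist()
    )
    return truth


def _inside_csi_box(geom: CsiGeometry, x, y, z) -> np.ndarray:
    pts = np.stack([x, y, z], axis=-1)
    idx = geom.world_to_voxel(pts.reshape(-1, 3)).reshape(pts.shape)
    ni, nj = geom.matrix
    ns = geom.n_slices
    # inside means within the physical box (centers at -0.5..n-0.5 fractional)
    return (
        (idx[..., 0] >= -0.5) & (idx[..., 0] <= ni - 0.5)
        & (idx[..., 1] >= -0.5) & (idx[..., 1] <= nj - 0.5)
        & (idx[..., 2] >= -0.5) & (idx[..., 2] <= ns - 0.5)
    )


def _edge_rejection(
    geom: CsiGeometry, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli rejection restricted to the outer ring of each CSI slice,
    mimicking lipid/bone spectral contamination at the box boundary."""
    n_s, n_j, n_i = geom.shape
    rejected = np.zeros((n_s, n_j, n_i), dtype=bool)
    if fraction <= 0:
        return rejected
    ring = np.zeros((n_j, n_i), dtype=bool)
    ring[0, :] = ring[-1, :] = True
    ring[:, 0] = ring[:, -1] = True
    draws = rng.random((n_s, n_j, n_i))
    rejected[:, ring] = draws[:, ring] < fraction
    return rejected


# ---------------------------------------------------------------------------
# Composite rendering
# ---------------------------------------------------------------------------

def _to_gray8(slice2d: np.ndarray) -> np.ndarray:
    lo, hi = float(slice2d.min()), float(slice2d.max())
    if hi <= lo:
        return np.zeros(slice2d.shape, dtype=np.uint8)
    return np.round((slice2d - lo) / (hi - lo) * 255.0).astype(np.uint8)


def render_composites(
    truth: PhantomTruth, table: ColorTable | None = None
) -> list[CompositeSlice]:
    """Render one anatomic-metabolic snapshot per CSI slice.

    The underlay is the grayscale T1-Gd slice nearest the slab center; the
    overlay paints each accepted CSI voxel as a solid block with
    hue = table(ratio / slice_max), full saturation and value.  Rejected
    voxels (and everything outside the box) show the bare anatomy.
    """
    if table is None:
        table = default_table()
    geom = truth.config.csi
    t1 = truth.t1_gd
    n_s = geom.n_slices
    out: list[CompositeSlice] = []
    x, y, _ = t1.voxel_centers()
    px_x = x[0, 0, :]  # world x per column
    px_y = y[0, :, 0]  # world y per row
    for s in range(n_s):
        slab_center_z = geom.voxel_center(0, 0, s)[2]
        zs = t1.index_to_world(np.array([[0, 0, k] for k in range(t1.shape[0])]))[:, 2]
        k = int(np.argmin(np.abs(zs - slab_center_z)))
        gray = _to_gray8(t1.array[k])
        rgb = np.repeat(gray[:, :, None], 3, axis=2)

        smax = truth.slice_maxima[s]
        no_overlay = not np.isfinite(smax) or smax <= 0
        if no_overlay:
            warnings.warn(f"CSI slice {s} has no positive maximum; no overlay")
        else:
            # map every anatomy pixel to its CSI voxel
            gx = np.floor(
                (px_x - geom.box_origin_mm[0]) / geom.voxel_size_mm[0]
            ).astype(int)
            gy = np.floor(
                (px_y - geom.box_origin_mm[1]) / geom.voxel_size_mm[1]
            ).astype(int)
            in_x = (gx >= 0) & (gx < geom.matrix[0])
            in_y = (gy >= 0) & (gy < geom.matrix[1])
            for j in np.flatnonzero(in_y):
                cols = np.flatnonzero(in_x)
                vi = gx[cols]
                vj = gy[j]
                acc = truth.accepted[s, vj, vi]
                ratios = truth.ratio_field[s, vj, vi]
                u = np.clip(ratios / smax, 0.0, 1.0)
                hues = table.hue(u)
                colors = hsv_to_rgb8(hues, 1.0, 1.0)
                sel = cols[acc]
                rgb[j, sel] = colors[acc]
        out.append(
            CompositeSlice(
                rgb=rgb,
                csi_slice_index=s,
                pixel_spacing_mm=(t1.spacing[0], t1.spacing[1]),
                pixel_origin_mm=(float(px_x[0]), float(px_y[0])),
                source_anat_index=k,
                no_overlay=no_overlay,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Dose
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrescriptionSpec:
    """Per-target prescriptions (Gy) and a Gaussian falloff width (mm)."""

    prescriptions: tuple[tuple[str, float], ...] = (("ptv1", 60.0), ("ptv2", 72.0))
    falloff_mm: float = 12.0

    def __post_init__(self) -> None:
        if any(rx <= 0 for _, rx in self.prescriptions):
            raise ValueError("prescriptions must be positive")
        if self.falloff_mm < 0:
            raise ValueError("falloff width must be >= 0")


def make_dose(structures: StructureSet, plan: PrescriptionSpec | None = None):
    """Synthesize an idealized dose grid from PTV masks.

    Dose equals the prescription inside each PTV and falls off smoothly and
    isotropically outside it, dose(d) = Rx * exp(-0.5 (d / w)^2) with d the
    Euclidean distance (mm) to the PTV surface.  Where targets overlap the
    higher prescription wins.  ``falloff_mm = 0`` gives the degenerate
    step-function plan.  Returns a :class:`specpaint.dosimetry.DoseGrid`.
    """
    from .dosimetry import DoseGrid

    if plan is None:
        plan = PrescriptionSpec()
    ref = None
    dose = None
    overlap_logged = False
    for name, rx in plan.prescriptions:
        if name not in structures:
            raise KeyError(f"structure {name!r} missing from structure set")
        mask = structures[name]
        if ref is None:
            ref = mask
            dose = np.zeros(mask.array.shape, dtype=float)
        else:
            ref.require_same_grid(mask)
        if not mask.array.any():
            warnings.warn(f"target {name!r} is empty; contributes no dose")
            continue
        if plan.falloff_mm == 0:
            contrib = np.where(mask.array, float(rx), 0.0)
        else:
            dist = ndimage.distance_transform_edt(
                ~mask.array, sampling=mask.spacing[::-1]
            )
            contrib = rx * np.exp(-0.5 * (dist / plan.falloff_mm) ** 2)
        if dose.max() > 0 and np.any((contrib > 0) & (dose > 0)) and not overlap_logged:
            log.info("overlapping prescriptions: higher dose wins voxel-wise")
            overlap_logged = True
        dose = np.maximum(dose, contrib)
    return DoseGrid(
        array=dose,
        spacing=ref.spacing,
        origin=ref.origin,
        direction=ref.direction,
        modality="RTDOSE",
        prescriptions=dict(plan.prescriptions),
    )
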