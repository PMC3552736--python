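"""Radiotherapy target-volume construction by Euclidean margin expansion.

Two nested target sets are built.  The conventional set starts from the
contrast-enhancing lesion: CTV1 = (GTV1 expanded by 17.0 mm) union the
T2 edema, PTV1 = CTV1 + 3.0 mm.  The dose-painting set starts from the
MRSI abnormality (Cho/NAA >= 2.00): GTV2 = the segmented MRSI mask,
CTV2 = (GTV2 + 7.0 mm) union GTV1, PTV2 = CTV2 + 3.0 mm.

"GTV + margin including structure X" is read as (GTV expanded) union X:
the named structure must end up inside the CTV whatever its distance from
the GTV.  Expansions use the exact Euclidean distance transform in
physical units, so anisotropic voxels are handled correctly; no anatomical
barrier clipping is applied by default (a clip mask is available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, GridMismatchError, StructureSet

log = logging.getLogger(__name__)

__all__ = [
    "MarginSpec",
    "expand_margin",
    "build_target_set",
    "normal_brain",
]


@dataclass(frozen=True)
class MarginSpec:
    """Margins (mm) for target construction and the MRSI threshold."""

    ctv1_margin: float = 17.0
    ctv2_margin: float = 7.0
    ptv_margin: float = 3.0
    threshold: float = 2.00

    def __post_init__(self) -> None:
        if min(self.ctv1_margin, self.ctv2_margin, self.ptv_margin) < 0:
            raise ValueError("margins must be >= 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def expand_margin(
    mask: BinaryMask, margin_mm: float, clip_to: BinaryMask | None = None
) -> BinaryMask:
    """Isotropic physical-space expansion of a binary mask.

    Output voxels are exactly those whose center lies within ``margin_mm``
    (Euclidean, in mm) of the input set, computed with the distance
    transform under the grid's physical spacing — exact under anisotropy,
    unlike iterated structuring elements.  Expansion is clipped at the grid
    edge (with a warning if the margin reaches it).
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    arr = mask.array
    if not arr.any():
        warnings.warn("expanding an empty mask yields an empty mask")
        return replace(mask, array=arr.copy())
    if margin_mm == 0:
        out = arr.copy()
    else:
        # distance from each background voxel to the nearest set voxel
        dist = ndimage.distance_transform_edt(~arr, sampling=mask.spacing[::-1])
        out = dist <= margin_mm
        edge = np.zeros_like(out)
        edge[0], edge[-1] = True, True
        edge[:, 0], edge[:, -1] = True, True
        edge[:, :, 0], edge[:, :, -1] = True, True
        if np.any(out & edge & ~arr):
            warnings.warn("margin expansion reached the grid edge; clipped")
    if clip_to is not None:
        mask.require_same_grid(clip_to)
        out = out & clip_to.array
    return replace(mask, array=out)


def build_target_set(
    gtv1_ce: BinaryMask,
    edema_t2: BinaryMask,
    mrsi_mask: BinaryMask,
    spec: MarginSpec | None = None,
    clip_to: BinaryMask | None = None,
) -> StructureSet:
    """Construct GTV/CTV/PTV pairs for the 60 Gy and boost prescriptions."""
    spec = spec or MarginSpec()
    for other in (edema_t2, mrsi_mask):
        if not gtv1_ce.same_grid(other):
            raise GridMismatchError("all input masks must share one grid")

    ctv1 = expand_margin(gtv1_ce, spec.ctv1_margin, clip_to).union(edema_t2)
    ptv1 = expand_margin(ctv1, spec.ptv_margin, clip_to)
    gtv2 = replace(mrsi_mask, array=mrsi_mask.array.copy())
    ctv2 = expand_margin(gtv2, spec.ctv2_margin, clip_to).union(gtv1_ce)
    ptv2 = expand_margin(ctv2, spec.ptv_margin, clip_to)

    out = StructureSet(
        masks={
            "gtv1": gtv1_ce,
            "ctv1": ctv1,
            "ptv1": ptv1,
            "gtv2": gtv2,
            "ctv2": ctv2,
            "ptv2": ptv2,
        }
    )
    log.info(
        "target volumes (cm3): %s",
        {k: round(v, 2) for k, v in out.volumes_cm3().items()},
    )
    return out


def normal_brain(brain: BinaryMask, ptv1: BinaryMask) -> BinaryMask:
    """Normal-brain structure: whole brain minus PTV1."""
    return brain.minus(ptv1)
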