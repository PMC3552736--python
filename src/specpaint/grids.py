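"""Shared spatial containers: scalar volumes, binary masks, CSI grid geometry.

Conventions used throughout the package:

* Patient coordinates are DICOM LPS, millimetres.
* Voxel arrays are indexed ``array[k, j, i]`` with ``i`` along x, ``j`` along
  y and ``k`` along z; positions refer to voxel *centers*, 0-based.
* ``world = origin + direction @ (i*sx, j*sy, k*sz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "StructureSet",
    "CsiGeometry",
    "GridMismatchError",
]


class GridMismatchError(ValueError):
    """Two grids expected to coincide do not."""


def _as_direction(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float).reshape(3, 3)
    if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
        raise ValueError("direction cosines must be orthonormal")
    return d


@dataclass
class VolumeImage:
    """A 3D scalar (or RGB) image on a regular grid in patient space.

    Parameters
    ----------
    array : ndarray, shape (nz, ny, nx) or (nz, ny, nx, 3)
        Voxel values; the trailing axis of length 3 marks an RGB volume.
    spacing : (sx, sy, sz) in mm, all > 0.
    origin : patient-space position (mm, LPS) of the center of voxel [0,0,0].
    direction : 3x3 orthonormal direction cosines (columns = image axes).
    modality : free-text label ("CT", "MR", "SC", ...).
    """

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality: str = ""

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim not in (3, 4) or self.array.size == 0:
            raise ValueError("array must be a non-empty 3D (or 3D+RGB) array")
        if self.array.ndim == 4 and self.array.shape[-1] != 3:
            raise ValueError("4D arrays must carry 3 channels on the last axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = _as_direction(self.direction)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.array.shape

    @property
    def is_rgb(self) -> bool:
        return self.array.ndim == 4

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (i, j, k) to patient coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        scaled = ijk * np.asarray(self.spacing)
        return np.asarray(self.origin) + scaled @ self.direction.T

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        rel = (xyz - np.asarray(self.origin)) @ self.direction
        return rel / np.asarray(self.spacing)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Patient-space x, y, z coordinate arrays, each shaped like the volume."""
        nz, ny, nx = self.array.shape[:3]
        kk, jj, ii = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        pts = self.index_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
        pts = pts.reshape(nz, ny, nx, 3)
        return pts[..., 0], pts[..., 1], pts[..., 2]

    def same_grid(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return (
            self.array.shape[:3] == other.array.shape[:3]
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def require_same_grid(self, other: "VolumeImage") -> None:
        if not self.same_grid(other):
            raise GridMismatchError("volumes are not on the same grid")

    def with_array(self, array: np.ndarray, modality: str | None = None) -> "VolumeImage":
        return replace(
            self, array=array, modality=self.modality if modality is None else modality
        )

    # -- SimpleITK interop -------------------------------------------------
    def to_sitk(self):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(self.array, dtype=np.float64))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten(order="C")))
        return img

    @classmethod
    def from_sitk(cls, img, modality: str = "") -> "VolumeImage":
        import SimpleITK as sitk

        arr = sitk.GetArrayFromImage(img)
        return cls(
            array=arr,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
            modality=modality,
        )


class BinaryMask(VolumeImage):
    """A VolumeImage restricted to {0, 1} voxels, with a physical volume."""

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be strictly binary")
            arr = arr.astype(bool)
        self.array = arr
        super().__post_init__()

    @property
    def volume_cm3(self) -> float:
        return float(self.array.sum()) * self.voxel_volume_cm3

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        self.require_same_grid(other)
        return replace(self, array=self.array & other.array)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        self.require_same_grid(other)
        return replace(self, array=self.array | other.array)

    def minus(self, other: "BinaryMask") -> "BinaryMask":
        self.require_same_grid(other)
        return replace(self, array=self.array & ~other.array)


@dataclass
class StructureSet:
    """Named binary structures sharing one grid (GTV/CTV/PTV, OARs, brain)."""

    masks: dict[str, BinaryMask]

    def __post_init__(self) -> None:
        names = list(self.masks)
        for name in names[1:]:
            if not self.masks[name].same_grid(self.masks[names[0]]):
                raise GridMismatchError(f"structure {name!r} is on a different grid")

    def __getitem__(self, name: str) -> BinaryMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)

    def volumes_cm3(self) -> dict[str, float]:
        return {name: m.volume_cm3 for name, m in self.masks.items()}


@dataclass
class CsiGeometry:
    """Geometry of the chemical-shift-imaging acquisition box.

    Defaults reproduce a 100x100 mm^2 in-plane field of view on a 16x16
    phase-encode matrix with eight 25.0 mm slabs, i.e. 6.25x6.25x25.0 mm^3
    (~1 cm^3) voxels.
    """

    fov_mm: tuple[float, float] = (100.0, 100.0)
    matrix: tuple[int, int] = (16, 16)
    n_slices: int = 8
    slice_thickness_mm: float = 25.0
    box_origin_mm: tuple[float, float, float] = (-50.0, -50.0, -100.0)
    box_orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        if min(self.fov_mm) <= 0 or min(self.matrix) <= 0:
            raise ValueError("FOV and matrix must be positive")
        if self.n_slices <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("slice count and thickness must be positive")
        self.box_orientation = _as_direction(self.box_orientation)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return (
            self.fov_mm[0] / self.matrix[0],
            self.fov_mm[1] / self.matrix[1],
            self.slice_thickness_mm,
        )

    @property
    def voxel_volume_cm3(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_slices, ny, nx) matching RatioMap array layout."""
        return (self.n_slices, self.matrix[1], self.matrix[0])

    def voxel_center(self, i: float, j: float, s: float) -> np.ndarray:
        """Patient position of CSI voxel center (i along x, j along y, s slab)."""
        vx, vy, vz = self.voxel_size_mm
        local = np.array([(i + 0.5) * vx, (j + 0.5) * vy, (s + 0.5) * vz])
        return np.asarray(self.box_origin_mm) + self.box_orientation @ local

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional CSI voxel indices (i, j, s); centers at integers."""
        xyz = np.asarray(xyz, dtype=float)
        rel = (xyz - np.asarray(self.box_origin_mm)) @ self.box_orientation
        v = np.asarray(self.voxel_size_mm)
        return rel / v - 0.5

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return (
            self.fov_mm[0],
            self.fov_mm[1],
            self.n_slices * self.slice_thickness_mm,
        )
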