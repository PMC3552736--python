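"""DICOM I/O and header transplantation.

MRSI snapshots exported by scanner consoles are RGB secondary captures that
a treatment-planning system cannot fuse with the planning CT, because they
lack the frame-of-reference and geometry headers of a registered MR series.
The fix implemented here copies the DICOM headers of the T1-Gd series —
patient identity, study, frame of reference, image position/orientation and
pixel spacing — into the generated anatomic-metabolic images, while
regenerating every instance identifier (a TPS database must never see two
objects with one SOPInstanceUID) and marking the images as derived.

``read_series``/``write_series`` handle plain scalar volumes (CT, MR) and
8-bit interleaved RGB secondary captures.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grids import VolumeImage

__all__ = [
    "HeaderTransplantSpec",
    "SeriesReadError",
    "read_series",
    "write_series",
    "transplant_headers",
]

_SOP_CLASS = {
    "CT": "1.2.840.10008.5.1.4.1.1.2",
    "MR": "1.2.840.10008.5.1.4.1.1.4",
    "SC": "1.2.840.10008.5.1.4.1.1.7",  # secondary capture
}


class SeriesReadError(ValueError):
    """Directory does not contain one spatially coherent DICOM series."""


@dataclass(frozen=True)
class HeaderTransplantSpec:
    """What to copy, what to regenerate, what to set during transplantation.

    The frame-of-reference UID is always copied (it is what makes the TPS
    treat two series as co-registered) and instance identifiers are always
    regenerated — both are enforced regardless of the configured lists.
    """

    copy_groups: tuple[str, ...] = ("patient", "study", "frame_of_reference", "geometry")
    regenerate: tuple[str, ...] = ("SOPInstanceUID", "SeriesInstanceUID")
    set_tags: dict = field(
        default_factory=lambda: {
            "SeriesDescription": "Anatomic-metabolic Cho/NAA map (derived)",
            "ImageType": ["DERIVED", "SECONDARY"],
        }
    )

    def __post_init__(self) -> None:
        if "frame_of_reference" not in self.copy_groups:
            raise ValueError("the frame-of-reference UID must always be copied")
        for uid in ("SOPInstanceUID", "SeriesInstanceUID"):
            if uid not in self.regenerate:
                raise ValueError(f"{uid} must always be regenerated, never copied")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _slice_normal(ds: Dataset) -> np.ndarray:
    iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
    return np.cross(iop[:3], iop[3:])


def read_series(directory) -> VolumeImage:
    """Read one DICOM series from a directory into a VolumeImage.

    Slices are sorted by their projected position along the slice normal;
    spacing is inferred from consecutive gaps.  A directory mixing series,
    missing geometry tags, or irregular slice spacing (gantry tilt, missing
    slice) raises :class:`SeriesReadError`.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        datasets.append(ds)
    if not datasets:
        raise SeriesReadError(f"no DICOM files found in {directory}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise SeriesReadError(f"directory mixes {len(uids)} series")
    for ds in datasets:
        for tag in ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing"):
            if tag not in ds:
                raise SeriesReadError(f"missing geometry tag {tag}")

    normal = _slice_normal(datasets[0])
    datasets.sort(
        key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
    )
    pos = np.array(
        [np.dot(np.asarray(ds.ImagePositionPatient, float), normal) for ds in datasets]
    )
    if len(datasets) > 1:
        gaps = np.diff(pos)
        if gaps.min() <= 0:
            raise SeriesReadError("duplicate or non-advancing slice positions")
        if (gaps.max() - gaps.min()) > 1e-3 * max(1.0, gaps.mean()) + 1e-4:
            raise SeriesReadError(
                f"irregular slice spacing (gaps {gaps.min():.4f}..{gaps.max():.4f} mm)"
            )
        dz = float(gaps.mean())
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    first = datasets[0]
    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    row, col = iop[:3], iop[3:]
    direction = np.column_stack([row, col, np.cross(row, col)])
    # PixelSpacing is (row spacing, column spacing) = (dy, dx)
    dy, dx = (float(v) for v in first.PixelSpacing)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        if arr.ndim == 2:
            arr = arr * slope + intercept
        slices.append(arr)
    vol = np.stack(slices, axis=0)

    return VolumeImage(
        array=vol,
        spacing=(dx, dy, dz),
        origin=tuple(np.asarray(first.ImagePositionPatient, dtype=float)),
        direction=direction,
        modality=str(getattr(first, "Modality", "")),
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _base_dataset(modality: str, patient: dict | None) -> Dataset:
    ds = Dataset()
    patient = patient or {}
    ds.PatientName = patient.get("PatientName", "PHANTOM^SYNTHETIC")
    ds.PatientID = patient.get("PatientID", "SPECPAINT-000")
    ds.PatientBirthDate = patient.get("PatientBirthDate", "")
    ds.PatientSex = patient.get("PatientSex", "O")
    ds.StudyInstanceUID = patient.get("StudyInstanceUID", generate_uid())
    ds.StudyID = patient.get("StudyID", "1")
    ds.AccessionNumber = ""
    ds.StudyDate = "20130102"
    ds.StudyTime = "000000"
    ds.ReferringPhysicianName = ""
    ds.Modality = modality
    return ds


def write_series(
    volume: VolumeImage,
    directory,
    modality: str | None = None,
    series_description: str = "",
    patient: dict | None = None,
    frame_of_reference_uid: str | None = None,
) -> list[Path]:
    """Write a VolumeImage as an uncompressed DICOM series, one file per slice.

    Scalar volumes are stored as signed 16-bit with rescale tags; RGB volumes
    as 8-bit interleaved color secondary captures.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    modality = modality or (volume.modality if volume.modality in _SOP_CLASS else "SC")
    if modality not in _SOP_CLASS:
        modality = "SC"
    series_uid = generate_uid()
    for_uid = frame_of_reference_uid or generate_uid()
    nz = volume.array.shape[0]
    rgb = volume.is_rgb
    paths = []
    for k in range(nz):
        ds = _base_dataset(volume.modality or modality, patient)
        ds.Modality = volume.modality if volume.modality in ("CT", "MR") else modality
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = 1
        ds.SeriesDescription = series_description
        ds.FrameOfReferenceUID = for_uid
        ds.PositionReferenceIndicator = ""
        ds.SOPClassUID = _SOP_CLASS.get(ds.Modality, _SOP_CLASS["SC"])
        ds.SOPInstanceUID = generate_uid()
        ds.InstanceNumber = k + 1

        origin = volume.index_to_world(np.array([0.0, 0.0, float(k)]))
        ds.ImagePositionPatient = [float(v) for v in origin]
        ds.ImageOrientationPatient = [
            *(float(v) for v in volume.direction[:, 0]),
            *(float(v) for v in volume.direction[:, 1]),
        ]
        ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[0])]
        ds.SliceThickness = float(volume.spacing[2])

        sl = volume.array[k]
        ds.Rows, ds.Columns = int(sl.shape[0]), int(sl.shape[1])
        if rgb:
            ds.SamplesPerPixel = 3
            ds.PhotometricInterpretation = "RGB"
            ds.PlanarConfiguration = 0
            ds.BitsAllocated = ds.BitsStored = 8
            ds.HighBit = 7
            ds.PixelRepresentation = 0
            ds.PixelData = np.ascontiguousarray(sl, dtype=np.uint8).tobytes()
        else:
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 1
            ds.RescaleSlope = 1.0
            ds.RescaleIntercept = 0.0
            ds.PixelData = np.ascontiguousarray(
                np.round(sl).astype(np.int16)
            ).tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        # filename carries a series-unique component so two series can
        # coexist in one directory (read_series will still reject the mix)
        path = directory / f"{ds.Modality}_{series_uid[-6:]}_{k:04d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Header transplantation
# ---------------------------------------------------------------------------

def transplant_headers(
    source_dir,
    images: np.ndarray,
    out_dir,
    spec: HeaderTransplantSpec | None = None,
) -> list[Path]:
    """Copy T1-Gd headers into generated images and write the derived series.

    ``images`` is (n_slices, rows, cols[, 3]); one generated slice per source
    slice, matched by slice order along the series normal.  Geometry tags
    (position, orientation, pixel spacing), patient, study and the
    frame-of-reference UID are taken verbatim from the source; SOP and
    series instance UIDs are regenerated so no identifier collides with the
    source series.
    """
    spec = spec or HeaderTransplantSpec()
    source_dir = Path(source_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    datasets = []
    for p in sorted(source_dir.iterdir()):
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:
            continue
    if not datasets:
        raise SeriesReadError(f"no DICOM files found in {source_dir}")
    normal = _slice_normal(datasets[0])
    datasets.sort(
        key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
    )

    images = np.asarray(images)
    if images.shape[0] != len(datasets):
        raise ValueError(
            f"slice-count mismatch: {images.shape[0]} generated vs "
            f"{len(datasets)} source slices"
        )
    rgb = images.ndim == 4

    new_series_uid = generate_uid()
    paths = []
    for k, src in enumerate(datasets):
        ds = copy.deepcopy(src)  # carries patient/study/FoR/geometry verbatim
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = new_series_uid
        ds.SOPClassUID = _SOP_CLASS["SC"]
        ds.SeriesNumber = int(getattr(src, "SeriesNumber", 0) or 0) + 500
        ds.InstanceNumber = k + 1
        for tag, value in spec.set_tags.items():
            setattr(ds, tag, value)

        sl = images[k]
        ds.Rows, ds.Columns = int(sl.shape[0]), int(sl.shape[1])
        if rgb:
            ds.SamplesPerPixel = 3
            ds.PhotometricInterpretation = "RGB"
            ds.PlanarConfiguration = 0
            ds.BitsAllocated = ds.BitsStored = 8
            ds.HighBit = 7
            ds.PixelRepresentation = 0
            for tag in ("RescaleSlope", "RescaleIntercept", "WindowCenter", "WindowWidth"):
                if tag in ds:
                    delattr(ds, tag)
            ds.PixelData = np.ascontiguousarray(sl, dtype=np.uint8).tobytes()
        else:
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 1
            ds.RescaleSlope = 1.0
            ds.RescaleIntercept = 0.0
            ds.PixelData = np.ascontiguousarray(
                np.round(sl).astype(np.int16)
            ).tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = out_dir / f"AM_{k:04d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths
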