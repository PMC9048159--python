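"""DICOM series reading and a minimal fixture writer.

``load_series`` assembles an :class:`~petmr_qa.core.ImageVolume` from one
directory of single-frame DICOM slices: it rejects mixed series, sorts
slices by their position along the slice normal, checks slice-spacing
consistency, applies rescale slope/intercept and extracts the metadata the
analyses need (b-value, PET units, series description, acquisition time).

``write_series`` is the inverse used by the synthetic-phantom generators so
that analyses can exercise the real ingestion path.  It emits minimal but
valid single-frame files (Explicit VR Little Endian).  Integer-valued data
within the int16 range round-trips bit-exactly (slope 1, intercept 0);
other data is linearly quantised to 16 bits.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import ImageVolume, Modality, QAError

__all__ = ["load_series", "write_series", "to_nifti"]

_MR_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.4"  # MR Image Storage
_PT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.128"  # PET Image Storage


class DicomSeriesError(QAError):
    """Raised when a directory does not hold one consistent image series."""


def _read_slices(directory: Path) -> list[pydicom.Dataset]:
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix != ".json")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue  # non-DICOM clutter is ignored
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise DicomSeriesError(f"no DICOM image files found in {directory}")
    return slices


def load_series(directory: str | Path) -> ImageVolume:
    """Load one spatially consistent DICOM series from a directory."""
    directory = Path(directory)
    slices = _read_slices(directory)

    uids = {str(ds.SeriesInstanceUID) for ds in slices}
    if len(uids) > 1:
        raise DicomSeriesError(f"mixed series in {directory}: UIDs {sorted(uids)}")

    first = slices[0]
    for tag in ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing"):
        if tag not in first:
            raise DicomSeriesError(f"missing geometry tag {tag} in {directory}")

    iop = np.array(first.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)

    slices.sort(key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, float), normal)))
    positions = np.array([np.dot(np.array(ds.ImagePositionPatient, float), normal) for ds in slices])

    if len(slices) > 1:
        gaps = np.diff(positions)
        if np.any(gaps <= 0):
            raise DicomSeriesError(f"duplicate or unordered slice positions in {directory}")
        if (gaps.max() - gaps.min()) > 0.01 * gaps.mean():
            raise DicomSeriesError(
                f"inconsistent slice spacing in {directory}: gaps {gaps.min():.4f}–{gaps.max():.4f} mm"
            )
        slice_spacing = float(gaps.mean())
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0) or 1.0)

    row_sp, col_sp = (float(v) for v in first.PixelSpacing)  # (between rows, between cols)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(arr * slope + intercept)
    # pixel_array is [row, col]; volume index order is (col=i, row=j, slice=k)
    voxels = np.stack([p.T for p in planes], axis=2)

    direction = np.column_stack([row_dir, col_dir, normal])
    modality = Modality.PET if str(getattr(first, "Modality", "MR")).upper() in ("PT", "PET") else Modality.MR

    meta: dict = {"series_description": str(getattr(first, "SeriesDescription", ""))}
    if modality is Modality.PET:
        meta["units"] = str(getattr(first, "Units", "BQML"))
    bval = first.get("DiffusionBValue")
    if bval is not None:
        meta["b_value"] = float(bval)

    acq_time = None
    if getattr(first, "AcquisitionDateTime", None):
        try:
            acq_time = _dt.datetime.strptime(str(first.AcquisitionDateTime)[:14], "%Y%m%d%H%M%S")
        except ValueError:
            acq_time = None

    return ImageVolume(
        voxels=voxels,
        spacing=(col_sp, row_sp, slice_spacing),
        origin=tuple(float(v) for v in first.ImagePositionPatient),
        direction=direction,
        modality=modality,
        acquisition_time=acq_time,
        meta=meta,
    )


def write_series(volume: ImageVolume, directory: str | Path, series_description: str = "") -> Path:
    """Write a volume as a minimal single-frame DICOM series.

    Returns the directory written.  Values are stored as int16 with a
    rescale transform; integer-valued volumes within int16 range are stored
    losslessly (slope 1, intercept 0).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    vox = np.asarray(volume.voxels, dtype=np.float64)
    vmin, vmax = float(vox.min()), float(vox.max())
    integral = np.allclose(vox, np.round(vox)) and vmin >= -32768 and vmax <= 32767
    if integral:
        slope, intercept = 1.0, 0.0
        stored = np.round(vox).astype(np.int16)
    else:
        span = max(vmax - vmin, 1e-12)
        slope = span / 32000.0
        intercept = vmin
        stored = np.round((vox - intercept) / slope).astype(np.int16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    sop_class = _PT_SOP_CLASS if volume.modality is Modality.PET else _MR_SOP_CLASS

    row_dir = volume.direction[:, 0]
    col_dir = volume.direction[:, 1]
    normal = volume.direction[:, 2]
    nx, ny, nz = volume.shape
    sx, sy, sz = volume.spacing
    origin = np.asarray(volume.origin, dtype=float)

    acq = volume.acquisition_time or _dt.datetime(2021, 1, 1, 12, 0, 0)

    for k in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = sop_class
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds.SOPClassUID = sop_class
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "PT" if volume.modality is Modality.PET else "MR"
        ds.SeriesDescription = series_description or volume.meta.get("series_description", "")
        ds.InstanceNumber = k + 1
        ds.PatientName = "QA^Phantom"
        ds.PatientID = "QA"
        ds.AcquisitionDateTime = acq.strftime("%Y%m%d%H%M%S")
        ds.StudyDate = acq.strftime("%Y%m%d")
        ds.StudyTime = acq.strftime("%H%M%S")

        ds.ImageOrientationPatient = [*map(float, row_dir), *map(float, col_dir)]
        ds.ImagePositionPatient = list(map(float, origin + k * sz * normal))
        ds.PixelSpacing = [float(sy), float(sx)]  # [between rows, between cols]
        ds.SliceThickness = float(sz)
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept

        if volume.modality is Modality.PET:
            ds.Units = volume.meta.get("units", "BQML")
        if "b_value" in volume.meta:
            ds.DiffusionBValue = float(volume.meta["b_value"])

        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()

        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)
    return directory


def to_nifti(volume: ImageVolume, path: str | Path) -> Path:
    """Export to NIfTI-1 for visual inspection (optional convenience)."""
    import nibabel as nib

    affine = np.eye(4)
    # NIfTI uses RAS; DICOM LPS -> flip x and y
    flip = np.diag([-1.0, -1.0, 1.0])
    affine[:3, :3] = flip @ volume.direction @ np.diag(volume.spacing)
    affine[:3, 3] = flip @ np.asarray(volume.origin)
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    path = Path(path)
    nib.save(img, str(path))
    return path
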