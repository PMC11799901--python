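"""Readers and writers for the standard radiotherapy volume formats.

DICOM (CT series, RTDOSE, RTSTRUCT) is supported for real clinical data;
NIfTI plus a JSON sidecar is the canonical format for synthetic fixtures so
the test suite never depends on external downloads.  Everything is converted
to/from the :class:`~sctqa.geometry.Volume` convention (axis order x, y, z;
voxel-centre addressing; columns of ``axes`` = index-axis directions).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from matplotlib.path import Path as MplPath

from sctqa.geometry import StructureMask, Volume

__all__ = [
    "read_dicom_ct_series",
    "write_dicom_ct_series",
    "read_rtdose",
    "write_rtdose",
    "rasterize_rtstruct",
    "read_nifti",
    "write_nifti",
]

_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"

SLICE_SPACING_TOL_MM = 0.01


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------

def read_dicom_ct_series(directory: str | Path, frame_id: str = "dicom") -> Volume:
    """Read a single-series DICOM CT directory into a Volume of HU.

    Slices are ordered by physical position along the slice normal; the
    slice spacing is measured from the positions themselves (any header
    slice-thickness tag is ignored).  Rescale slope/intercept are applied.

    Raises ``ValueError`` for mixed series or non-uniform slice spacing
    beyond ``SLICE_SPACING_TOL_MM``.
    """
    directory = Path(directory)
    slices = []
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
        except (pydicom.errors.InvalidDicomError, IsADirectoryError):
            continue
        if getattr(ds, "SOPClassUID", None) == _CT_STORAGE or hasattr(ds, "ImagePositionPatient"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no CT slices found in {directory}")
    series = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(series) != 1:
        raise ValueError(f"directory contains {len(series)} series; expected exactly one")

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    col_dir, row_dir = iop[:3], iop[3:]
    for ds in slices[1:]:
        if not np.allclose(ds.ImageOrientationPatient, iop, atol=1e-6):
            raise ValueError("inconsistent ImageOrientationPatient within series")
    normal = np.cross(col_dir, row_dir)
    slices.sort(key=lambda ds: float(np.dot(ds.ImagePositionPatient, normal)))

    zpos = np.array([float(np.dot(ds.ImagePositionPatient, normal)) for ds in slices])
    if len(slices) > 1:
        gaps = np.diff(zpos)
        if np.ptp(gaps) > SLICE_SPACING_TOL_MM:
            raise ValueError(
                f"non-uniform slice spacing: gaps range {gaps.min():.4f}-{gaps.max():.4f} mm"
            )
        sz = float(gaps.mean())
    else:
        sz = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)

    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)  # (between rows, between cols)
    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(float) * slope + intercept)
    stack = np.stack(planes, axis=0)  # (z, rows=y, cols=x)
    values = np.transpose(stack, (2, 1, 0))  # -> (x, y, z)

    axes = np.column_stack([col_dir, row_dir, normal])
    origin = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    return Volume(values, origin, (col_sp, row_sp, sz), axes, frame_id)


def write_dicom_ct_series(volume: Volume, directory: str | Path) -> list[Path]:
    """Write a Volume of HU as a DICOM CT series (one file per slice).

    HU are stored as int16 with rescale slope 1 / intercept -1024, so
    integer HU round-trip exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    nx, ny, nz = volume.shape
    col_dir, row_dir, normal = volume.axes[:, 0], volume.axes[:, 1], volume.axes[:, 2]
    paths = []
    for k in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = _CT_STORAGE
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = _CT_STORAGE
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "SYNTHETIC^PHANTOM"
        ds.PatientID = "SCTQA"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [*map(float, col_dir), *map(float, row_dir)]
        ds.ImagePositionPatient = list(map(float, volume.origin + k * volume.spacing[2] * normal))
        ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[0])]
        ds.SliceThickness = float(volume.spacing[2])
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        plane = np.round(volume.values[:, :, k].T + 1024).astype(np.int16)  # (rows, cols)
        ds.PixelData = plane.tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# DICOM RTDOSE
# ---------------------------------------------------------------------------

def read_rtdose(file: str | Path, frame_id: str = "dicom") -> Volume:
    """Read a DICOM RTDOSE grid into a Volume of Gy.

    Values are stored-integer x DoseGridScaling; geometry comes from
    ImagePositionPatient plus the GridFrameOffsetVector.  Non-uniform frame
    offsets and a missing scaling tag are rejected.
    """
    ds = pydicom.dcmread(Path(file))
    if "DoseGridScaling" not in ds:
        raise ValueError("RTDOSE missing DoseGridScaling tag")
    scaling = float(ds.DoseGridScaling)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        gaps = np.diff(offsets)
        if np.ptp(gaps) > SLICE_SPACING_TOL_MM:
            raise ValueError(f"non-uniform GridFrameOffsetVector: gaps {gaps.min():.4f}-{gaps.max():.4f} mm")
        sz = float(gaps.mean())
    else:
        sz = 1.0
    iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
    col_dir, row_dir = iop[:3], iop[3:]
    normal = np.cross(col_dir, row_dir)
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    stack = ds.pixel_array.astype(float) * scaling  # (frames=z, rows=y, cols=x)
    if stack.ndim == 2:
        stack = stack[None]
    values = np.transpose(stack, (2, 1, 0))
    origin = np.asarray(ds.ImagePositionPatient, dtype=float) + offsets[0] * normal
    axes = np.column_stack([col_dir, row_dir, normal])
    return Volume(values, origin, (col_sp, row_sp, sz), axes, frame_id)


def write_rtdose(volume: Volume, file: str | Path) -> Path:
    """Write a Volume of Gy as DICOM RTDOSE (32-bit unsigned, auto scaling)."""
    file = Path(file)
    vmax = float(np.max(volume.values)) if volume.values.size else 0.0
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.MediaStorageSOPClassUID = _RTDOSE_STORAGE
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.SOPClassUID = _RTDOSE_STORAGE
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nx, ny, nz = volume.shape
    ds.ImageOrientationPatient = [*map(float, volume.axes[:, 0]), *map(float, volume.axes[:, 1])]
    ds.ImagePositionPatient = list(map(float, volume.origin))
    ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[0])]
    ds.GridFrameOffsetVector = [float(k * volume.spacing[2]) for k in range(nz)]
    ds.NumberOfFrames = nz
    ds.Rows, ds.Columns = ny, nx
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseGridScaling = scaling
    stored = np.round(np.transpose(volume.values, (2, 1, 0)) / scaling).astype(np.uint32)
    ds.PixelData = stored.tobytes()
    ds.save_as(file, enforce_file_format=True)
    return file


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT rasterisation
# ---------------------------------------------------------------------------

def rasterize_rtstruct(file: str | Path, grid: Volume) -> list[StructureMask]:
    """Rasterise the closed planar contours of an RTSTRUCT onto ``grid``.

    A voxel is included iff its centre lies inside the contour polygon on
    its slice (even-odd rule: overlapping contours of the same structure
    toggle membership).  Contours on slices not present in the grid are
    skipped with a warning.  Empty structures produce empty, flagged masks.
    """
    ds = pydicom.dcmread(Path(file))
    roi_names = {int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence}
    nx, ny, nz = grid.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    centres = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)

    masks = []
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        name = roi_names.get(int(roi_contour.ReferencedROINumber), "unknown")
        mask = np.zeros(grid.shape, dtype=bool)
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            idx = grid.physical_to_index(pts)
            k_float = idx[:, 2]
            k = int(np.round(k_float.mean()))
            if not (0 <= k < nz) or np.max(np.abs(k_float - k)) > 0.5 + 1e-9:
                warnings.warn(
                    f"contour of {name!r} lies on a slice not present in the grid; skipped",
                    stacklevel=2,
                )
                continue
            poly = MplPath(idx[:, :2])  # implicitly closed by contains_points
            inside = poly.contains_points(centres).reshape(nx, ny)
            mask[:, :, k] ^= inside  # even-odd rule across contours on a slice
        if not mask.any():
            warnings.warn(f"structure {name!r} rasterised to an empty mask", stacklevel=2)
        masks.append(StructureMask(name, mask, source="contour"))
    return masks


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar (canonical synthetic-fixture format)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_nifti(volume: Volume, path: str | Path, metadata: dict | None = None) -> Path:
    """Write a Volume as NIfTI with a JSON sidecar carrying frame_id etc."""
    import nibabel as nib

    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = volume.axes * volume.spacing[None, :]
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine)
    nib.save(img, path)
    sidecar = {"frame_id": volume.frame_id}
    if metadata:
        sidecar.update(metadata)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_nifti(path: str | Path) -> tuple[Volume, dict]:
    """Read a NIfTI volume (+ sidecar if present). Returns (volume, metadata)."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    affine = img.affine
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    axes = linear / spacing[None, :]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    vol = Volume(
        np.asarray(img.get_fdata(), dtype=float),
        affine[:3, 3],
        spacing,
        axes,
        frame_id=meta.get("frame_id", "default"),
    )
    return vol, meta
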