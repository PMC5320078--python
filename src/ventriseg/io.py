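"""Reading and writing CT volumes and masks.

NIfTI files are handled with nibabel; DICOM series with pydicom.  All readers
return HU-calibrated :class:`~ventriseg.volume.CTVolume` objects with arrays
indexed ``[x, y, z]``.
"""
from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .volume import BinaryVolume, CTVolume, check_same_geometry

__all__ = ["read_volume", "write_volume", "write_mask", "read_mask", "FormatError"]

#: relative tolerance on inter-slice gap uniformity for DICOM series
SLICE_GAP_RTOL = 0.01


class FormatError(ValueError):
    """Raised for malformed or unsupported input volumes."""


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume in HU from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    vol = CTVolume(data, tuple(float(z) for z in zooms), affine=np.asarray(img.affine))
    vol.warn_if_no_air()
    return vol


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"no readable DICOM slices in {path}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"directory mixes {len(uids)} DICOM series; expected one")

    # Sort slices by position along the slice normal.
    first = datasets[0]
    try:
        orient = np.array(first.ImageOrientationPatient, dtype=float)
        normal = np.cross(orient[:3], orient[3:])
        positions = [float(np.dot(np.array(ds.ImagePositionPatient, float), normal)) for ds in datasets]
    except AttributeError as exc:
        raise FormatError("DICOM slices lack position/orientation tags") from exc
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    if len(positions) > 1:
        gaps = np.diff(positions)
        if gaps.min() <= 0:
            raise FormatError("duplicate or non-increasing DICOM slice positions")
        if (gaps.max() - gaps.min()) > SLICE_GAP_RTOL * gaps.mean():
            raise FormatError("non-uniform DICOM slice spacing beyond tolerance")
        dz = float(np.mean(gaps))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
            raise FormatError("DICOM slice missing RescaleSlope/RescaleIntercept")
        hu = ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        # pixel_array is (rows, cols) = (y, x); transpose to (x, y)
        slices.append(hu.T)
    voxels = np.stack(slices, axis=2)

    dy, dx = (float(v) for v in first.PixelSpacing)  # PixelSpacing is (row, col)
    vol = CTVolume(voxels, (dx, dy, dz))
    vol.warn_if_no_air()
    return vol


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a CT volume as NIfTI with correct pixdim."""
    affine = vol.affine if vol.affine is not None else _default_affine(vol.spacing)
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryVolume, ref: CTVolume, path: str | os.PathLike) -> None:
    """Write a binary mask as a 0/1 NIfTI sharing ``ref``'s geometry."""
    check_same_geometry(mask, ref)
    affine = ref.affine if ref.affine is not None else _default_affine(ref.spacing)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    img.header.set_zooms(ref.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> BinaryVolume:
    """Read a mask NIfTI back into a :class:`BinaryVolume` (nonzero = true)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return BinaryVolume(data != 0, tuple(float(z) for z in zooms))
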