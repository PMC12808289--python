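"""Reading and writing volumes and label maps.

Single files (NIfTI ``.nii``/``.nii.gz``, NRRD ``.nrrd``) go through
SimpleITK, which normalises every format to LPS physical coordinates.
DICOM series directories are read with pydicom so slice ordering,
rescale-to-HU and spacing consistency can be validated explicitly.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pydicom
import SimpleITK as sitk

from .errors import FormatError, ValidationError
from .grids import LabelGrid, ScalarVolume, _from_sitk, _to_sitk

_FILE_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".nhdr", ".mha", ".mhd")

# Relative tolerance on slice-to-slice spacing consistency within a series.
_SPACING_RTOL = 1e-3


def _read_dicom_series(directory: Path) -> ScalarVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM slices in {directory}")

    first = slices[0]
    try:
        orient = np.asarray(first.ImageOrientationPatient, dtype=float)
    except AttributeError as e:
        raise FormatError(f"DICOM series lacks orientation information: {e}")
    row_dir, col_dir = orient[:3], orient[3:]
    normal = np.cross(row_dir, col_dir)

    for ds in slices[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, dtype=float), orient, atol=1e-4):
            raise ValidationError("DICOM series has inconsistent slice orientation")

    slices.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal)))
    positions = np.array(
        [np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal) for ds in slices]
    )
    if len(slices) > 1:
        dz = np.diff(positions)
        if np.any(dz <= 0):
            raise ValidationError("DICOM series has duplicate or unsorted slice positions")
        mean_dz = float(dz.mean())
        if np.any(np.abs(dz - mean_dz) > _SPACING_RTOL * mean_dz + 1e-6):
            raise ValidationError(
                f"inconsistent slice spacing in DICOM series: {np.round(dz, 4).tolist()}"
            )
        z_spacing = mean_dz
    else:
        z_spacing = float(getattr(first, "SliceThickness", 1.0) or 1.0)

    dr, dc = (float(x) for x in first.PixelSpacing)  # row spacing, column spacing
    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(ds.pixel_array.astype(float) * slope + intercept)
    stack = np.stack(planes, axis=-1)  # (rows, cols, slices)
    values = stack.transpose(1, 0, 2)  # (i=cols, j=rows, k=slices)

    direction = np.column_stack([row_dir, col_dir, normal])
    meta: Dict[str, object] = {}
    for key in ("KVP", "Exposure", "SliceThickness", "ConvolutionKernel", "Manufacturer"):
        if hasattr(first, key):
            meta[key] = str(getattr(first, key))
    return ScalarVolume(
        spacing=np.array([dc, dr, z_spacing]),
        origin=np.asarray(slices[0].ImagePositionPatient, dtype=float),
        direction=direction,
        values=values,
        meta=meta,
    )


def load_volume(path, format_hint: Optional[str] = None) -> ScalarVolume:
    """Load a CT volume in Hounsfield units.

    ``path`` may be a DICOM series directory or a NIfTI/NRRD file.  DICOM
    rescale slope/intercept is applied; a series whose slice positions are
    not evenly spaced raises ``ValidationError``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if path.is_dir() or format_hint == "dicom":
        return _read_dicom_series(path)
    try:
        img = sitk.ReadImage(str(path), sitk.sitkFloat64)
    except Exception as e:
        raise FormatError(f"cannot read volume {path}: {e}")
    vol = _from_sitk(img, ScalarVolume())
    vol.meta["source"] = str(path)
    return vol


def save_volume(vol: ScalarVolume, path) -> None:
    """Write a volume to NIfTI or NRRD (chosen by file suffix)."""
    _check_suffix(path)
    sitk.WriteImage(_to_sitk(vol), str(path))


def load_labels(path, legend: Optional[Dict[int, str]] = None) -> LabelGrid:
    """Load an integer label map; ``legend`` maps label id -> role.

    If no legend is given, every nonzero label found is assigned the role
    ``"metaphysis"`` for label 1 and ``"epiphysis_center"`` otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as e:
        raise FormatError(f"cannot read label map {path}: {e}")
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-6):
            raise ValidationError(f"label map {path} holds non-integer values")
        arr = rounded.astype(np.int32)
    if legend is None:
        present = sorted(set(np.unique(arr).tolist()) - {0})
        legend = {l: ("metaphysis" if l == 1 else "epiphysis_center") for l in present}
    return LabelGrid(
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=np.array(img.GetDirection()).reshape(3, 3),
        labels=arr.astype(np.int32),
        legend=legend,
    )


def save_labels(seg: LabelGrid, path) -> None:
    """Write a label map to NIfTI or NRRD (chosen by file suffix)."""
    _check_suffix(path)
    sitk.WriteImage(_to_sitk(seg), str(path))


def _check_suffix(path) -> None:
    name = str(path)
    if not any(name.endswith(s) for s in _FILE_SUFFIXES):
        raise FormatError(
            f"unsupported output format for {name!r}; use one of {_FILE_SUFFIXES}"
        )
    parent = Path(path).parent
    if parent and not parent.exists():
        os.makedirs(parent, exist_ok=True)
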