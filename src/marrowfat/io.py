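"""Reading and writing image stacks and result tables.

NIfTI is the canonical on-disk format.  In-plane voxel size goes into the
first two header zooms and the axial zoom is the center-to-center slice
distance (thickness + gap); thickness and gap are additionally round-
tripped through the header ``descrip`` field so no geometry is ever
guessed.  DICOM series are converted on read: ``SpacingBetweenSlices`` is
center-to-center per the DICOM standard, so gap = spacing − thickness.
All lengths on disk are mm (the convention of both formats) and cm in
memory.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .errors import FormatError
from .stack import ImageStack, MarrowMaskStack

__all__ = ["read_stack", "write_stack", "read_mask_stack", "write_mask_stack"]

_DESCRIP_RE = re.compile(rb"thk_mm=([0-9.eE+-]+);gap_mm=([0-9.eE+-]+)")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a NIfTI volume (float64, mm units)."""
    path = Path(path)
    arr = np.ascontiguousarray(stack.data.transpose(2, 1, 0))  # (x, y, z)
    ps_mm = stack.pixel_spacing * 10.0
    z_mm = stack.slice_extent * 10.0
    img = nib.Nifti1Image(arr, affine=np.diag([ps_mm, ps_mm, z_mm, 1.0]))
    img.header.set_zooms((ps_mm, ps_mm, z_mm))
    img.header["descrip"] = (
        f"thk_mm={stack.slice_thickness * 10.0:.6g};"
        f"gap_mm={stack.slice_gap * 10.0:.6g}".encode())
    nib.save(img, str(path))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a NIfTI volume or a DICOM series directory into an ImageStack."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def _read_nifti(path: Path) -> ImageStack:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {img.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel size in header")
    if not np.isclose(zooms[0], zooms[1]):
        raise FormatError(f"{path}: anisotropic in-plane spacing {zooms[:2]}")
    data = np.asarray(img.dataobj, dtype=float).transpose(2, 1, 0)

    m = _DESCRIP_RE.search(bytes(img.header["descrip"].tobytes()))
    if m:
        thickness_cm = float(m.group(1)) / 10.0
        gap_cm = float(m.group(2)) / 10.0
    else:
        warnings.warn(
            f"{path}: no thickness/gap annotation in header; assuming "
            "contiguous slices (gap = 0)", stacklevel=3)
        thickness_cm = float(zooms[2]) / 10.0
        gap_cm = 0.0
    return ImageStack(data, pixel_spacing=float(zooms[0]) / 10.0,
                      slice_thickness=thickness_cm, slice_gap=gap_cm)


def _read_dicom_series(dirpath: Path) -> ImageStack:
    files = sorted(p for p in dirpath.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no .dcm files in {dirpath}")
    datasets = [pydicom.dcmread(str(p)) for p in files]
    try:
        datasets.sort(key=lambda ds: int(ds.InstanceNumber))
    except AttributeError as exc:
        raise FormatError(f"{dirpath}: missing InstanceNumber") from exc
    numbers = [int(ds.InstanceNumber) for ds in datasets]
    expected = list(range(numbers[0], numbers[0] + len(numbers)))
    if numbers != expected:
        gaps = sorted(set(expected) - set(numbers)) or numbers
        raise FormatError(
            f"{dirpath}: DICOM series has non-consecutive instance numbers; "
            f"missing/unexpected instances near {gaps}")

    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) != 1:
        raise FormatError(f"{dirpath}: inconsistent slice dimensions {shapes}")
    ds0 = datasets[0]
    try:
        ps = [float(v) for v in ds0.PixelSpacing]
        thickness_mm = float(ds0.SliceThickness)
    except AttributeError as exc:
        raise FormatError(
            f"{dirpath}: unreadable header geometry ({exc})") from exc
    if not np.isclose(ps[0], ps[1]):
        raise FormatError(f"{dirpath}: anisotropic in-plane spacing {ps}")
    if "SpacingBetweenSlices" in ds0:
        gap_mm = float(ds0.SpacingBetweenSlices) - thickness_mm
        if gap_mm < 0:
            warnings.warn(f"{dirpath}: overlapping slices; clamping gap to 0",
                          stacklevel=3)
            gap_mm = 0.0
    else:
        warnings.warn(f"{dirpath}: SpacingBetweenSlices absent; assuming "
                      "gap = 0", stacklevel=3)
        gap_mm = 0.0
    data = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    return ImageStack(data, pixel_spacing=ps[0] / 10.0,
                      slice_thickness=thickness_mm / 10.0,
                      slice_gap=gap_mm / 10.0)


def write_mask_stack(masks: MarrowMaskStack, path: str | Path,
                     slice_thickness: float = 0.5,
                     slice_gap: float = 0.5) -> Path:
    """Write binary masks as a uint8 NIfTI label volume."""
    path = Path(path)
    arr = np.ascontiguousarray(masks.masks.astype(np.uint8).transpose(2, 1, 0))
    ps_mm = masks.pixel_spacing * 10.0
    z_mm = (slice_thickness + slice_gap) * 10.0
    img = nib.Nifti1Image(arr, affine=np.diag([ps_mm, ps_mm, z_mm, 1.0]))
    img.header.set_zooms((ps_mm, ps_mm, z_mm))
    nib.save(img, str(path))
    return path


def read_mask_stack(path: str | Path) -> MarrowMaskStack:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.asarray(img.dataobj).transpose(2, 1, 0) > 0
    return MarrowMaskStack(data, pixel_spacing=float(zooms[0]) / 10.0)
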