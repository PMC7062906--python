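"""Core in-memory containers: axial image stacks and binary marrow masks.

All geometry is carried in centimetres: ``pixel_spacing`` is the in-plane
size of a square voxel, ``slice_thickness`` the axial extent of each slice
and ``slice_gap`` the unimaged gap between consecutive slices.  With
contiguous coverage the axial extent attributed to one slice is
``slice_thickness + slice_gap``, which is how per-slice areas become
volumes everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class ImageStack:
    """Ordered axial slices with acquisition geometry.

    Parameters
    ----------
    data : ndarray, shape (n_slices, ny, nx)
        Non-negative image intensities, ordered along the bone axis.
    pixel_spacing : float
        In-plane voxel size in cm/pixel (square pixels).
    slice_thickness : float
        Slice thickness in cm.
    slice_gap : float, optional
        Gap between consecutive slices in cm (default 0).
    """

    data: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    slice_gap: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValidationError(
                f"stack data must be 3-D (n_slices, ny, nx); got shape {arr.shape}"
            )
        if self.pixel_spacing <= 0:
            raise ValidationError("pixel_spacing must be > 0")
        if self.slice_thickness <= 0:
            raise ValidationError("slice_thickness must be > 0")
        if self.slice_gap < 0:
            raise ValidationError("slice_gap must be >= 0")
        object.__setattr__(self, "data", arr)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def slices(self) -> list[np.ndarray]:
        """The slices as a list of 2-D arrays (views, not copies)."""
        return list(self.data)

    @property
    def slice_extent(self) -> float:
        """Axial extent attributed to one slice: thickness + gap, in cm."""
        return self.slice_thickness + self.slice_gap

    def geometry_matches(self, other: "ImageStack") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.pixel_spacing, other.pixel_spacing)
            and np.isclose(self.slice_thickness, other.slice_thickness)
            and np.isclose(self.slice_gap, other.slice_gap)
        )


@dataclass(frozen=True)
class MarrowMaskStack:
    """Per-slice binary marrow masks aligned with an :class:`ImageStack`.

    ``marrow_area`` is derived: voxel count per slice times
    ``pixel_spacing**2`` (cm²).
    """

    masks: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.masks)
        if arr.ndim != 3:
            raise ValidationError(
                f"masks must be 3-D (n_slices, ny, nx); got shape {arr.shape}"
            )
        if self.pixel_spacing <= 0:
            raise ValidationError("pixel_spacing must be > 0")
        object.__setattr__(self, "masks", arr.astype(bool))

    @property
    def n_slices(self) -> int:
        return self.masks.shape[0]

    @property
    def marrow_area(self) -> np.ndarray:
        """Marrow area per slice in cm²."""
        return self.masks.sum(axis=(1, 2)) * self.pixel_spacing**2
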