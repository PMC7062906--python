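"""Marrow fat quantification from the T1-weighted channel alone.

A fat-intensity threshold is calibrated per slice against the
subcutaneous-fat reference region: among the candidate thresholds, pick
the one whose above-threshold area inside an annulus bounding the
subcutaneous ring best matches the segmented subcutaneous-fat area
(lowest threshold on ties).  Marrow voxels at or above the calibrated
threshold count as fat; per-slice fat fraction is the fat-area share of
the marrow area, and volumes accumulate with slice thickness + gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError
from .quant_ideal import _normalize_range
from .results import MarrowFatResult
from .stack import ImageStack, MarrowMaskStack

__all__ = [
    "ThresholdCalibration",
    "calibrate_threshold",
    "calibrate_stack",
    "quantify_t1",
    "area_to_volume",
    "T1MarrowFat",
]


@dataclass(frozen=True)
class ThresholdCalibration:
    """Calibrated intensity cutoff for one slice.

    ``reference_area`` is the segmented subcutaneous-fat area (cm²);
    ``achieved_area`` the above-threshold area within the calibration
    support at the chosen threshold.
    """

    threshold: float
    reference_area: float
    achieved_area: float
    support_area: float    # cm² of the annulus searched


def _support_annulus(shape: tuple[int, int], subcut_mask: np.ndarray,
                     pad_px: float = 1.0) -> np.ndarray:
    """Annulus bounding the subcutaneous ring (plus a small pad), centred
    on the ring's centroid.  Restricting the search here keeps deep-muscle
    voxels from satisfying the area match."""
    ys, xs = np.nonzero(subcut_mask)
    cy, cx = ys.mean(), xs.mean()
    yy, xx = np.indices(shape)
    r = np.hypot(yy - cy, xx - cx)
    r_vox = np.hypot(ys - cy, xs - cx)
    return (r >= r_vox.min() - pad_px) & (r <= r_vox.max() + pad_px)


def calibrate_threshold(
    t1_slice: np.ndarray,
    subcut_mask: np.ndarray,
    pixel_spacing: float,
    search_grid: np.ndarray | None = None,
    pad_px: float = 1.0,
) -> ThresholdCalibration:
    """Find the threshold whose above-threshold area matches the reference.

    The search grid defaults to every distinct intensity inside the
    calibration annulus (exhaustive, so the optimum is found); ties are
    broken toward the lowest threshold.  Voxels exactly at the threshold
    count as fat (``>=``).
    """
    sl = np.asarray(t1_slice, dtype=float)
    mask = np.asarray(subcut_mask, dtype=bool)
    if sl.shape != mask.shape:
        raise ValidationError("slice and subcutaneous mask shapes differ")
    if not mask.any():
        raise CalibrationError("empty subcutaneous-fat reference mask")

    support = _support_annulus(sl.shape, mask, pad_px=pad_px)
    vals = np.sort(sl[support])
    grid = np.unique(vals) if search_grid is None else np.sort(
        np.asarray(search_grid, dtype=float))
    ps2 = pixel_spacing**2
    ref_area = float(mask.sum()) * ps2
    # area(>= g) for each candidate via one sorted pass
    counts = vals.size - np.searchsorted(vals, grid, side="left")
    achieved = counts * ps2
    err = np.abs(achieved - ref_area)
    best = int(np.argmin(err))       # first minimum = lowest threshold
    return ThresholdCalibration(
        threshold=float(grid[best]),
        reference_area=ref_area,
        achieved_area=float(achieved[best]),
        support_area=float(support.sum()) * ps2,
    )


def calibrate_stack(
    t1: ImageStack,
    subcut: MarrowMaskStack,
    slice_range: range | tuple[int, int] | None = None,
    per_slice: bool = True,
    pad_px: float = 1.0,
) -> dict[int, ThresholdCalibration]:
    """Calibrate thresholds for every slice in range.

    Per-image calibration is the default (coil shading varies along the
    bone); with ``per_slice=False`` a single pooled threshold is computed
    from the middle slice of the range and reused everywhere.
    """
    rng_ = _normalize_range(slice_range, t1.n_slices)
    if per_slice:
        return {
            i: calibrate_threshold(t1.data[i], subcut.masks[i],
                                   t1.pixel_spacing, pad_px=pad_px)
            for i in rng_
        }
    mid = rng_[len(rng_) // 2]
    cal = calibrate_threshold(t1.data[mid], subcut.masks[mid],
                              t1.pixel_spacing, pad_px=pad_px)
    return {i: cal for i in rng_}


def quantify_t1(
    t1: ImageStack,
    masks: MarrowMaskStack,
    calibrations: dict[int, ThresholdCalibration],
    slice_range: range | tuple[int, int] | None = None,
) -> MarrowFatResult:
    """Threshold-count marrow fat on the T1 channel.

    Per slice: fat area = (marrow voxels >= threshold) × pixel area, fat
    fraction = 100 × fat area / marrow area.  Aggregates as in the
    fat/water procedure: BMFV sums fat areas times the axial extent, BMFF
    is the unweighted mean of per-slice fractions.
    """
    if masks.masks.shape != t1.data.shape:
        raise ValidationError("marrow masks are not aligned with the T1 stack")
    rng_ = _normalize_range(slice_range, t1.n_slices)
    missing = [i for i in rng_ if i not in calibrations]
    if missing:
        raise ValidationError(f"no threshold calibration for slices {missing}")

    ps2 = masks.pixel_spacing**2
    rows, excluded = [], []
    for i in rng_:
        m = masks.masks[i]
        count = int(m.sum())
        if count == 0:
            warnings.warn(f"slice {i}: zero marrow area, excluded", stacklevel=2)
            excluded.append(i)
            continue
        thr = calibrations[i].threshold
        fat_count = int((t1.data[i][m] >= thr).sum())
        marrow_area = count * ps2
        fat_area = fat_count * ps2
        rows.append((i, thr, marrow_area, fat_area,
                     100.0 * fat_area / marrow_area))
    if not rows:
        raise ValidationError("no analyzable slices in range")

    df = pd.DataFrame(rows, columns=["slice", "threshold_au",
                                     "marrow_area_cm2", "fat_area_cm2",
                                     "ff_pct"])
    extent = t1.slice_extent
    return MarrowFatResult(
        method="T1",
        per_slice=df[["slice", "threshold_au", "ff_pct",
                      "marrow_area_cm2", "fat_area_cm2"]],
        bmff=float(df["ff_pct"].mean()),
        bmfv=area_to_volume(df["fat_area_cm2"].to_numpy(),
                            t1.slice_thickness, t1.slice_gap),
        slice_range=(rng_.start, rng_.stop),
        slice_extent_cm=extent,
        excluded_slices=tuple(excluded),
    )


def area_to_volume(areas, thickness: float, gap: float = 0.0) -> float:
    """Volume (cm³) of per-slice areas (cm²): Σ area × (thickness + gap)."""
    a = np.asarray(areas, dtype=float)
    if a.size and (a < 0).any():
        raise ValidationError("areas must be >= 0")
    if thickness <= 0:
        raise ValidationError("thickness must be > 0")
    if gap < 0:
        raise ValidationError("gap must be >= 0")
    return float(a.sum() * (thickness + gap))


class T1MarrowFat:
    """Model-style wrapper: threshold-based T1 quantification.

    Calibrates per-slice thresholds from the subcutaneous-fat reference if
    explicit calibrations are not supplied, then counts marrow fat voxels;
    :meth:`fit` returns the :class:`~marrowfat.results.MarrowFatResult`.
    """

    def __init__(self, t1: ImageStack, masks: MarrowMaskStack,
                 subcut: MarrowMaskStack | None = None,
                 calibrations: dict[int, ThresholdCalibration] | None = None,
                 slice_range=None, per_slice_calibration: bool = True) -> None:
        if calibrations is None and subcut is None:
            raise ValidationError(
                "supply either calibrations or the subcutaneous-fat masks")
        self.t1 = t1
        self.masks = masks
        self.subcut = subcut
        self.calibrations = calibrations
        self.slice_range = slice_range
        self.per_slice_calibration = per_slice_calibration

    def fit(self) -> MarrowFatResult:
        cal = self.calibrations
        if cal is None:
            cal = calibrate_stack(self.t1, self.subcut, self.slice_range,
                                  per_slice=self.per_slice_calibration)
        return quantify_t1(self.t1, self.masks, cal, self.slice_range)
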