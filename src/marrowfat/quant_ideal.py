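"""Marrow fat quantification from fat/water image pairs.

The fat fraction of a region is the signal-intensity ratio

    FF (%) = 100 · SI_fat / (SI_fat + SI_water)

where SI_fat and SI_water are the mean fat- and water-channel signals over
the marrow voxels of a slice.  Per-slice fat area is FF × marrow area, and
fat volume accumulates fat areas over slices with an axial extent of
slice thickness + inter-slice gap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .errors import AlignmentError, UndefinedRatioError, ValidationError
from .results import MarrowFatResult
from .stack import ImageStack, MarrowMaskStack

__all__ = [
    "fat_fraction",
    "transfer_mask",
    "quantify_ideal",
    "IdealMarrowFat",
    "SliceFatWaterMeasurement",
]

log = logging.getLogger("marrowfat.quant_ideal")


@dataclass(frozen=True)
class SliceFatWaterMeasurement:
    """Per-slice fat/water readout over the marrow mask."""

    slice_index: int
    si_fat: float
    si_water: float
    marrow_area: float     # cm²
    ff: float              # percent
    fat_area: float        # cm²


def fat_fraction(si_fat, si_water):
    """Fat fraction in percent from fat and water signal intensities.

    Accepts scalars or arrays; both inputs must be >= 0 and may not both be
    zero (elementwise).  Scale-invariant and strictly increasing in
    ``si_fat`` for fixed ``si_water``.
    """
    f = np.asarray(si_fat, dtype=float)
    w = np.asarray(si_water, dtype=float)
    if (f < 0).any() or (w < 0).any():
        raise ValidationError("signal intensities must be >= 0")
    total = f + w
    if (total == 0).any():
        raise UndefinedRatioError("fat and water signals are both zero")
    out = 100.0 * f / total
    return float(out) if out.ndim == 0 else out


def transfer_mask(
    masks: MarrowMaskStack,
    target: ImageStack,
    reference: ImageStack | None = None,
    register: bool = False,
) -> MarrowMaskStack:
    """Express a marrow mask on a target channel's grid.

    With co-registered grids (the phantom case) this is the identity.  If
    ``register`` is true, a rigid integer-pixel in-plane translation is
    estimated by maximizing the cross-correlation between the mean
    ``reference`` slice (the channel the mask was drawn on, e.g. T1) and
    the mean ``target`` slice, and the mask is shifted accordingly.
    """
    if masks.masks.shape != target.data.shape:
        raise AlignmentError(
            f"mask grid {masks.masks.shape} does not match target grid "
            f"{target.data.shape}; enable registration or resample")
    if not register:
        return masks
    if reference is None:
        raise ValidationError("registration requires the reference stack")
    shift, _, _ = phase_cross_correlation(
        target.data.mean(axis=0), reference.data.mean(axis=0),
        upsample_factor=1)
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    log.info("transfer_mask: estimated in-plane shift (dy=%d, dx=%d)", dy, dx)
    shifted = np.roll(masks.masks, (dy, dx), axis=(1, 2))
    return MarrowMaskStack(shifted, masks.pixel_spacing)


def quantify_ideal(
    fat: ImageStack,
    water: ImageStack,
    masks: MarrowMaskStack,
    slice_range: range | tuple[int, int] | None = None,
    aggregation: str = "slice-mean",
) -> MarrowFatResult:
    """Quantify marrow fat from a fat/water pair over the masked region.

    Per slice: mean signal over marrow voxels on each channel, fat fraction
    by the signal-intensity ratio, fat area = FF × marrow area.  Aggregate
    fat volume sums fat areas times the axial extent; aggregate fat
    fraction is the unweighted mean of per-slice fractions (or the
    area-weighted mean with ``aggregation='area-weighted'``).
    """
    if fat.data.shape != water.data.shape:
        raise ValidationError("fat and water stacks must share one grid")
    if masks.masks.shape != fat.data.shape:
        raise AlignmentError("marrow masks are not aligned with the channels")
    if aggregation not in ("slice-mean", "area-weighted"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    rng_ = _normalize_range(slice_range, fat.n_slices)

    rows, excluded = [], []
    ps2 = masks.pixel_spacing**2
    for i in rng_:
        m = masks.masks[i]
        count = int(m.sum())
        if count == 0:
            warnings.warn(f"slice {i}: empty marrow mask, excluded", stacklevel=2)
            excluded.append(i)
            continue
        si_f = float(fat.data[i][m].mean())
        si_w = float(water.data[i][m].mean())
        ff = fat_fraction(si_f, si_w)
        area = count * ps2
        rows.append(SliceFatWaterMeasurement(i, si_f, si_w, area, ff,
                                             (ff / 100.0) * area))
    if not rows:
        raise ValidationError("no analyzable slices in range")

    df = pd.DataFrame(
        {
            "slice": [r.slice_index for r in rows],
            "si_fat_au": [r.si_fat for r in rows],
            "si_water_au": [r.si_water for r in rows],
            "ff_pct": [r.ff for r in rows],
            "marrow_area_cm2": [r.marrow_area for r in rows],
            "fat_area_cm2": [r.fat_area for r in rows],
        }
    )
    extent = fat.slice_extent
    bmfv = float(df["fat_area_cm2"].sum() * extent)
    if aggregation == "slice-mean":
        bmff = float(df["ff_pct"].mean())
    else:
        bmff = float(np.average(df["ff_pct"], weights=df["marrow_area_cm2"]))
    return MarrowFatResult(
        method="IDEAL",
        per_slice=df,
        bmff=bmff,
        bmfv=bmfv,
        slice_range=(rng_.start, rng_.stop),
        slice_extent_cm=extent,
        aggregation=aggregation,
        excluded_slices=tuple(excluded),
    )


def _normalize_range(slice_range, n_slices: int) -> range:
    if slice_range is None:
        return range(n_slices)
    if isinstance(slice_range, range):
        r = slice_range
    else:
        r = range(int(slice_range[0]), int(slice_range[1]))
    if len(r) == 0:
        raise ValidationError("slice range is empty")
    if r.start < 0 or r.stop > n_slices:
        raise ValidationError(
            f"slice range {r} outside stack of {n_slices} slices")
    return r


class IdealMarrowFat:
    """Model-style wrapper: fat/water quantification over a marrow mask.

    Parameters mirror :func:`quantify_ideal`; :meth:`fit` runs the
    quantification and returns the :class:`~marrowfat.results.MarrowFatResult`.
    """

    def __init__(self, fat: ImageStack, water: ImageStack,
                 masks: MarrowMaskStack,
                 slice_range=None, aggregation: str = "slice-mean") -> None:
        self.fat = fat
        self.water = water
        self.masks = masks
        self.slice_range = slice_range
        self.aggregation = aggregation

    def fit(self) -> MarrowFatResult:
        return quantify_ideal(self.fat, self.water, self.masks,
                              slice_range=self.slice_range,
                              aggregation=self.aggregation)
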