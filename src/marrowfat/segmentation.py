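"""Marrow and subcutaneous-fat segmentation from T1-weighted slices.

The procedure mirrors the classic intensity pipeline for long-bone
cross-sections: median-filter each slice, soft-cluster the intensities
with fuzzy c-means, identify the cortical-bone shell as the low-intensity
ring and take its hole-filled interior as bone marrow, and take the
largest connected component of the brightest (fat) cluster as the
subcutaneous-fat reference ring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateInputError, SegmentationError, ValidationError
from .stack import ImageStack, MarrowMaskStack

__all__ = [
    "ClusterResult",
    "SegmentationResult",
    "median_filter",
    "fuzzy_cmeans",
    "extract_masks",
    "segment_stack",
    "select_middle_third",
]


def median_filter(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median-filter a 2-D slice with an odd square kernel (reflect edges)."""
    if not isinstance(kernel, (int, np.integer)) or kernel < 1 or kernel % 2 == 0:
        raise ValidationError(f"kernel must be an odd integer >= 1, got {kernel}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("median_filter expects a 2-D slice")
    return ndimage.median_filter(img, size=kernel, mode="reflect")


@dataclass(frozen=True)
class ClusterResult:
    """Fuzzy c-means output on 1-D intensities.

    ``centroids`` are sorted ascending; ``memberships`` has shape
    (n_values, k), rows summing to 1; ``objective`` is the value of the
    weighted within-cluster sum of squares at each iteration.
    """

    centroids: np.ndarray
    memberships: np.ndarray
    n_iter: int
    objective: np.ndarray

    def hard_labels(self) -> np.ndarray:
        """Cluster index of maximal membership per value."""
        return np.argmax(self.memberships, axis=1)


def fuzzy_cmeans(
    values: np.ndarray,
    k: int = 4,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
    init: str = "quantile",
) -> ClusterResult:
    """Fuzzy c-means on 1-D intensities.

    Standard fixed point: memberships u_ij ∝ (1/d_ij²)^{1/(m−1)} normalised
    per value, centroids are u^m-weighted means; iterate until the largest
    centroid movement is below ``tol``.  Initialisation is deterministic
    (evenly spaced quantiles of the distinct intensities) unless
    ``init='random'``, in which case ``seed`` controls the draw.
    """
    v = np.asarray(values, dtype=float).ravel()
    if k < 2:
        raise ValidationError("k must be >= 2")
    if m <= 1:
        raise ValidationError("fuzziness m must be > 1")
    uniq = np.unique(v)
    if uniq.size < k:
        raise DegenerateInputError(
            f"need at least {k} distinct values, got {uniq.size}")

    if init == "random":
        rng = np.random.default_rng(seed)
        c = np.sort(rng.choice(uniq, size=k, replace=False))
    else:
        # quantiles of the *distinct* intensities, so heavy background
        # multiplicity cannot collapse two initial centroids onto one value
        c = np.quantile(uniq, (np.arange(k) + 0.5) / k)

    exponent = 1.0 / (m - 1.0)
    objective = []
    u = None
    for it in range(1, max_iter + 1):
        d2 = (v[:, None] - c[None, :]) ** 2
        zero = d2 == 0.0
        with np.errstate(divide="ignore"):
            w = d2 ** (-exponent)
        u = np.empty_like(d2)
        rows_zero = zero.any(axis=1)
        np.divide(w, w.sum(axis=1, keepdims=True), out=u,
                  where=~rows_zero[:, None])
        if rows_zero.any():
            u[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(
                axis=1, keepdims=True)
        um = u ** m
        objective.append(float((um * d2).sum()))
        c_new = (um * v[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = float(np.max(np.abs(c_new - c)))
        c = c_new
        if shift < tol:
            break

    order = np.argsort(c)
    return ClusterResult(
        centroids=c[order],
        memberships=u[:, order],
        n_iter=it,
        objective=np.asarray(objective),
    )


def _components_not_touching_border(mask: np.ndarray) -> list[np.ndarray]:
    lab = measure.label(mask, connectivity=2)
    comps = []
    for idx in range(1, lab.max() + 1):
        comp = lab == idx
        if comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any():
            continue
        comps.append(comp)
    return comps


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(lab.ravel())[1:]
    return lab == int(np.argmax(sizes)) + 1


def extract_masks(
    t1_slice: np.ndarray,
    cluster: ClusterResult,
    slice_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Derive (marrow mask, subcutaneous-fat mask) from one clustered slice.

    The clustering must have been run on the (median-filtered) slice whose
    shape is ``t1_slice.shape``.  Marrow is the hole-filled interior of the
    low-intensity cortical contour, excluding the contour itself;
    subcutaneous fat is the largest connected component of the brightest
    cluster.  The two masks are disjoint by construction.
    """
    shape = np.asarray(t1_slice).shape
    if cluster.memberships.shape[0] != shape[0] * shape[1]:
        raise ValidationError("cluster result does not match slice shape")
    hard = cluster.hard_labels().reshape(shape)
    k = cluster.centroids.size

    low = hard == 0            # darkest cluster: cortical bone + background
    where = f" (slice {slice_index})" if slice_index is not None else ""
    rings = _components_not_touching_border(low)
    if not rings:
        raise SegmentationError(f"no closed cortical contour found{where}")
    # the cortical shell: interior-holding component closest to image center
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    best, best_dist = None, np.inf
    for comp in rings:
        filled = ndimage.binary_fill_holes(comp)
        if filled.sum() == comp.sum():
            continue               # no enclosed interior: not a shell
        cy, cx = ndimage.center_of_mass(comp)
        dist = (cy - center[0]) ** 2 + (cx - center[1]) ** 2
        if dist < best_dist:
            best, best_dist = comp, dist
    if best is None:
        raise SegmentationError(f"no closed cortical contour found{where}")
    interior = ndimage.binary_fill_holes(best) & ~best
    marrow = _largest_component(interior)
    marrow = ndimage.binary_fill_holes(marrow)

    fat = hard == (k - 1)          # brightest cluster
    subcut = _largest_component(fat)
    subcut &= ~marrow              # geometric exclusion safeguard
    return marrow, subcut


@dataclass(frozen=True)
class SegmentationResult:
    """Per-stack segmentation: marrow masks, subcutaneous-fat masks and the
    per-slice cluster centroids actually used."""

    marrow: MarrowMaskStack
    subcut: MarrowMaskStack
    centroids: list[np.ndarray]


def segment_stack(
    t1: ImageStack,
    k: int = 4,
    kernel: int = 3,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> SegmentationResult:
    """Median-filter, cluster and mask every slice of a T1 stack."""
    marrow_masks = np.zeros(t1.data.shape, dtype=bool)
    subcut_masks = np.zeros(t1.data.shape, dtype=bool)
    centroids = []
    for i, sl in enumerate(t1.data):
        filt = median_filter(sl, kernel=kernel)
        cluster = fuzzy_cmeans(filt.ravel(), k=k, m=m, tol=tol,
                               max_iter=max_iter)
        marrow_masks[i], subcut_masks[i] = extract_masks(filt, cluster,
                                                         slice_index=i)
        centroids.append(cluster.centroids)
    return SegmentationResult(
        marrow=MarrowMaskStack(marrow_masks, t1.pixel_spacing),
        subcut=MarrowMaskStack(subcut_masks, t1.pixel_spacing),
        centroids=centroids,
    )


def select_middle_third(
    stack: ImageStack,
    bone_extent: tuple[int, int] | None = None,
) -> range:
    """Slice indices of the middle third of the bone extent.

    ``bone_extent`` is a 0-based half-open (start, stop) range of slices
    spanning the bone; by default the whole stack models the tibia.
    Returns ``range(start + N//3, start + 2N//3)`` for an N-slice extent.
    """
    start, stop = bone_extent if bone_extent is not None else (0, stack.n_slices)
    if not (0 <= start < stop <= stack.n_slices):
        raise ValidationError(
            f"bone extent ({start}, {stop}) outside stack of {stack.n_slices} slices")
    n = stop - start
    if n < 3:
        raise ValidationError("bone extent must span at least 3 slices")
    return range(start + n // 3, start + (2 * n) // 3)
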