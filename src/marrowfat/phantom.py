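"""Synthetic midtibia phantoms with known marrow fat fraction.

A phantom emulates an axial MRI acquisition of the lower leg at the
midtibia: concentric tissue compartments (central marrow, cortical-bone
shell, muscle, subcutaneous-fat ring, thin skin layer, background) on a
square voxel grid, imaged on three co-registered channels — a T1-weighted
channel and a fat/water channel pair such as a chemical-shift (IDEAL-type)
decomposition would produce.  The generator returns the three stacks plus
a :class:`PhantomGroundTruth` carrying the per-voxel tissue labels and the
true fat-fraction map, which downstream recovery tests treat as the
oracle.

Two marrow microstructures are supported:

* ``speckled=False`` (homogeneous): every marrow voxel mixes the fat and
  red-marrow signals in proportion ``marrow_fat_fraction``.  On the
  fat/water pair this makes ``fat/(fat+water)`` equal the true fraction
  exactly (before noise); on the T1 channel all marrow voxels share one
  intensity, so a single-threshold count is degenerate by construction.
* ``speckled=True``: on the T1 channel each marrow voxel is drawn
  Bernoulli(FF) as pure marrow fat or pure red marrow, mimicking the
  partial-volume speckle a threshold-based count actually sees.  The
  fat/water channels keep the homogeneous mixture — a chemical-shift
  decomposition measures the mean fat content of the compartment either
  way, and zero-signal voxels would otherwise acquire a Rayleigh noise
  floor that no real decomposed image has.  The realized per-slice
  speckle fraction is recorded alongside the nominal fraction.

Noise is Rician by default — independent Gaussian noise on two quadrature
components followed by a magnitude operation — which is the distribution
of magnitude MR images; a plain (clipped) Gaussian model is available for
high-SNR checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .errors import GeometryError, ValidationError
from .stack import ImageStack

__all__ = [
    "Tissue",
    "ChannelSignals",
    "TissueRadii",
    "PhantomConfig",
    "PhantomGroundTruth",
    "generate_phantom",
    "ground_truth_summary",
    "sample_cohort_configs",
    "DEFAULT_SIGNALS",
]


class Tissue(IntEnum):
    """Label codes for the concentric phantom compartments."""

    BACKGROUND = 0
    SKIN = 1
    SUBCUT_FAT = 2
    MUSCLE = 3
    CORTICAL_BONE = 4
    MARROW = 5


@dataclass(frozen=True)
class ChannelSignals:
    """Mean signal of one tissue on each channel (arbitrary units, >= 0)."""

    t1: float
    fat: float
    water: float

    def __post_init__(self) -> None:
        if min(self.t1, self.fat, self.water) < 0:
            raise ValidationError("tissue signals must be >= 0")


@dataclass(frozen=True)
class TissueRadii:
    """Outer radii of the concentric compartments, in cm, strictly increasing."""

    marrow: float = 0.7
    cortical_bone: float = 1.1
    muscle: float = 2.6
    subcutaneous_fat: float = 3.4
    skin: float = 3.7

    def __post_init__(self) -> None:
        seq = (self.marrow, self.cortical_bone, self.muscle,
               self.subcutaneous_fat, self.skin)
        if any(r <= 0 for r in seq):
            raise GeometryError("all radii must be > 0")
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise GeometryError(f"radii must be strictly increasing, got {seq}")


# Default per-tissue channel means.  The study protocol publishes no signal
# values, so these are free parameters chosen for T1-weighted contrast
# (fat brightest, then muscle, then water-dominant red marrow, cortical bone
# and background darkest) and a fat/water pair in which fat-rich tissue
# dominates the fat channel and lean tissue the water channel.
DEFAULT_SIGNALS: dict[str, ChannelSignals] = {
    "background": ChannelSignals(10.0, 2.0, 2.0),
    "skin": ChannelSignals(80.0, 30.0, 120.0),
    "subcutaneous_fat": ChannelSignals(200.0, 200.0, 10.0),
    "muscle": ChannelSignals(120.0, 15.0, 160.0),
    "cortical_bone": ChannelSignals(20.0, 5.0, 5.0),
    # marrow is a mixture of the two signals below, weighted by the
    # fat fraction; their fat+water totals are equal (200) so that the
    # signal-intensity ratio recovers the fraction exactly.
    "red_marrow": ChannelSignals(70.0, 0.0, 200.0),
    "marrow_fat": ChannelSignals(200.0, 200.0, 0.0),
}

_TISSUE_KEYS = ("background", "skin", "subcutaneous_fat", "muscle",
                "cortical_bone")


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one synthetic acquisition.

    Defaults reproduce the study conditions: 0.5 cm thick axial slices with
    a 0.5 cm inter-slice gap, stacks of 24–34 slices (24 by default), and a
    marrow fat fraction around 0.8 as observed in the pediatric tibia.
    ``noise_sd`` defaults to 5% of the subcutaneous-fat signal.
    """

    n_slices: int = 24
    grid_size: int = 160
    pixel_spacing: float = 0.05        # cm / pixel
    slice_thickness: float = 0.5       # cm
    slice_gap: float = 0.5             # cm
    radii: TissueRadii = field(default_factory=TissueRadii)
    tissue_signals: dict[str, ChannelSignals] = field(
        default_factory=lambda: dict(DEFAULT_SIGNALS))
    marrow_fat_fraction: float = 0.8
    noise_sd: float = 10.0
    noise_model: str = "rician"        # "rician" | "gaussian"
    speckled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise ValidationError("n_slices must be >= 3")
        if self.grid_size < 8:
            raise ValidationError("grid_size must be >= 8")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValidationError("pixel_spacing and slice_thickness must be > 0")
        if self.slice_gap < 0:
            raise ValidationError("slice_gap must be >= 0")
        if not 0.0 <= self.marrow_fat_fraction <= 1.0:
            raise ValidationError("marrow_fat_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        missing = ({*_TISSUE_KEYS, "red_marrow", "marrow_fat"}
                   - set(self.tissue_signals))
        if missing:
            raise ValidationError(f"tissue_signals missing entries: {sorted(missing)}")
        half_fov = self.grid_size * self.pixel_spacing / 2.0
        if self.radii.skin >= half_fov:
            warnings.warn(
                "outer skin radius exceeds the field of view; the phantom "
                "will be clipped at the image border", stacklevel=2)


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Voxel-level oracle for recovery tests.

    ``ff_map`` holds the true per-voxel fat fraction in [0, 1] (zero outside
    marrow); ``true_marrow_area`` is the pixel-counted marrow area per slice
    in cm²; ``true_bmff`` (percent) is the mean over slices of the per-slice
    marrow fat fraction; ``true_bmfv`` (cm³) sums per-slice marrow fat area
    times the axial extent (thickness + gap).
    """

    labels: np.ndarray                 # (n_slices, ny, nx) uint8, Tissue codes
    ff_map: np.ndarray                 # (n_slices, ny, nx) float in [0, 1]
    true_marrow_area: np.ndarray       # (n_slices,) cm²
    true_slice_ff: np.ndarray          # (n_slices,) in [0, 1]
    true_bmff: float                   # percent
    true_bmfv: float                   # cm³
    speckle_fraction: np.ndarray | None = None   # realized T1 speckle per slice

    def range_truth(self, slice_range, slice_extent: float) -> tuple[float, float]:
        """(true BMFF %, true BMFV cm³) restricted to analyzed slices."""
        idx = np.asarray(list(slice_range))
        ff = self.true_slice_ff[idx]
        area = self.true_marrow_area[idx]
        return 100.0 * float(ff.mean()), float((area * ff).sum() * slice_extent)


def _label_map(config: PhantomConfig) -> np.ndarray:
    """2-D tissue label map: a voxel belongs to the innermost compartment
    whose outer radius covers its *center* (no anti-aliasing), so ground
    truth areas are exact pixel counts."""
    n = config.grid_size
    center = (n - 1) / 2.0
    coord = (np.arange(n) - center) * config.pixel_spacing
    r = np.hypot(coord[:, None], coord[None, :])
    rad = config.radii
    labels = np.full((n, n), Tissue.BACKGROUND, dtype=np.uint8)
    labels[r < rad.skin] = Tissue.SKIN
    labels[r < rad.subcutaneous_fat] = Tissue.SUBCUT_FAT
    labels[r < rad.muscle] = Tissue.MUSCLE
    labels[r < rad.cortical_bone] = Tissue.CORTICAL_BONE
    labels[r < rad.marrow] = Tissue.MARROW
    return labels


def _add_noise(img: np.ndarray, sd: float, model: str,
               rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return img
    if model == "rician":
        real = img + rng.normal(0.0, sd, img.shape)
        imag = rng.normal(0.0, sd, img.shape)
        return np.hypot(real, imag)
    return np.clip(img + rng.normal(0.0, sd, img.shape), 0.0, None)


def generate_phantom(
    config: PhantomConfig,
) -> tuple[ImageStack, ImageStack, ImageStack, PhantomGroundTruth]:
    """Generate the T1, fat and water stacks plus ground truth.

    The three stacks share one voxel grid.  The same ``config`` (including
    ``seed``) reproduces the output bit-exactly.

    Returns
    -------
    (t1, fat, water, ground_truth)
    """
    rng = np.random.default_rng(config.seed)
    labels2d = _label_map(config)
    n_sl = config.n_slices
    labels = np.broadcast_to(labels2d, (n_sl,) + labels2d.shape).copy()
    marrow = labels == Tissue.MARROW

    # true per-voxel fat fraction: the nominal mixing fraction everywhere
    ff_map = np.zeros(labels.shape, dtype=float)
    ff_map[marrow] = config.marrow_fat_fraction
    # T1-channel marrow weight: Bernoulli speckle (partial-volume voxels)
    # if requested, otherwise the same homogeneous mixture
    if config.speckled:
        t1_weight = (rng.random(int(marrow.sum()))
                     < config.marrow_fat_fraction).astype(float)
    else:
        t1_weight = ff_map[marrow]

    sig = config.tissue_signals
    base = {ch: np.zeros(labels.shape, dtype=float) for ch in ("t1", "fat", "water")}
    for key, code in zip(_TISSUE_KEYS, (Tissue.BACKGROUND, Tissue.SKIN,
                                        Tissue.SUBCUT_FAT, Tissue.MUSCLE,
                                        Tissue.CORTICAL_BONE)):
        sel = labels == code
        for ch in base:
            base[ch][sel] = getattr(sig[key], ch)
    # marrow: fat-fraction-weighted mixture of marrow fat and red marrow
    mfat, red = sig["marrow_fat"], sig["red_marrow"]
    ffm = ff_map[marrow]
    base["t1"][marrow] = t1_weight * mfat.t1 + (1.0 - t1_weight) * red.t1
    for ch in ("fat", "water"):
        base[ch][marrow] = ffm * getattr(mfat, ch) + (1.0 - ffm) * getattr(red, ch)

    if config.speckled:
        spk = np.zeros(labels.shape, dtype=float)
        spk[marrow] = t1_weight
        counts = np.maximum(marrow.sum(axis=(1, 2)), 1)
        speckle_fraction = spk.sum(axis=(1, 2)) / counts
    else:
        speckle_fraction = None

    geom = dict(pixel_spacing=config.pixel_spacing,
                slice_thickness=config.slice_thickness,
                slice_gap=config.slice_gap)
    stacks = {}
    for ch in ("t1", "fat", "water"):   # fixed draw order for reproducibility
        noisy = _add_noise(base[ch], config.noise_sd, config.noise_model, rng)
        stacks[ch] = ImageStack(noisy, **geom)

    area = marrow.sum(axis=(1, 2)) * config.pixel_spacing**2
    with np.errstate(invalid="ignore"):
        slice_ff = np.where(
            marrow.any(axis=(1, 2)),
            ff_map.sum(axis=(1, 2)) / np.maximum(marrow.sum(axis=(1, 2)), 1),
            0.0,
        )
    extent = config.slice_thickness + config.slice_gap
    gt = PhantomGroundTruth(
        labels=labels,
        ff_map=ff_map,
        true_marrow_area=area,
        true_slice_ff=slice_ff,
        true_bmff=100.0 * float(slice_ff.mean()),
        true_bmfv=float((area * slice_ff).sum() * extent),
        speckle_fraction=speckle_fraction,
    )
    return stacks["t1"], stacks["fat"], stacks["water"], gt


def ground_truth_summary(gt: PhantomGroundTruth,
                         geometry: ImageStack) -> tuple[float, float]:
    """Recompute (true_bmff %, true_bmfv cm³) from the voxel-level truth.

    ``geometry`` supplies the voxel grid and slice geometry and must match
    the ground-truth label grid.
    """
    if gt.labels.shape != geometry.data.shape:
        raise ValidationError(
            f"ground-truth grid {gt.labels.shape} does not match "
            f"stack grid {geometry.data.shape}")
    marrow = gt.labels == Tissue.MARROW
    counts = marrow.sum(axis=(1, 2))
    area = counts * geometry.pixel_spacing**2
    slice_ff = np.where(counts > 0,
                        gt.ff_map.sum(axis=(1, 2)) / np.maximum(counts, 1), 0.0)
    bmff = 100.0 * float(slice_ff.mean())
    bmfv = float((area * slice_ff).sum() * geometry.slice_extent)
    return bmff, bmfv


def sample_cohort_configs(
    n: int,
    seed: int = 0,
    base: PhantomConfig | None = None,
    speckled: bool = True,
    ff_range: tuple[float, float] = (0.70, 0.90),
    marrow_radius_range: tuple[float, float] = (0.50, 0.80),
    n_slices_range: tuple[int, int] = (24, 34),
) -> list[PhantomConfig]:
    """Draw ``n`` phantom configurations with varied anatomy.

    Marrow radius, cortical shell, fat fraction and stack length vary
    between phantoms the way tibia cross-sections vary between children;
    each phantom receives its own sub-seed so the cohort is reproducible
    from ``seed`` alone.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    base = base if base is not None else PhantomConfig()
    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(n):
        r_marrow = rng.uniform(*marrow_radius_range)
        radii = TissueRadii(
            marrow=r_marrow,
            cortical_bone=r_marrow + 0.4,
            muscle=base.radii.muscle,
            subcutaneous_fat=base.radii.subcutaneous_fat,
            skin=base.radii.skin,
        )
        configs.append(replace(
            base,
            radii=radii,
            marrow_fat_fraction=float(rng.uniform(*ff_range)),
            n_slices=int(rng.integers(n_slices_range[0], n_slices_range[1] + 1)),
            speckled=speckled,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return configs
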