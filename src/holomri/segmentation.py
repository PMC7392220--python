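"""Automated brain-tissue and tumor segmentation of axial MR slices.

Pipeline per slice:

1. *Seed automation* — the Canny detector is applied twice with two high
   thresholds (defaults 0.1 and 0.2 on the normalised gradient magnitude,
   lower threshold 0).  The 0.1 pass keeps skull, tumor and tissue contours;
   the 0.2 pass keeps only the high-contrast skull/tumor contours.  Their
   set difference, cleaned by a small area opening, leaves target points on
   brain-tissue contours only.
2. *Pixel weight matrix* — every pixel is weighted by its gray-level
   difference from the mean intensity of the seed points,
   ``W = 1 / (1 + (|I - mu| / kappa)^2)``, a strictly positive, bounded map
   that is large inside the seeded region and small elsewhere.
3. *Fast marching* — W is the speed of an Eikonal front started at the
   seeds; the front covers the region of interest quickly and stalls at its
   boundary.
4. *Arrival-time thresholding* — normalised arrival times below a small
   threshold (default 0.009) give the binary mask; the seeded connected
   component is kept and interior holes are filled.

The tumor stage reuses the machinery with a single seed: the brightest
pixel of the skull-stripped brain, with propagation confined to the brain
mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._util import as_float_image
from .eikonal import fmm_arrival_times, normalize_arrival_times

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline (all dimensionless or in pixels)."""

    canny_high_1: float = 0.1     # high threshold of the permissive Canny pass
    canny_high_2: float = 0.2     # high threshold of the strict Canny pass
    canny_low: float = 0.0        # shared low (hysteresis) threshold
    canny_sigma: float = 1.4      # Gaussian smoothing of the Canny detector
    opening_radius: int = 1       # area opening removes components smaller than (2r+1)^2
    arrival_threshold: float = 0.009   # on normalised arrival times in [0, 1]
    kappa: float = 0.04           # weight softness: |I - mu| = kappa gives weight 1/2
    no_tumor_zscore: float = 3.0  # seed must exceed brain median + z * robust std to count as tumor
    seed_margin: int = 4          # erosion (pixels) of the brain mask before tumor seeding
    tumor_seed_dilation: int = 1  # tumor seed block half-width; the block mean sets mu

    def __post_init__(self) -> None:
        if not self.canny_high_1 < self.canny_high_2:
            raise ValueError("canny_high_1 must be < canny_high_2")
        if not 0.0 < self.arrival_threshold <= 1.0:
            raise ValueError("arrival_threshold must lie in (0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class SeedSet:
    """Initialised target points for one region."""

    points: np.ndarray            # (n, 2) array of (row, col)
    kind: str                     # "brain" | "tumor"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=int))
        if self.points.size == 0:
            raise ValueError("seed set must be nonempty")
        if self.points.shape[1] != 2:
            raise ValueError("seed points must be (row, col) pairs")


@dataclass
class WeightMatrix:
    """Pixel weight matrix used as the fast-marching speed function."""

    values: np.ndarray
    seed_reference_intensity: float


@dataclass
class SegmentationResult:
    """Binary mask, gray-level masked image and arrival-time map for one region."""

    binary_mask: np.ndarray
    gray_mask: np.ndarray
    arrival: np.ndarray           # normalised arrival times in [0, 1]
    threshold: float
    seeds: SeedSet | None = None


@dataclass
class SliceSegmentation:
    """Brain and tumor segmentation of one slice."""

    brain: SegmentationResult
    tumor: SegmentationResult
    tumor_present: bool
    index: int = 0


def canny_edges(
    image: np.ndarray, low: float, high: float, sigma: float = 1.4
) -> np.ndarray:
    """One-pixel-wide Canny edges of a [0, 1] image.

    Gradient magnitude (normalised to its maximum) after Gaussian smoothing,
    non-maximum suppression along the quantised gradient direction, then
    double-threshold hysteresis keeping weak points 8-connected to strong
    ones.  ``low``/``high`` act on the normalised magnitude, so a value of
    0.1 means 10% of the strongest gradient in the image.
    """
    image = as_float_image(image)
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"thresholds must satisfy 0 <= low < high <= 1, got {low}, {high}")
    smoothed = ndimage.gaussian_filter(image, sigma, mode="nearest")
    gr = ndimage.sobel(smoothed, axis=0, mode="nearest")
    gc = ndimage.sobel(smoothed, axis=1, mode="nearest")
    mag = np.hypot(gr, gc)
    peak = mag.max()
    if peak == 0:
        return np.zeros_like(mag, dtype=bool)
    mag /= peak

    angle = np.rad2deg(np.arctan2(gr, gc)) % 180.0
    offsets = np.empty(mag.shape + (2,), dtype=int)
    sector0 = (angle < 22.5) | (angle >= 157.5)
    sector45 = (angle >= 22.5) & (angle < 67.5)
    sector90 = (angle >= 67.5) & (angle < 112.5)
    sector135 = (angle >= 112.5) & (angle < 157.5)
    offsets[sector0] = (0, 1)
    offsets[sector45] = (1, 1)
    offsets[sector90] = (1, 0)
    offsets[sector135] = (1, -1)

    keep = np.zeros_like(mag, dtype=bool)
    for off, sel in (
        ((0, 1), sector0),
        ((1, 1), sector45),
        ((1, 0), sector90),
        ((1, -1), sector135),
    ):
        nxt = np.roll(mag, shift=(-off[0], -off[1]), axis=(0, 1))
        prv = np.roll(mag, shift=(off[0], off[1]), axis=(0, 1))
        # asymmetric tie-break keeps plateau ridges one pixel wide
        keep |= sel & (mag > prv) & (mag >= nxt)
    keep &= mag > 0
    keep[0, :] = keep[-1, :] = False
    keep[:, 0] = keep[:, -1] = False

    strong = keep & (mag > high)
    weak = keep & (mag > low)
    if not strong.any():
        return np.zeros_like(mag, dtype=bool)
    labels, _ = ndimage.label(weak, structure=_EIGHT)
    good = np.unique(labels[strong])
    return weak & np.isin(labels, good[good > 0])


def brain_seed_points(image: np.ndarray, config: SegmentationConfig | None = None) -> SeedSet:
    """Automated brain-tissue target points via the double-threshold Canny rule.

    Seeds are the ON pixels of ``edges(low, 0.1) \\ edges(low, 0.2)`` after an
    area opening that removes components smaller than an
    ``opening_radius``-sized neighbourhood.
    """
    config = config or SegmentationConfig()
    e_permissive = canny_edges(image, config.canny_low, config.canny_high_1, config.canny_sigma)
    e_strict = canny_edges(image, config.canny_low, config.canny_high_2, config.canny_sigma)
    diff = e_permissive & ~e_strict
    min_size = (2 * config.opening_radius + 1) ** 2
    labels, n = ndimage.label(diff, structure=_EIGHT)
    if n:
        sizes = ndimage.sum_labels(diff, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_size) + 1
        diff &= ~np.isin(labels, small)
    if not diff.any():
        raise ValueError(
            "no brain seeds found: the two Canny passes left no tissue-contrast contours"
        )
    return SeedSet(points=np.argwhere(diff), kind="brain")


def tumor_seed_point(
    image: np.ndarray, brain_mask: np.ndarray, smooth: int = 0
) -> SeedSet:
    """The brightest pixel of the skull-stripped brain (ties: smallest (row, col)).

    With ``smooth`` > 0 the arg-max is taken over a (2*smooth+1)-sized local
    mean restricted to the mask, which keeps the seed off noise spikes and
    ties away from region boundaries.
    """
    image = as_float_image(image)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty; cannot seed the tumor stage")
    if smooth > 0:
        size = 2 * smooth + 1
        num = ndimage.uniform_filter(np.where(brain_mask, image, 0.0), size)
        den = ndimage.uniform_filter(brain_mask.astype(float), size)
        score = np.where(brain_mask & (den > 0), num / np.maximum(den, 1e-12), -np.inf)
    else:
        score = np.where(brain_mask, image, -np.inf)
    idx = np.unravel_index(np.argmax(score), score.shape)
    return SeedSet(points=np.array([idx]), kind="tumor")


def pixel_weight_matrix(image: np.ndarray, seeds: SeedSet, kappa: float) -> WeightMatrix:
    """Weights inversely related to the gray-level difference from the seed mean.

    ``W = 1 / (1 + (|I - mu|/kappa)^2)`` with ``mu`` the mean intensity over
    the seed points; W = 1 where the intensity equals mu and decays smoothly
    (W = 1/2 at a difference of exactly ``kappa``).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    image = as_float_image(image)
    mu = float(image[seeds.points[:, 0], seeds.points[:, 1]].mean())
    diff = (image - mu) / kappa
    return WeightMatrix(values=1.0 / (1.0 + diff * diff), seed_reference_intensity=mu)


def segment_region(
    image: np.ndarray,
    seeds: SeedSet,
    config: SegmentationConfig | None = None,
    support: np.ndarray | None = None,
) -> SegmentationResult:
    """Segment one region: weight matrix -> FMM -> arrival-time threshold.

    The binary mask is the set of pixels whose normalised arrival time is
    below ``config.arrival_threshold``, reduced to the connected component(s)
    containing the seeds, with interior holes filled.
    """
    config = config or SegmentationConfig()
    image = as_float_image(image)
    weights = pixel_weight_matrix(image, seeds, config.kappa)
    raw = fmm_arrival_times(weights.values, seeds.points, support=support)
    arrival = normalize_arrival_times(raw)
    if config.arrival_threshold >= 1.0:
        binary = np.isfinite(raw)  # no cut: every reached pixel belongs to the region
    else:
        binary = arrival < config.arrival_threshold
    if not binary.any():
        raise ValueError(
            f"empty mask: no pixel below arrival threshold {config.arrival_threshold}"
        )
    labels, _ = ndimage.label(binary)
    seed_labels = np.unique(labels[seeds.points[:, 0], seeds.points[:, 1]])
    binary = np.isin(labels, seed_labels[seed_labels > 0])
    binary = ndimage.binary_fill_holes(binary)
    return SegmentationResult(
        binary_mask=binary,
        gray_mask=image * binary,
        arrival=arrival,
        threshold=config.arrival_threshold,
        seeds=seeds,
    )


def _empty_result(image: np.ndarray, threshold: float, seeds: SeedSet) -> SegmentationResult:
    empty = np.zeros(image.shape, dtype=bool)
    return SegmentationResult(
        binary_mask=empty,
        gray_mask=np.zeros_like(np.asarray(image, dtype=float)),
        arrival=np.ones(image.shape),
        threshold=threshold,
        seeds=seeds,
    )


def segment_brain_and_tumor(series, config: SegmentationConfig | None = None) -> list[SliceSegmentation]:
    """Segment brain tissue then tumor on every slice of a normalised series.

    The brain is segmented first from automated Canny seeds; the tumor seed
    is the brightest pixel of the skull-stripped gray mask and its front is
    confined to the brain support.  A slice whose candidate seed is not
    hyperintense relative to the brain (below mean + ``no_tumor_zscore`` *
    std) is reported as a valid empty tumor result with
    ``tumor_present=False`` rather than an error, since series routinely
    contain tumor-free slices.
    """
    config = config or SegmentationConfig()
    slices = series.slices if hasattr(series, "slices") else list(series)
    out = []
    for i, image in enumerate(slices):
        try:
            brain_seeds = brain_seed_points(image, config)
            brain = segment_region(image, brain_seeds, config)
            # skull-stripping margin: residual skull rim in the brain mask must
            # not capture the brightest-pixel rule, so seed on an eroded core
            core = ndimage.binary_erosion(brain.binary_mask, iterations=config.seed_margin)
            if not core.any():
                core = brain.binary_mask
            seed = tumor_seed_point(image, core, smooth=config.tumor_seed_dilation)
            brain_values = image[core]
            # robust hyperintensity test: a tumor must stand clear of the
            # tissue texture; median/MAD so a present tumor cannot inflate
            # its own acceptance cutoff
            med = np.median(brain_values)
            sigma = 1.4826 * np.median(np.abs(brain_values - med))
            cutoff = med + config.no_tumor_zscore * sigma
            seed_intensity = image[seed.points[0, 0], seed.points[0, 1]]
            if seed_intensity < cutoff:
                tumor = _empty_result(image, config.arrival_threshold, seed)
                present = False
            else:
                # the seed *block* (not the noisy argmax pixel alone) sets the
                # reference intensity of the tumor weight matrix
                r0, c0 = seed.points[0]
                d = config.tumor_seed_dilation
                block = [
                    (r, c)
                    for r in range(r0 - d, r0 + d + 1)
                    for c in range(c0 - d, c0 + d + 1)
                    if 0 <= r < image.shape[0] and 0 <= c < image.shape[1] and core[r, c]
                ]
                seed = SeedSet(points=np.array(block or [[r0, c0]]), kind="tumor")
                tumor = segment_region(image, seed, config, support=brain.binary_mask)
                tumor.binary_mask &= brain.binary_mask
                tumor.gray_mask = image * tumor.binary_mask
                present = True
        except ValueError as exc:
            raise RuntimeError(f"segmentation failed on slice {i}: {exc}") from exc
        out.append(SliceSegmentation(brain=brain, tumor=tumor, tumor_present=present, index=i))
    return out
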