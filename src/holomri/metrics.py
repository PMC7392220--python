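"""Quantitative evaluation: reconstruction quality, segmentation accuracy,
and tumor morphometry.

* ``rmse`` — root-mean-square error between two [0, 1] rasters (monitors
  IFTA convergence).
* ``scaled_snr`` — signal-to-noise ratio with a norm-matching factor
  ``beta = ||I|| / ||I_d||`` removing the global intensity scale, so the
  metric compares structure, not exposure.
* ``speckle_contrast`` — C = sigma / mu over a region; the standard
  granularity measure of a coherent reconstruction (1 for fully developed
  speckle, 0 for a smooth image).
* ``dice`` and ``bf_score`` — region-overlap and boundary-F1 segmentation
  accuracy in [0, 1].
* ``region_properties`` / ``tumor_volume`` — physical area (cm^2), solidity
  and stack volume (cm^3) of tumor masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

_EIGHT = np.ones((3, 3), dtype=bool)


def rmse(reference: np.ndarray, test: np.ndarray) -> float:
    """Root mean square of pixel differences between two equally shaped rasters."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    return float(np.sqrt(np.mean((reference - test) ** 2)))


def scaled_snr(reference: np.ndarray, reconstructed: np.ndarray) -> tuple[float, float]:
    """Scale-invariant SNR = ||I||^2 / ||I - beta * I_d||^2 with beta = ||I||/||I_d||.

    Returns ``(snr, beta)``; the SNR is +inf when the scaled residual is
    exactly zero (i.e. the reconstruction is a positive multiple of the
    reference).
    """
    i = np.asarray(reference, dtype=float)
    i_d = np.asarray(reconstructed, dtype=float)
    if i.shape != i_d.shape:
        raise ValueError(f"shape mismatch: {i.shape} vs {i_d.shape}")
    norm_i = np.linalg.norm(i)
    norm_d = np.linalg.norm(i_d)
    if norm_i == 0:
        raise ValueError("reference intensity is identically zero")
    if norm_d == 0:
        raise ValueError("reconstructed intensity is identically zero; beta undefined")
    beta = norm_i / norm_d
    denom = np.linalg.norm(i - beta * i_d) ** 2
    snr = float("inf") if denom == 0 else float(norm_i**2 / denom)
    return snr, float(beta)


def speckle_contrast(intensity: np.ndarray, region_mask: np.ndarray | None = None) -> float:
    """C = sigma / mu over the masked pixels (population standard deviation)."""
    intensity = np.asarray(intensity, dtype=float)
    if region_mask is None:
        values = intensity.ravel()
    else:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != intensity.shape:
            raise ValueError("mask shape must match intensity")
        if not region_mask.any():
            raise ValueError("region mask is empty")
        values = intensity[region_mask]
    mu = values.mean()
    if mu == 0:
        raise ValueError("zero mean intensity; speckle contrast undefined")
    return float(values.std() / mu)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|); 1 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with any 8-neighbour outside the mask (image border counts as outside)."""
    return mask & ~ndimage.binary_erosion(mask, structure=_EIGHT, border_value=0)


def bf_score(
    mask_a: np.ndarray, mask_b: np.ndarray, tolerance: float | None = None
) -> float:
    """Boundary F1 score: harmonic mean of boundary precision and recall.

    A boundary pixel matches if it lies within ``tolerance`` pixels
    (Euclidean) of the other mask's boundary; the default tolerance is
    0.75% of the image diagonal.  Two empty masks score 1; one empty mask
    scores 0.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() and not b.any():
        return 1.0
    if not a.any() or not b.any():
        return 0.0
    if tolerance is None:
        tolerance = 0.0075 * float(np.hypot(*a.shape))
    ba, bb = _boundary(a), _boundary(b)
    dist_to_b = ndimage.distance_transform_edt(~bb)
    dist_to_a = ndimage.distance_transform_edt(~ba)
    precision = float(np.mean(dist_to_b[ba] <= tolerance))
    recall = float(np.mean(dist_to_a[bb] <= tolerance))
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def region_properties(
    mask: np.ndarray, pixel_spacing: tuple[float, float] | float
) -> tuple[float, float | None]:
    """Physical area (cm^2) and solidity of a binary mask.

    Area is the pixel count times the pixel area (``pixel_spacing`` in mm).
    Solidity is the pixel count divided by the area of the convex hull of
    the union of pixel squares (polygonal hull of all pixel corners), so a
    filled convex region has solidity exactly 1.  An empty mask has area 0
    and undefined (None) solidity.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = (
        (float(pixel_spacing), float(pixel_spacing))
        if np.isscalar(pixel_spacing)
        else (float(pixel_spacing[0]), float(pixel_spacing[1]))
    )
    if min(spacing) <= 0:
        raise ValueError("pixel spacing must be positive")
    count = int(mask.sum())
    area_cm2 = count * spacing[0] * spacing[1] / 100.0  # mm^2 -> cm^2
    if count == 0:
        return 0.0, None
    pix = np.argwhere(mask).astype(float)
    corners = np.concatenate(
        [pix + offset for offset in ((0, 0), (0, 1), (1, 0), (1, 1))]
    )
    try:
        hull_area = ConvexHull(corners).volume  # "volume" is the area in 2-D
    except QhullError:
        hull_area = float(count)
    solidity = min(count / hull_area, 1.0)
    return area_cm2, solidity


def tumor_volume(
    masks: list[np.ndarray],
    pixel_spacing: tuple[float, float] | float,
    slice_separation: float,
) -> float:
    """Stack volume in cm^3: sum of per-slice areas times the slice separation (mm)."""
    if not masks:
        raise ValueError("need at least one mask")
    if slice_separation <= 0:
        raise ValueError("slice_separation must be positive")
    areas = [region_properties(m, pixel_spacing)[0] for m in masks]
    return float(sum(areas) * slice_separation / 10.0)  # cm^2 * mm -> cm^3


@dataclass
class MetricsReport:
    """Bundle of the evaluation metrics for one reconstruction/segmentation."""

    rmse: float | None = None
    snr: float | None = None
    beta_snr: float | None = None
    sigma: float | None = None
    speckle_contrast: float | None = None
    dice: float | None = None
    bf_score: float | None = None
    area_cm2: float | None = None
    solidity: float | None = None
    volume_cm3: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}
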