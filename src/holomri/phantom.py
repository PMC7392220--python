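"""Synthetic brain-MR phantom generator with ground-truth masks.

The phantom emulates the appearance of an axial T1-weighted post-contrast
slice of a glioblastoma patient at the level of detail the downstream
pipeline is sensitive to:

* a bright elliptical skull ring surrounding the brain,
* mid-intensity brain tissue carrying a smooth sinusoidal texture (so that
  edge-based seed automation finds tissue contours of intermediate
  contrast),
* a hyperintense, irregular, star-convex tumor blob strictly inside the
  brain,
* optional multi-slice stacks with an ellipsoid-like tapering tumor and
  follow-up pairs with a grown or shrunk tumor on identical brain geometry
  (i.e. co-registered by construction).

Every generated object comes with ground-truth brain and tumor masks, so
segmentation and holography stages can be evaluated without any external
dataset.  Intensities live in [0, 1]; geometry defaults mirror a typical
axial series (0.6875 mm pixel spacing, 6.5 mm slice separation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a (seed, key) pair."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic slice generator.

    Intensities are fractions of the display range [0, 1]; lengths are in
    pixels unless the name says millimetres.
    """

    image_shape: tuple[int, int] = (320, 260)
    pixel_spacing: float = 0.6875        # mm per pixel (isotropic)
    slice_separation: float = 6.5        # mm between slice centres
    slice_thickness: float = 5.0         # mm, acquisition thickness
    skull_intensity: float = 1.0
    tissue_intensity: float = 0.55
    tumor_intensity: float = 0.85
    tumor_center: tuple[float, float] | None = None  # (row, col); None = parietal-ish default
    tumor_radius: float = 18.0           # pixels, mean radius
    irregularity: float = 0.3            # radial boundary perturbation amplitude
    noise_sigma: float = 0.01            # additive Gaussian noise std
    seed: int = 0
    texture_amplitude: float = 0.12      # tissue texture contrast
    texture_period: float = 10.0         # tissue texture period, pixels
    skull_thickness: float = 3.0         # pixels

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 16 or cols < 16:
            raise ValueError("image_shape must be at least 16x16")
        for name in ("skull_intensity", "tissue_intensity", "tumor_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.tumor_intensity <= self.tissue_intensity:
            raise ValueError("tumor must be hyperintense: tumor_intensity > tissue_intensity")
        if self.skull_intensity < self.tumor_intensity:
            raise ValueError("skull_intensity must be >= tumor_intensity")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValueError("irregularity must lie in [0, 1]")
        if self.tumor_radius <= 0:
            raise ValueError("tumor_radius must be positive")
        if self.pixel_spacing <= 0 or self.slice_separation <= 0:
            raise ValueError("physical spacings must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 2 <= self.skull_thickness <= 4:
            raise ValueError("skull ring thickness must be 2-4 pixels")

    @property
    def brain_center(self) -> tuple[float, float]:
        rows, cols = self.image_shape
        return ((rows - 1) / 2.0, (cols - 1) / 2.0)

    @property
    def brain_semiaxes(self) -> tuple[float, float]:
        rows, cols = self.image_shape
        return (0.38 * rows, 0.40 * cols)

    def default_tumor_center(self) -> tuple[float, float]:
        rows, cols = self.image_shape
        return (0.42 * rows, 0.58 * cols)


@dataclass
class PhantomTruth:
    """A generated slice with its ground-truth masks."""

    image: np.ndarray
    brain_mask: np.ndarray
    tumor_mask: np.ndarray
    config: PhantomConfig

    def __post_init__(self) -> None:
        assert self.brain_mask.shape == self.image.shape
        assert self.tumor_mask.shape == self.image.shape


def _ellipse_interior(shape, center, semiaxes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return ((rr - center[0]) / semiaxes[0]) ** 2 + ((cc - center[1]) / semiaxes[1]) ** 2 < 1.0


def _perturbation_coefficients(config: PhantomConfig) -> np.ndarray:
    """Low-order Fourier coefficients of the tumor boundary perturbation P(theta).

    Harmonics 2..5 with RNG coefficients, normalised so max |P| <= 1; the
    resulting radius r(theta) = R (1 + irregularity * P) stays positive and
    star-convex for irregularity <= 1.
    """
    rng = _rng(config.seed, 0)
    # draw order fixed: texture phases first, then perturbation coefficients
    _ = rng.uniform(0.0, 2.0 * np.pi, size=2)
    coeffs = rng.normal(size=(2, 4))  # cos/sin x harmonics 2..5
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    p = _eval_perturbation(theta, coeffs)
    peak = np.max(np.abs(p))
    if peak > 0:
        coeffs = coeffs / peak
    return coeffs


def _texture_phases(config: PhantomConfig) -> np.ndarray:
    rng = _rng(config.seed, 0)
    return rng.uniform(0.0, 2.0 * np.pi, size=2)


def _eval_perturbation(theta: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    harmonics = np.arange(2, 2 + coeffs.shape[1])
    ang = np.multiply.outer(theta, harmonics)
    return np.cos(ang) @ coeffs[0] + np.sin(ang) @ coeffs[1]


def _tumor_mask(config: PhantomConfig, radius: float, center, coeffs) -> np.ndarray:
    rr, cc = np.mgrid[0 : config.image_shape[0], 0 : config.image_shape[1]].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dc, dr)
    r_theta = radius * (1.0 + config.irregularity * _eval_perturbation(theta, coeffs))
    return dist < r_theta


def _check_tumor_inside_brain(config: PhantomConfig, radius: float, center, coeffs) -> None:
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    r_theta = radius * (1.0 + config.irregularity * _eval_perturbation(theta, coeffs))
    if np.any(r_theta <= 0):
        raise ValueError("tumor boundary radius collapses to zero; lower irregularity")
    br, bc = config.brain_center
    sa, sb = config.brain_semiaxes
    pr = center[0] + r_theta * np.cos(theta)
    pc = center[1] + r_theta * np.sin(theta)
    # require a 2-pixel margin to the inner skull boundary
    if np.any(((pr - br) / (sa - 2.0)) ** 2 + ((pc - bc) / (sb - 2.0)) ** 2 >= 1.0):
        raise ValueError(
            f"tumor (radius {radius:.1f} px at {center}) does not fit inside the brain ellipse"
        )


def _generate_slice(
    config: PhantomConfig,
    radius: float | None,
    noise_key: tuple[int, ...],
    with_tumor: bool = True,
) -> PhantomTruth:
    rows, cols = config.image_shape
    center = config.tumor_center or config.default_tumor_center()
    coeffs = _perturbation_coefficients(config)
    phases = _texture_phases(config)

    brain = _ellipse_interior(config.image_shape, config.brain_center, config.brain_semiaxes)
    outer = _ellipse_interior(
        config.image_shape,
        config.brain_center,
        tuple(s + config.skull_thickness for s in config.brain_semiaxes),
    )
    skull = outer & ~brain

    if with_tumor and radius is not None and radius > 0:
        _check_tumor_inside_brain(config, radius, center, coeffs)
        tumor = _tumor_mask(config, radius, center, coeffs)
    else:
        tumor = np.zeros(config.image_shape, dtype=bool)

    image = np.zeros(config.image_shape, dtype=float)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    omega = 2.0 * np.pi / config.texture_period
    texture = config.texture_amplitude * np.sin(omega * rr + phases[0]) * np.sin(
        omega * cc + phases[1]
    )
    # the tissue texture fades out in a narrow band along the skull and
    # around the lesion, keeping its medium-contrast contours spatially
    # separate from the high-contrast skull/tumor rims (as CSF does in a
    # real T1 slice); without the band the edge maps of the two structures
    # would touch, which real tissue interfaces do not do
    from scipy import ndimage as _ndi

    fade = np.clip((_ndi.distance_transform_edt(brain) - 3.0) / 6.0, 0.0, 1.0)
    if tumor.any():
        fade *= np.clip((_ndi.distance_transform_edt(~tumor) - 3.0) / 6.0, 0.0, 1.0)
    texture = texture * fade
    image[brain] = config.tissue_intensity + texture[brain]
    image[skull] = config.skull_intensity
    image[tumor] = config.tumor_intensity

    if config.noise_sigma > 0:
        noise = _rng(config.seed, *noise_key).normal(0.0, config.noise_sigma, size=image.shape)
        image = image + noise
    image = np.clip(image, 0.0, 1.0)
    return PhantomTruth(image=image, brain_mask=brain, tumor_mask=tumor, config=config)


def make_brain_slice(config: PhantomConfig | None = None) -> PhantomTruth:
    """Generate one synthetic axial slice with skull ring, textured brain and tumor.

    Deterministic for a fixed ``config.seed``; the tumor is a star-convex
    blob with boundary radius ``r(theta) = tumor_radius * (1 + irregularity *
    P(theta))`` for a smooth low-order Fourier perturbation ``P``.
    """
    config = config or PhantomConfig()
    return _generate_slice(config, config.tumor_radius, noise_key=(1, 0))


def make_series(
    config: PhantomConfig | None = None,
    n_slices: int = 6,
    tumor_slices: range | tuple[int, int] | None = None,
) -> list[PhantomTruth]:
    """Generate an ordered stack of slices with an ellipsoid-like tapering tumor.

    ``tumor_slices`` is the index range (inclusive bounds tuple or ``range``)
    that contains tumor; the tumor radius tapers toward its ends so the stack
    approximates an ellipsoidal lesion.  Slices outside the range have empty
    tumor masks.
    """
    config = config or PhantomConfig()
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if tumor_slices is None:
        tumor_slices = range(n_slices)
    if isinstance(tumor_slices, tuple):
        tumor_slices = range(tumor_slices[0], tumor_slices[1] + 1)
    indices = list(tumor_slices)
    if indices and (min(indices) < 0 or max(indices) >= n_slices):
        raise ValueError("tumor_slices must lie inside [0, n_slices)")

    slices = []
    if indices:
        mid = (indices[0] + indices[-1]) / 2.0
        half = (indices[-1] - indices[0]) / 2.0 + 0.5
    for s in range(n_slices):
        if s in indices:
            t = (s - mid) / half
            scale = np.sqrt(max(1.0 - t * t, 0.15))
            slices.append(_generate_slice(config, config.tumor_radius * scale, noise_key=(1, s)))
        else:
            slices.append(_generate_slice(config, None, noise_key=(1, s), with_tumor=False))
    return slices


def make_followup_pair(
    config: PhantomConfig | None = None, growth_factor: float = 1.5
) -> tuple[PhantomTruth, PhantomTruth]:
    """Generate a registered follow-up pair; the second exam's tumor radius is scaled.

    Brain geometry, texture and tumor shape are identical between the exams
    (the real inputs are co-registered; the phantom is registered by
    construction); only the tumor radius changes by ``growth_factor`` and the
    acquisition noise is redrawn.
    """
    config = config or PhantomConfig()
    if growth_factor <= 0:
        raise ValueError("growth_factor must be positive")
    first = _generate_slice(config, config.tumor_radius, noise_key=(1, 0))
    second = _generate_slice(
        config, config.tumor_radius * growth_factor, noise_key=(2, 0)
    )
    return first, second


def to_mr_series(slices: list[PhantomTruth]):
    """Wrap generated slices in an :class:`holomri.mrio.MRSeries`."""
    from .mrio import MRSeries

    cfg = slices[0].config
    return MRSeries(
        slices=[s.image for s in slices],
        pixel_spacing=(cfg.pixel_spacing, cfg.pixel_spacing),
        slice_thickness=cfg.slice_thickness,
        slice_separation=cfg.slice_separation,
        ids=[f"phantom-{i:03d}" for i in range(len(slices))],
    )
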