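"""Shared numerical helpers: centered unitary transforms and phase wrapping."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def fft_c(field: np.ndarray) -> np.ndarray:
    """Centered unitary forward 2-D Fourier transform (zero frequency at array center)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field), norm="ortho"))


def ifft_c(field: np.ndarray) -> np.ndarray:
    """Centered unitary inverse 2-D Fourier transform."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(field), norm="ortho"))


def wrap_phase(phase: np.ndarray | float) -> np.ndarray:
    """Wrap phase values into [0, 2*pi)."""
    return np.asarray(phase, dtype=float) % TWO_PI


def wrap_to_pi(delta: np.ndarray) -> np.ndarray:
    """Wrap a phase difference into (-pi, pi]."""
    return np.pi - (np.pi - np.asarray(delta, dtype=float)) % TWO_PI


def as_float_image(image: np.ndarray, name: str = "image") -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError(f"{name} contains NaN or Inf values")
    return image
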