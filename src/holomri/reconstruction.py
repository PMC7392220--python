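"""Numerical reconstruction of phase holograms (Fourier-lens simulator).

The SLM sits in the front focal plane of a lens and is illuminated by a
unit plane wave; the back focal plane then carries the Fourier transform
of the displayed field, sampled at ``lambda * f / (N * pitch)`` metres per
pixel.  The simulator computes that intensity with a centred unitary FFT,
so total energy is conserved exactly and Parseval checks hold to rounding.

Temporal multiplexing is modelled as incoherent averaging: the tiles of an
extended hologram are displayed sequentially and their reconstructed
*intensities* are averaged, which suppresses speckle while leaving the
mean image in place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import fft_c
from .holography import OpticsConfig, PhaseHologram, chirp_phase


@dataclass
class ReconstructionPlane:
    """Nonnegative intensity raster in the back focal plane."""

    intensity: np.ndarray
    pixel_scale: tuple[float, float]   # metres per pixel (row, col)
    optics: OpticsConfig

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def reconstruct_field(hologram: PhaseHologram, refocus_z: float = 0.0) -> np.ndarray:
    """Complex field in the back focal plane, optionally refocused.

    ``refocus_z`` multiplies the SLM field by the inverse chirp of that
    propagation distance before the transform, which brings a layer encoded
    at ``z = refocus_z`` into focus.
    """
    field = hologram.field
    if refocus_z != 0.0:
        field = field * chirp_phase(hologram.shape, -refocus_z, hologram.optics)
    return fft_c(field)


def fourier_reconstruct(
    hologram: PhaseHologram, refocus_z: float = 0.0
) -> ReconstructionPlane:
    """Intensity of the Fourier-lens reconstruction of a phase hologram."""
    intensity = np.abs(reconstruct_field(hologram, refocus_z)) ** 2
    return ReconstructionPlane(
        intensity=intensity,
        pixel_scale=hologram.optics.reconstruction_pixel(hologram.shape),
        optics=hologram.optics,
    )


def multiplexed_reconstruct(
    tiles: list[PhaseHologram], refocus_z: float = 0.0
) -> ReconstructionPlane:
    """Incoherent (temporally multiplexed) reconstruction of sub-holograms.

    The mean of the individual reconstructed intensities; normalising by the
    tile count keeps single- and multi-tile reconstructions directly
    comparable in SNR and speckle-contrast computations.
    """
    if not tiles:
        raise ValueError("need at least one tile")
    shape = tiles[0].shape
    if any(t.shape != shape for t in tiles):
        raise ValueError("all tiles must share one shape")
    acc = np.zeros(shape)
    for tile in tiles:
        acc += fourier_reconstruct(tile, refocus_z).intensity
    return ReconstructionPlane(
        intensity=acc / len(tiles),
        pixel_scale=tiles[0].optics.reconstruction_pixel(shape),
        optics=tiles[0].optics,
    )
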