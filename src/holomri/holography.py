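"""Phase-only hologram synthesis for a Fourier-lens projection system.

The core is the iterative Fourier transform algorithm (IFTA, the
Gerchberg-Saxton loop): alternating projections between the object plane,
where the target amplitude ``sqrt(I)`` is enforced, and the SLM plane,
where unit amplitude (plane-wave illumination of a phase-only modulator)
is enforced.  On top of the plain IFTA two display schemes are built:

* a layered 3-D tumor map — each slice's hologram is multiplied by a
  quadratic chirp (paraxial propagation transfer function, axial placement)
  and a linear phase ramp (lateral placement), and all layers are
  superposed by complex addition into a single phase hologram;
* a side-by-side follow-up comparison — per exam, brain-tissue and tumor
  holograms are combined with the tumor weighted by a factor ``gamma``
  (default 2) to highlight the lesion, the later exam is shifted by a phase
  ramp, and everything is superposed into one hologram.

All transforms are unitary and centred (zero frequency at the array
centre).  Phase fields are stored wrapped to [0, 2*pi); the phase of an
exact zero is defined as 0.  Lateral shifts are specified in
reconstruction-plane pixels and realised as exact DFT-bin linear phases, so
a ramped reconstruction is the unramped one circularly shifted; the
physical shift in metres is ``shift * lambda * f / (N * pitch)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import TWO_PI, as_float_image, fft_c, ifft_c, wrap_phase, wrap_to_pi


@dataclass(frozen=True)
class OpticsConfig:
    """Geometry of the projection system: laser, SLM and Fourier lens."""

    wavelength: float = 670e-9          # m
    slm_pixel_pitch: float = 8e-6       # m
    slm_shape: tuple[int, int] = (1080, 1920)
    focal_length: float = 0.125         # m

    def __post_init__(self) -> None:
        if min(self.wavelength, self.slm_pixel_pitch, self.focal_length) <= 0:
            raise ValueError("optics parameters must be positive")
        if min(self.slm_shape) < 1:
            raise ValueError("slm_shape must be positive")

    @property
    def wave_number(self) -> float:
        """k = 2*pi / lambda, in rad/m."""
        return TWO_PI / self.wavelength

    def reconstruction_pixel(self, shape: tuple[int, int]) -> tuple[float, float]:
        """Metres per pixel in the back focal plane for a hologram of ``shape``."""
        lf = self.wavelength * self.focal_length
        return (lf / (shape[0] * self.slm_pixel_pitch), lf / (shape[1] * self.slm_pixel_pitch))


@dataclass
class PhaseHologram:
    """A pure-phase hologram: phi in radians wrapped to [0, 2*pi)."""

    phase: np.ndarray
    optics: OpticsConfig

    def __post_init__(self) -> None:
        self.phase = wrap_phase(as_float_image(self.phase, "phase"))

    @property
    def field(self) -> np.ndarray:
        """The unit-modulus complex field exp(i*phi) displayed on the SLM."""
        return np.exp(1j * self.phase)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass
class IterationTrace:
    """Convergence record of one IFTA run."""

    rmse: list[float]                  # per-iteration reconstruction RMSE
    phase_change: list[float]          # RMS wrapped phase change per iteration
    n_iterations: int
    converged: bool
    epsilon: float


@dataclass(frozen=True)
class LayerSpec:
    """Axial/lateral placement of one reconstruction layer.

    ``z`` is the propagation distance of the chirp in metres (0 = in the
    focal plane, no defocus); ``shift_px`` is the lateral shift of the
    layer in reconstruction-plane pixels (row, col).
    """

    z: float = 0.0
    shift_px: tuple[float, float] = (0.0, 0.0)

    def delta_u(self, optics: OpticsConfig, shape: tuple[int, int]) -> tuple[float, float]:
        """Physical lateral shift (metres) realised by ``shift_px`` on this grid."""
        pr, pc = optics.reconstruction_pixel(shape)
        return (self.shift_px[0] * pr, self.shift_px[1] * pc)

    def tilt_angles(self, optics: OpticsConfig, shape: tuple[int, int]) -> tuple[float, float]:
        """(sin(alpha), sin(beta)) = delta_u / z for a nonzero propagation distance."""
        if self.z == 0:
            raise ValueError("tilt angles are undefined for z = 0")
        du = self.delta_u(optics, shape)
        return (du[0] / self.z, du[1] / self.z)


def zero_pad_center(image: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Centre ``image`` in a zero field of ``target_shape``.

    Odd remainders put the extra zero row/column on the trailing side.
    """
    image = np.asarray(image)
    rows, cols = image.shape
    tr, tc = target_shape
    if rows > tr or cols > tc:
        raise ValueError(f"image {image.shape} larger than target {target_shape}")
    out = np.zeros(target_shape, dtype=image.dtype)
    r0, c0 = (tr - rows) // 2, (tc - cols) // 2
    out[r0 : r0 + rows, c0 : c0 + cols] = image
    return out


def padded_shape(optics: OpticsConfig, pad_factor: int = 4) -> tuple[int, int]:
    """Shape of the extended hologram: ``pad_factor`` times the SLM window per axis."""
    return (optics.slm_shape[0] * pad_factor, optics.slm_shape[1] * pad_factor)


def ifta(
    target_intensity: np.ndarray,
    max_iter: int = 200,
    epsilon: float = 0.05,
    initial_phase: np.ndarray | str = "random",
    seed: int = 0,
) -> tuple[np.ndarray, IterationTrace]:
    """Phase-retrieval loop for a Fourier phase-only hologram.

    Starting from the target amplitude ``sqrt(I)``, alternate between the
    SLM plane (keep phase, force unit amplitude) and the object plane (keep
    phase, force the target amplitude) until the RMS wrapped change of the
    hologram phase — with the unobservable global piston removed — drops
    below ``epsilon`` radians, or ``max_iter`` iterations.

    ``initial_phase`` is the object-plane starting phase: ``"random"``
    (default) uses a seeded uniform diffuser, which breaks the Hermitian
    symmetry a real-valued start is trapped in (a real object has a
    conjugate-symmetric spectrum, so a flat start stagnates in the real
    subspace until rounding noise frees it); ``"zero"`` is the flat start;
    an array is used as given.

    Returns the hologram-plane phase (wrapped to [0, 2*pi)) and the trace.
    The hologram reconstructs through a *forward* centred transform:
    ``|fft_c(exp(i*phi))|^2`` approximates I up to scale.
    """
    intensity = as_float_image(target_intensity, "target intensity")
    if np.any(intensity < 0):
        raise ValueError("target intensity must be nonnegative")
    total = intensity.sum()
    if total == 0:
        raise ValueError("target intensity is identically zero")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    amplitude = np.sqrt(intensity)
    target_norm = intensity / intensity.max()
    target_norm_2 = float(np.linalg.norm(target_norm))

    if isinstance(initial_phase, str):
        if initial_phase == "zero":
            phase0 = np.zeros_like(amplitude)
        elif initial_phase == "random":
            phase0 = np.random.default_rng(seed).uniform(0.0, TWO_PI, amplitude.shape)
        else:
            raise ValueError("initial_phase must be 'random', 'zero' or an array")
    else:
        phase0 = np.asarray(initial_phase, dtype=float)
    obj = amplitude * np.exp(1j * phase0)

    rmse_trace: list[float] = []
    dphi_trace: list[float] = []
    prev_phase: np.ndarray | None = None
    converged = False
    n = 0
    for n in range(1, max_iter + 1):
        # object -> SLM plane; the hologram is what the forward transform of
        # the SLM field must invert, so propagate with the inverse transform
        holo = ifft_c(obj)
        phase = np.angle(holo)
        slm_field = np.exp(1j * phase)
        # SLM -> object plane
        recon = fft_c(slm_field)
        recon_intensity = np.abs(recon) ** 2
        # norm-matched intensity RMSE on the [0, 1] target scale: the global
        # brightness of a phase-only reconstruction is arbitrary, so the
        # reconstruction is rescaled to equal energy before differencing
        beta = target_norm_2 / max(float(np.linalg.norm(recon_intensity)), 1e-300)
        rmse_trace.append(float(np.sqrt(np.mean((beta * recon_intensity - target_norm) ** 2))))
        # iteration 1 is measured against the zero initial hologram guess;
        # a global phase offset is unobservable, so the piston (circular
        # mean of the change) is removed before taking the RMS
        delta = phase if prev_phase is None else phase - prev_phase
        piston = np.angle(np.mean(np.exp(1j * delta)))
        dphi = float(np.sqrt(np.mean(wrap_to_pi(delta - piston) ** 2)))
        dphi_trace.append(dphi)
        if dphi < epsilon:
            converged = True
            break
        prev_phase = phase
        obj = amplitude * np.exp(1j * np.angle(recon))

    trace = IterationTrace(
        rmse=rmse_trace,
        phase_change=dphi_trace,
        n_iterations=n,
        converged=converged,
        epsilon=epsilon,
    )
    return wrap_phase(phase), trace


def _freq_grids(shape: tuple[int, int], optics: OpticsConfig):
    """Centred spatial-frequency grids (cycles/m) of the SLM sampling."""
    fr = np.fft.fftshift(np.fft.fftfreq(shape[0], d=optics.slm_pixel_pitch))
    fc = np.fft.fftshift(np.fft.fftfreq(shape[1], d=optics.slm_pixel_pitch))
    return np.meshgrid(fr, fc, indexing="ij")


def chirp_phase(shape: tuple[int, int], z: float, optics: OpticsConfig) -> np.ndarray:
    """Quadratic chirp (paraxial propagation transfer function) over ``shape``.

    ``chi_z(v) = exp(i * k * (lambda^2 / 2) * z * |v|^2)`` with ``v`` the
    centred spatial-frequency grid; equals ``exp(i * pi * lambda * z |v|^2)``.
    ``z`` may be negative (opposite propagation direction); z = 0 gives ones.
    """
    vr, vc = _freq_grids(shape, optics)
    return np.exp(1j * (np.pi * optics.wavelength * z) * (vr**2 + vc**2))


def ramp_phase(
    shape: tuple[int, int], shift_px: tuple[float, float], optics: OpticsConfig | None = None
) -> np.ndarray:
    """Linear phase ramp shifting the reconstruction by ``shift_px`` pixels.

    Built directly on DFT bins, so an integer shift makes the reconstruction
    an exact circular shift of the unshifted one (Fourier shift theorem on
    the sampled grid).
    """
    rows, cols = shape
    ir = np.arange(rows) - rows // 2
    ic = np.arange(cols) - cols // 2
    pr = TWO_PI * shift_px[0] * ir / rows
    pc = TWO_PI * shift_px[1] * ic / cols
    return np.exp(1j * (pr[:, None] + pc[None, :]))


def modulate_layer(
    field: np.ndarray, layer: LayerSpec, optics: OpticsConfig
) -> np.ndarray:
    """Multiply a hologram field by its layer's chirp and ramp (pure phase factors)."""
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("hologram field must be 2-D")
    out = field
    if layer.z != 0.0:
        out = out * chirp_phase(field.shape, layer.z, optics)
    if layer.shift_px != (0.0, 0.0):
        out = out * ramp_phase(field.shape, layer.shift_px, optics)
    return out


def superpose_layers(fields: list[np.ndarray], optics: OpticsConfig) -> PhaseHologram:
    """Complex addition of modulated holograms; the sum's argument is the final phase.

    Where the sum is exactly zero the phase is defined as 0.
    """
    if not fields:
        raise ValueError("need at least one field to superpose")
    shape = fields[0].shape
    if any(f.shape != shape for f in fields):
        raise ValueError("all fields must share one shape")
    total = np.sum(fields, axis=0)
    phase = np.angle(total)
    phase[total == 0] = 0.0
    return PhaseHologram(phase=wrap_phase(phase), optics=optics)


def build_tumor_stack_hologram(
    tumor_slices: list[np.ndarray],
    layers: list[LayerSpec],
    optics: OpticsConfig,
    pad_factor: int = 4,
    max_iter: int = 200,
    epsilon: float = 0.05,
) -> tuple[PhaseHologram, list[IterationTrace]]:
    """Scheme 1: layered 3-D tumor map hologram.

    Each tumor gray-mask is zero-padded to ``pad_factor`` times the SLM
    window, run through the IFTA, modulated by its layer's chirp and ramp,
    and all layers are superposed by complex addition.
    """
    if len(tumor_slices) != len(layers):
        raise ValueError("one LayerSpec per tumor slice is required")
    shifts = [l.shift_px for l in layers]
    if len(set(shifts)) != len(shifts):
        warnings.warn("duplicate lateral shifts: layers will overlap in the reconstruction")
    shape = padded_shape(optics, pad_factor)
    fields, traces = [], []
    for image, layer in zip(tumor_slices, layers):
        padded = zero_pad_center(np.asarray(image, dtype=float), shape)
        phase, trace = ifta(padded, max_iter=max_iter, epsilon=epsilon)
        fields.append(modulate_layer(np.exp(1j * phase), layer, optics))
        traces.append(trace)
    return superpose_layers(fields, optics), traces


def default_layer_stack(
    n_layers: int = 4,
    layer_spacing: float = 6.5e-3,
    shift_step_px: float | tuple[float, float] | None = None,
    optics: OpticsConfig | None = None,
    pad_factor: int = 4,
) -> list[LayerSpec]:
    """Evenly spaced layers: z = s * layer_spacing, lateral shifts on a line.

    The default lateral step spreads the layers across a quarter of the
    reconstruction field so neighbouring layers do not overlap.
    """
    optics = optics or OpticsConfig()
    shape = padded_shape(optics, pad_factor)
    if shift_step_px is None:
        step = (0.0, shape[1] / 8.0)
    elif np.isscalar(shift_step_px):
        step = (0.0, float(shift_step_px))
    else:
        step = tuple(shift_step_px)
    offset = (n_layers - 1) / 2.0
    return [
        LayerSpec(
            z=s * layer_spacing,
            shift_px=((s - offset) * step[0], (s - offset) * step[1]),
        )
        for s in range(n_layers)
    ]


def build_comparative_hologram(
    brain_first: np.ndarray,
    tumor_first: np.ndarray,
    brain_second: np.ndarray,
    tumor_second: np.ndarray,
    gamma: float = 2.0,
    shift_px: tuple[float, float] = (0.0, 0.0),
    optics: OpticsConfig | None = None,
    pad_factor: int = 4,
    max_iter: int = 200,
    epsilon: float = 0.05,
) -> tuple[PhaseHologram, dict]:
    """Scheme 2: side-by-side follow-up comparison with tumor highlighting.

    Per exam, IFTA holograms of the brain-tissue and tumor targets are
    superposed with the tumor field weighted by ``gamma`` (> 1 raises the
    reconstructed intensity over the tumor footprint by about ``gamma^2``).
    The second exam's composite field is modulated by a phase ramp so the
    two exams reconstruct side by side, separated by ``shift_px``; the final
    hologram is the phase of the complex sum of both composites.

    Returns the hologram and a metadata dict (per-target traces and the
    expected lateral separation in pixels and metres).
    """
    optics = optics or OpticsConfig()
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    shape = padded_shape(optics, pad_factor)
    fields = {}
    traces = {}
    for name, img in (
        ("brain_first", brain_first),
        ("tumor_first", tumor_first),
        ("brain_second", brain_second),
        ("tumor_second", tumor_second),
    ):
        img = np.asarray(img, dtype=float)
        if img.sum() == 0:
            fields[name] = None
            traces[name] = None
            continue
        padded = zero_pad_center(img, shape)
        phase, trace = ifta(padded, max_iter=max_iter, epsilon=epsilon)
        fields[name] = np.exp(1j * phase)
        traces[name] = trace

    def composite(brain_key: str, tumor_key: str) -> np.ndarray:
        b, t = fields[brain_key], fields[tumor_key]
        if b is None and t is None:
            raise ValueError(f"both {brain_key} and {tumor_key} targets are empty")
        if t is None:
            return b
        if b is None:
            return gamma * t
        return b + gamma * t

    first = composite("brain_first", "tumor_first")
    second = composite("brain_second", "tumor_second")
    ramp = ramp_phase(shape, shift_px)
    hologram = superpose_layers([first, second * ramp], optics)
    meta = {
        "traces": traces,
        "gamma": gamma,
        "separation_px": shift_px,
        "separation_m": LayerSpec(z=0.0, shift_px=shift_px).delta_u(optics, shape),
    }
    return hologram, meta


def tile_hologram(hologram: PhaseHologram) -> list[PhaseHologram]:
    """Cut an extended hologram into SLM-sized sub-holograms, row-major order.

    A factor-4 padded hologram yields 4 x 4 = 16 tiles, each the size of the
    SLM window; concatenating the tiles in order reproduces the extended
    phase exactly.
    """
    tr, tc = hologram.optics.slm_shape
    rows, cols = hologram.shape
    if rows % tr or cols % tc:
        raise ValueError(
            f"extended shape {hologram.shape} is not an integer multiple of the SLM {hologram.optics.slm_shape}"
        )
    tiles = []
    for i in range(rows // tr):
        for j in range(cols // tc):
            tiles.append(
                PhaseHologram(
                    phase=hologram.phase[i * tr : (i + 1) * tr, j * tc : (j + 1) * tc].copy(),
                    optics=hologram.optics,
                )
            )
    return tiles
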