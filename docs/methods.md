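# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `holomri`, in the spirit of a package methods
appendix. Nothing here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Segmentation model

The segmentation treats a region of interest as the set of pixels a
monotone front can reach quickly. The front's speed is the pixel weight
matrix

    W(x, y) = 1 / (1 + (|I(x, y) − μ| / κ)²),

with μ the mean intensity over the initialised target points. The
functional form is a design choice: the underlying idea only fixes that
weights are *inversely related* to the gray-level difference; this
rational form is bounded in (0, 1], strictly positive (the fast marching
method requires F > 0 wherever propagation is allowed), dimensionless, and
has a single interpretable knob — |I − μ| = κ gives W = 1/2.

**κ default 0.04.** The binary mask is taken where *normalised* arrival
times fall below 0.009, so the in-region/out-region speed contrast must be
large enough that the slowest in-region pixel arrives before 0.9% of the
maximum arrival time. With tissue/tumor/background contrasts of the order
0.3–0.55 and in-region fluctuations of order 0.1 (texture) or 0.02
(noise), κ = 0.04 puts in-region weights near 1 and out-region weights
near 1/100. Larger κ (0.1) measurably fails: the contrast ratio saturates
around 10× and the 0.009 cutoff then cannot cover a whole region; smaller
κ makes in-region texture too slow. κ is exposed in
`SegmentationConfig`.

**Arrival-time normalisation.** Raw arrival times are min–max normalised
to [0, 1] over reached pixels before thresholding (seeds at 0, unreached
pixels set to 1). A fixed threshold like 0.009 is only meaningful on a
scale-free map; the raw-time scale depends on image size and κ.

**Seed automation.** Brain seeds are `edges(low=0, high=0.1) \
edges(low=0, high=0.2)` followed by an *area* opening (components smaller
than (2r+1)² pixels removed, r = 1 default). A structural
erosion–dilation opening would delete the one-pixel-wide Canny lines
entirely; the operation's purpose — removing small noisy components — is
exactly area opening. The Canny implementation is the package's own
(Gaussian σ = 1.4, Sobel gradients, four-direction non-maximum
suppression with an asymmetric tie-break that keeps plateau ridges one
pixel wide, 8-connected hysteresis), with thresholds acting on the
gradient magnitude normalised to its maximum, so 0.1/0.2 are
image-independent fractions.

**Tumor stage.** The tumor seed is the arg-max of a 3×3 mask-restricted
local mean over the brain mask eroded by 4 px. Three robustness details
matter: the erosion keeps a residual one-pixel skull rim (intensity ≈ 1)
from capturing the brightest-pixel rule; the local mean keeps the seed off
single noise spikes (a raw arg-max is biased ≈ +3σ and, for a noise-free
flat tumor, ties lexicographically to a *boundary* pixel); and μ for the
weight matrix is averaged over the 3×3 seed block, which the "mean of the
initialised target points" definition covers. Tumor propagation is
confined to the brain mask (masked fast marching, unreached = 1 after
normalisation) rather than slowed by a tiny weight floor: with a floor,
the enormous outside-brain arrival times dominate the normalisation and
the 0.009 cutoff floods the whole brain.

**"No tumor in this slice."** A slice's candidate seed must exceed the
brain's median + 3 × (1.4826 · MAD). Robust statistics are essential in
both directions: a present tumor inflates a plain standard deviation until
mean + 2σ can exceed the tumor intensity itself, and on tumor-free slices
mean + 2σ sits exactly at the tissue-texture maximum. A below-cutoff slice
returns a valid empty tumor result with `tumor_present=False`, not an
error, because series routinely contain tumor-free slices.

**Post-processing.** After thresholding, the connected component(s)
containing seeds are kept and interior holes filled. Hole filling is load
bearing: in the brain stage the tumor is a high-contrast *slow* island
inside the brain and is recovered as a filled hole.

## Fast marching solver

First-order upwind discretisation on the 4-neighbour stencil; min-heap
with deterministic (time, row, col) ordering; each pixel accepted exactly
once; the update solves `max(T−a,0)² + max(T−b,0)² = h²` with a, b the
smaller *accepted* neighbour per axis. The solver is verified against a
Bellman value-iteration oracle (same update, swept to its fixed point) to
1e−6 on random grids, and against the hand-solvable 3×3 uniform case
(neighbours 1, diagonals 1 + 1/√2) to 1e−12.

The first-order scheme overestimates diagonal distances: from a point
source the error is 20.7% at the first diagonal and decays slowly (≈ 10.8%
of the true distance at radius 5.7, ≈ 2.6% at radius 45). Relative
accuracy statements in the tests are therefore measured against the
computed time (|T − d|/T ≤ 10% at radii ≥ 5 px), the only convention
consistent with the pinned stencil.

## Hologram synthesis

Transforms are unitary and centred (`fftshift`/`ifftshift` around every
FFT); all modulation grids have zero frequency at the array centre. Phases
are stored wrapped to [0, 2π); the argument of an exact zero is defined
as 0.

**IFTA.** Object plane: amplitude √I with the running phase; SLM plane:
unit amplitude with the running phase. Stopping: RMS of the wrapped phase
change, with the global piston (circular mean) removed because a global
phase offset is unobservable, below ε = 0.05 rad, or 200 iterations. The
reported RMSE trace is the norm-matched intensity error
`RMS(βI_rec − I/max I)` with `β = ‖I/max I‖ / ‖I_rec‖` — the same β
construction as the scaled SNR metric — because a phase-only
reconstruction's absolute brightness is arbitrary.

**Initial phase.** The default start is a seeded uniform diffuser. A flat
(zero) start is available but documented as stagnating: a real-valued
object has a conjugate-symmetric spectrum, so the iteration is trapped in
the real subspace (phase updates collapse to rounding level within a few
iterations while the error plateaus) until floating-point noise breaks the
symmetry. The diffuser start converges smoothly and is deterministic for a
fixed seed.

**Chirp and ramp.** The chirp is the paraxial propagation transfer
function `χ_z(v) = exp(iπλz|v|²)` on the SLM spatial-frequency grid
`v = (idx − N/2)/(N · pitch)`; z may be negative, χ_z χ_{−z} = 1. Lateral
shifts are specified in reconstruction-plane pixels and realised as exact
DFT-bin linear phases, making the shifted reconstruction an exact circular
shift (verified to 1e−14 in intensity); the physical shift is
`Δu = shift · λf/(N · pitch)` and the equivalent tilt angles
`sin α = Δu/z` are reported by `LayerSpec`.

**3-D stack.** Per slice: IFTA → multiply by χ_{z_s} and the ramp →
complex addition of all layers → take the argument. Layer spacing defaults
to 6.5 mm (typical slice separation); the IFTA runs once per layer on the
full extended (padded) target, never per tile.

**Comparative scheme.** Per exam the composite field is `U_I + γ U_T`
(brain and tumor holograms coherently superposed with the tumor weighted
by γ, default 2); the second exam's composite is multiplied by the ramp;
the displayed phase is the argument of the sum of both composites. The
γ-weighting targets the *field*, so the tumor footprint gains ≈ γ² in
intensity (cross terms between the quasi-independent speckle fields
average out). An alternative formulation that adds γ-scaled *phases*
(`arg U_I + γ arg U_T`) was evaluated and rejected: `e^{i(φ_c+φ_p)}`
reconstructs the convolution of the two exam images rather than their
side-by-side superposition, and measured on the phantom pair it neither
separates the exams at the configured shift nor brightens the tumor — the
coherent-superposition form is the one consistent with displaying all
holograms "superimposed into a single 2-D hologram" and with γ modulating
the tumor's intensity.

Taking the argument of a multi-field sum is itself lossy (the amplitude
|ΣU| is discarded); on two-layer tests ≈ 80% of a layer's window energy
survives, and the loss is documented by a test rather than compensated.

## Reconstruction simulator

The back focal plane carries `|F{e^{iφ}}|²` at `λf/(N·pitch)` metres per
pixel; energy is conserved exactly by the unitary transform (Parseval
checks to 1e−10). Refocusing multiplies by χ_{−z} before the transform.
Temporal multiplexing averages the tile intensities (normalising by tile
count keeps single- and multi-frame intensities comparable; the scaled SNR
and speckle contrast are scale-invariant anyway, so summing would change
nothing). No camera chain, SLM fill factor, DC term or replica orders are
modelled.

## Phantom

The phantom generates what the pipeline is actually sensitive to, not an
anatomically realistic MR simulation:

* brain: ellipse (semi-axes 0.38·rows, 0.40·cols) of tissue intensity
  0.55, surrounded by a 3-px skull ring at 1.0, on a zero background;
* tissue texture: a sinusoidal product pattern (period 10 px, amplitude
  0.12, RNG phases) whose contours land between the two Canny thresholds,
  with a fade band (zero within ~3 px, full by ~9 px) along the skull and
  around the lesion so medium-contrast tissue contours stay spatially
  separate from the high-contrast rims — as CSF separates cortex from
  skull in a real T1 slice. Without the band, the zero-low-threshold
  hysteresis web can 8-connect texture ridges to the skull crest and the
  two-pass subtraction collapses;
* tumor: star-convex blob at a parietal-like position, intensity 0.85,
  default mean radius 18 px (≈ 4.8 cm² at 0.6875 mm pixels, a realistic
  lesion size), boundary `r(θ) = R(1 + irregularity · P(θ))` with P a
  low-order (harmonics 2–5) Fourier series normalised to max |P| = 1;
* stacks taper the radius ellipsoidally across the tumor slice range;
  follow-up pairs share identical geometry (registered by construction)
  with the radius scaled and the noise redrawn;
* Gaussian noise (σ default 0.01) added last, then clipped to [0, 1].

Geometry defaults (320×260 pixels, 0.6875 mm spacing, 5 mm thickness,
6.5 mm separation) mirror a typical axial T1 post-contrast series.

What passing phantom tests does *not* show: robustness to bias fields,
partial-volume effects, multi-modal contrast, anatomical texture, or
mis-registration between exams — real inputs are assumed co-registered.

## Problem sizes

Tests and the acceptance script run holography on a 1/8-scale SLM grid
(135×240, padded to 540×960, 16 tiles) and segmentation at the full
320×260 slice size. The transform physics (shift exactness, speckle
statistics, chirp refocusing) is scale-free, so the reduced grid is a
choice of demonstration size, not an approximation; the full 1080×1920
SLM with its 4320×7680 extended hologram is exercised where only geometry
matters (padding and tiling).

## Known limitations

* Slice-wise 2-D only; no 3-D (26-neighbour) fast marching.
* The comparative display assumes the two exams are already co-registered.
* The 0.009 arrival threshold, while scale-free, still interacts with
  region size: very large regions need the sharper weight contrast that
  κ = 0.04 provides (κ = 0.05 measurably truncates tumors at 1.5× the
  default radius).
* No SLM device artifacts (fill factor, DC term, replica orders,
  flicker), no CCD noise, no physical-unit radiometry.
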