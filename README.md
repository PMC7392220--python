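# holomri

Comparative holographic projection of brain-tumor MR follow-up exams:
automated fast-marching segmentation of brain tissue and tumor from axial
T1-weighted post-contrast slices, phase-only hologram synthesis for two
display schemes (a layered 3-D tumor map and a side-by-side follow-up
comparison with tumor highlighting), a numerical Fourier-lens
reconstruction simulator with temporally multiplexed speckle suppression,
and the quantitative metrics to evaluate all of it.

The intended users are researchers in medical image display and
computer-generated holography who want a tested, fully synthetic-data-backed
reference implementation of this pipeline: every stage runs end to end on a
built-in brain phantom with ground-truth masks, so no patient data or
optical bench is required.

## The method

**Segmentation.** A front propagating over the image with speed
`F(x, y) > 0` has first-arrival time `T(x, y)` obeying the Eikonal equation
`|∇T| = 1/F`, solved by the fast marching method (min-heap, first-order
upwind, each pixel accepted once). The speed is a *pixel weight matrix*
built from gray-level differences to automatically selected target points:

```
W(x, y) = 1 / (1 + (|I(x, y) − μ| / κ)²),
```

where `μ` is the mean intensity of the seed points and `κ` (default 0.04)
sets how fast weight decays with contrast. Brain-tissue seeds come from
applying the Canny detector twice (high thresholds 0.1 and 0.2 on the
normalised gradient magnitude, low threshold 0) and subtracting: the strict
pass keeps only skull/tumor contours, so the difference marks tissue
contours. The tumor seed is the brightest pixel of the skull-stripped
brain. Thresholding the normalised arrival times at 0.009 and keeping the
seeded component yields the masks.

**Holography.** A phase-only hologram `φ` of a target intensity `I` is
retrieved with the iterative Fourier transform (Gerchberg–Saxton) loop,
alternating the SLM constraint (unit amplitude) and the object constraint
(amplitude `√I`), stopping when the RMS phase change drops below
`ε = 0.05` rad. For the 3-D tumor map, each slice's hologram is modulated
by a quadratic chirp `χ_z(v) = exp(iπλz|v|²)` (axial placement, layer
spacing 6.5 mm) and a linear phase ramp (lateral placement), and all layers
are superposed by complex addition, `φ_F = arg Σ_s U_s χ_{z_s} R_s`. For
the follow-up comparison, each exam's brain and tumor holograms combine as
`U_I + γ U_T` with `γ = 2` highlighting the lesion, the later exam is
ramped sideways, and the sum of both composites is displayed.

**Reconstruction and speckle.** The SLM sits in the front focal plane of a
lens, so the reconstruction is `|F{e^{iφ}}|²` sampled at `λf/(N·pitch)` per
pixel. The extended (4× padded) hologram is cut into 16 SLM-sized tiles;
displaying them sequentially and averaging the intensities (temporal
multiplexing) suppresses speckle: the contrast `C = σ/μ` over the object
drops to roughly a quarter of a single frame's.

**Metrics.** Dice `2|A∩B|/(|A|+|B|)` and boundary-F1 for segmentation
accuracy; scale-matched SNR `‖I‖²/‖I − βI_d‖²` with `β = ‖I‖/‖I_d‖`;
speckle contrast `C = σ/μ`; tumor area (cm²), convex-hull solidity, and
stack volume `Σ area × slice separation` (cm³).

## Worked example

```bash
python examples/01_phantom_and_segmentation.py
```

```
phantom: (320, 260) pixels, tumor 1036 px ground truth
brain seeds found: 13203
tumor seed at (125, 151) (brightest skull-stripped point)
tumor present: True
brain  Dice 0.992, BF 1.000
tumor  Dice 0.986, BF 1.000
tumor area 5.04 cm^2, solidity 0.91
```

The phantom is a 320×260 axial slice (0.6875 mm pixels) with a bright
skull ring, textured tissue and a hyperintense irregular tumor; Dice/BF
near 1 mean the automated masks nearly coincide with the ground truth, and
the area/solidity are the morphometrics a follow-up report quotes per exam.

```bash
python examples/03_speckle_multiplexing.py
```

```
extended hologram (540, 960) -> 16 tiles of (135, 240)
speckle contrast C = sigma/mu over the brain footprint:
  single tile:        C_1  = 0.959 .. 1.039
  16-tile multiplex:  C_16 = 0.217
  ratio C_16/C_1 (vs best single tile): 0.227
```

A single coherent frame shows fully developed speckle (`C ≈ 1`); averaging
the 16 tile reconstructions smooths it by more than 4×. The other examples
demonstrate IFTA convergence, refocusing each layer of the 3-D tumor stack
at its encoded depth, and the γ-highlighted side-by-side comparison.

A thin CLI wraps the same library: `holomri phantom | segment | hologram |
reconstruct | evaluate | run` (see `holomri --help`).

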