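"""Suppress speckle by temporally multiplexing the 16 tiles of a hologram.

The extended (4x padded) hologram is cut into 16 SLM-sized sub-holograms;
displayed sequentially, their reconstructed intensities add incoherently.
Each tile carries a different subset of spatial frequencies, so its speckle
pattern differs, and the average is much smoother than any single frame.
"""

from holomri import (
    OpticsConfig,
    PhantomConfig,
    PhaseHologram,
    fourier_reconstruct,
    ifta,
    make_brain_slice,
    multiplexed_reconstruct,
    padded_shape,
    speckle_contrast,
    tile_hologram,
    zero_pad_center,
)

optics = OpticsConfig(slm_shape=(135, 240))
truth = make_brain_slice(PhantomConfig(seed=0))
shape = padded_shape(optics, 4)
phase, _ = ifta(zero_pad_center(truth.image, shape), max_iter=200, epsilon=0.05)
tiles = tile_hologram(PhaseHologram(phase=phase, optics=optics))
print(f"extended hologram {shape} -> {len(tiles)} tiles of {optics.slm_shape}")

# object support at tile resolution (the brain footprint, downsampled 4x)
factor = shape[0] // optics.slm_shape[0]
support = (
    zero_pad_center(truth.brain_mask.astype(float), shape)
    .reshape(optics.slm_shape[0], factor, optics.slm_shape[1], factor).mean(axis=(1, 3)) > 0.5
)

c_singles = [speckle_contrast(fourier_reconstruct(t).intensity, support) for t in tiles]
c_multi = speckle_contrast(multiplexed_reconstruct(tiles).intensity, support)
print(f"speckle contrast C = sigma/mu over the brain footprint:")
print(f"  single tile:        C_1  = {min(c_singles):.3f} .. {max(c_singles):.3f}")
print(f"  16-tile multiplex:  C_16 = {c_multi:.3f}")
print(f"  ratio C_16/C_1 (vs best single tile): {c_multi/min(c_singles):.3f}")
print("C near 1 is fully developed speckle; the multiplexed ratio well below 0.7")
print("reproduces the direction and magnitude of the optical-bench reduction.")
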