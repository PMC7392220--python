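"""Side-by-side comparative hologram of two follow-up exams with tumor highlighting.

A registered phantom pair (the tumor grows by 1.5x between exams) is
segmented; per exam, brain and tumor holograms are superposed with the
tumor field weighted by gamma = 2, the later exam is shifted by a phase
ramp, and everything becomes one phase hologram.  The reconstruction shows
the two exams side by side with the lesions brightened.
"""

import numpy as np
from scipy import ndimage

from holomri import (
    OpticsConfig,
    PhantomConfig,
    build_comparative_hologram,
    fourier_reconstruct,
    make_followup_pair,
    padded_shape,
    region_properties,
    segment_brain_and_tumor,
    to_mr_series,
    zero_pad_center,
)

optics = OpticsConfig(slm_shape=(135, 240))
first, second = make_followup_pair(PhantomConfig(seed=0), growth_factor=1.5)
segs = segment_brain_and_tumor(to_mr_series([first, second]))

for i, s in enumerate(segs, 1):
    area, solidity = region_properties(s.tumor.binary_mask, first.config.pixel_spacing)
    print(f"exam {i}: tumor area {area:.2f} cm^2, solidity {solidity:.2f}")

shift = (0.0, 300.0)
holo, meta = build_comparative_hologram(
    segs[0].brain.gray_mask, segs[0].tumor.gray_mask,
    segs[1].brain.gray_mask, segs[1].tumor.gray_mask,
    gamma=2.0, shift_px=shift, optics=optics, pad_factor=4, max_iter=200,
)
print(f"comparative hologram {holo.shape}, configured separation {shift[1]:.0f} px "
      f"({meta['separation_m'][1]*1e3:.2f} mm in the focal plane)")

recon = fourier_reconstruct(holo).intensity
footprint = zero_pad_center(segs[0].tumor.binary_mask.astype(float),
                            padded_shape(optics, 4)) > 0.5
holo1, _ = build_comparative_hologram(
    segs[0].brain.gray_mask, segs[0].tumor.gray_mask,
    segs[1].brain.gray_mask, segs[1].tumor.gray_mask,
    gamma=1.0, shift_px=shift, optics=optics, pad_factor=4, max_iter=200,
)
recon1 = fourier_reconstruct(holo1).intensity
gain = recon[footprint].mean() / recon1[footprint].mean()
print(f"tumor-footprint mean intensity, gamma=2 vs gamma=1: x{gain:.2f}")

smoothed = ndimage.uniform_filter(recon, 9)
p1 = np.unravel_index(np.argmax(smoothed), smoothed.shape)
blocked = smoothed.copy()
blocked[max(p1[0]-100, 0):p1[0]+100, max(p1[1]-150, 0):p1[1]+150] = 0
p2 = np.unravel_index(np.argmax(blocked), blocked.shape)
print(f"reconstructed exam peaks at columns {p1[1]} and {p2[1]} "
      f"(separation {abs(p1[1]-p2[1])} px)")
print("the area/solidity deltas quantify progression; the highlighted, laterally")
print("separated reconstructions are what a clinician would see on the projection.")
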