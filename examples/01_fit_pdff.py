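"""Fit a multi-echo marrow spectrum and compute the T2-corrected fat fraction.

Simulates a four-echo acquisition (TE 12/15/20/25 ms) of a marrow voxel with
a true proton-density fat fraction of 32% at realistic noise, then runs the
constrained Gaussian fit and T2 correction.
"""

import numpy as np

from marrowlab import SpectrumGenSpec, estimate_pdff, generate_spectrum

spectra, truth = generate_spectrum(
    SpectrumGenSpec(pdff_true=0.32, t2_fat=80.0, t2_water=25.0, snr=50, seed=1))
result, fits = estimate_pdff(spectra)

print(f"true PDFF          : {truth.pdff_true:.3f}")
print(f"estimated PDFF     : {result.pdff:.3f}")
print(f"fat T2  (true 80)  : {result.t2_fat:6.1f} ms")
print(f"water T2 (true 25) : {result.t2_water:6.1f} ms")
for fit in fits:
    print(f"  TE {fit.te:4.0f} ms: fat area {fit.fat_area:.4f}, "
          f"narrow water {fit.group_areas['water_narrow']:.4f}")

# The PDFF is the TE=0 fat area over (fat + narrow water); because water
# relaxes faster than fat, skipping the T2 correction would overestimate it:
fit = fits[-1]
sff = fit.fat_area / (fit.fat_area + fit.group_areas["water_narrow"])
print(f"uncorrected fat fraction at TE=25 ms: {sff:.3f}  (biased upward)")
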