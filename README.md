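# marrowlab

Vertebral bone-marrow adiposity is increasingly understood as an active
player in bone loss: as marrow fat goes up, trabecular bone density,
microstructure quality and mechanical strength go down. `marrowlab`
implements the complete analysis chain used to quantify that relationship in
an in-vitro vertebral model, for researchers working on quantitative MR
spectroscopy of marrow, quantitative CT of trabecular bone, or ex-vivo
biomechanics:

1. **MRS fat quantification** — multi-echo single-voxel spectra are fitted in
   the frequency domain with Gaussian lineshapes: nine triglyceride
   resonances (0.9–5.31 ppm) sharing one linewidth, plus narrow (long-T2*)
   and broad (short-T2*) water components at 4.7 ppm. The fat groups E
   (4.2 ppm) and F (5.19/5.31 ppm), which overlap water, are constrained to
   fixed ratios of the resolved A+B area derived from the marrow
   triglyceride structure. Per-echo areas are extrapolated to TE = 0 with
   single-exponential T2 decays, giving the proton-density fat fraction

   PDFF = F(0) / (F(0) + W_narrow(0)),

   where F is the total fat area and W_narrow the narrow water area (the
   broad water component is excluded).
2. **Quantitative CT morphometry** — HU volumes are converted to calcium
   hydroxyapatite-equivalent BMD (mg/cm³) by linear calibration against
   phantom rods; a 12 × 12 mm² ROI over the 20 most central slices is
   binarized at 200 mg/cm³ and summarized as BV/TV, trabecular number via
   the mean intercept length (TbN = (BV/TV) / Tb.Th*, Tb.Th* = mean
   intercept length of the bone phase), a 2D box-counting fractal dimension,
   and the mean/minimum transverse cross-sectional areas.
3. **Biomechanics** — the failure load is the first local maximum of the
   load–displacement curve followed by a drop of strictly more than 10%;
   dividing by the minimum cross-sectional area yields a normalized failure
   load in N/cm².
4. **Statistics** — Lilliefors-corrected Kolmogorov–Smirnov normality
   screening, pairwise OLS regressions (slope B, SE, Pearson r, two-sided
   p), and case-bootstrap validation (1000 resamples) of every slope.

Because cadaveric source data cannot be redistributed, the package ships a
first-class synthetic-data module that emulates the full study — 3 T
four-echo spectra (TE 12/15/20/25 ms, 4096 points, 5 kHz), trabecular
lattice CT volumes at 0.23 × 0.23 × 0.6 mm with an embedded calibration
phantom, softening load curves, and correlated specimen cohorts — with
exactly known ground truth for every stage.

## Worked example

```python
from marrowlab import SpectrumGenSpec, estimate_pdff, generate_spectrum

spectra, truth = generate_spectrum(
    SpectrumGenSpec(pdff_true=0.32, t2_fat=80.0, t2_water=25.0, snr=50, seed=1))
result, fits = estimate_pdff(spectra)
```

prints (see `examples/01_fit_pdff.py`):

```
true PDFF          : 0.320
estimated PDFF     : 0.315
fat T2  (true 80)  :   84.2 ms
water T2 (true 25) :   24.2 ms
uncorrected fat fraction at TE=25 ms: 0.490  (biased upward)
```

The estimate recovers the generating fat fraction to half a percentage point
at realistic noise, and the last line shows why the T2 correction matters:
water relaxes faster than fat, so a single-echo signal fat fraction
overestimates the proton-density value badly.

The full chain (`examples/05_full_pipeline.py`) simulates a ten-specimen
cohort, re-measures every quantity, and prints a mean ± SD summary
(fat fraction 32.3 ± 4.0 %, BMD 120.6 ± 37.8 mg/cm³, normalized failure
load 466.6 ± 179.9 N/cm² for seed 42) plus the pairwise regression table
with bootstrap standard errors and p-values.

Each script in `examples/` demonstrates one capability: PDFF fitting,
CT morphometry, failure-load detection, cohort regression, and the
end-to-end pipeline. A thin CLI mirrors the same steps
(`marrowlab simulate|fit-spectrum|morphometry|failure-load|analyze|run`).

## Layout

- `src/marrowlab/fatmodel.py` — triglyceride spectral model and constraint ratios
- `src/marrowlab/mrs.py` — phasing, constrained Gaussian fitting, T2 correction, PDFF
- `src/marrowlab/morphometry.py` — calibration, ROI, BV/TV, MIL/TbN, FD, areas
- `src/marrowlab/biomech.py` — failure-load rule and normalization
- `src/marrowlab/stats.py` — normality, OLS, bootstrap, regression tables
- `src/marrowlab/synthetic.py` — generators with exact ground truth
- `src/marrowlab/pipeline.py` — end-to-end orchestration with manifests
- `docs/methods.md` — models, assumptions, parameter choices, limitations
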