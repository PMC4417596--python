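# Methods

This note documents the models implemented in `marrowlab`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Spectral model and PDFF

A marrow voxel's 1H spectrum is modelled as a sum of Gaussian lines: nine
triglyceride resonances at 0.90, 1.30, 1.59, 2.00, 2.25, 2.77, 4.20, 5.19
and 5.31 ppm, grouped into the conventional letters A–F, plus two water
components at a nominal 4.7 ppm — a narrow line for the long-T2* water pool
and a broad line for the short-T2* pool. All fat peaks share one linewidth;
the two water linewidths are independent, so exactly three linewidths are
free. Fat peak positions may shift by ±0.05 ppm and water positions by
±0.50 ppm (both water components get the bound, applied independently).

The relative areas of the fat groups are fixed by the average triglyceride
structure, parameterized by chain length, double bonds per molecule and
methylene-interrupted double bonds. The defaults (17.4 / 2.8 / 0.7) describe
a moderately unsaturated depot fat typical of human marrow; they are the
package's choice, exposed as `TriglycerideComposition`, because published
marrow compositions vary and the fit is only weakly sensitive to them. The
groups E and F overlap water strongly, so their areas are not free: they are
tied to the resolved A+B area by the composition's proton-count ratios
(E/(A+B) ≈ 0.054, F/(A+B) ≈ 0.089 at the defaults). The tie is enforced by
construction inside the model function, so it holds to machine precision in
every fit, including non-converged ones.

Fitting minimizes the residual of the phased real spectrum (not the
magnitude, which breaks additivity of overlapping lines in noise) over the
−1 to 7 ppm window; the acquisition axis spans ~39 ppm at 5 kHz/3 T and
everything outside the window is baseline. Zero-order phasing maximizes the
real integral over 0–6 ppm (closed form: the argument of the complex
integral), which is idempotent. The optimizer is bounded trust-region least
squares; amplitudes are initialized from the on-resonance signal values,
linewidths at 20/20/100 Hz within [1, 500] Hz, and the narrow/broad water
identity is resolved after fitting by ordering the two fitted linewidths, so
labels cannot swap between echoes. Tolerances are 1e−12 on cost, step and
gradient; non-convergence sets a flag and warns, never silently.

T2 correction fits `area(TE) = a0 · exp(−TE/T2)` separately to the summed
fat area (the protocol's long TR removes T1 weighting, and a single fat T2
is assumed, so summing the groups loses nothing and stabilizes the fit) and
to the narrow-water area, with T2 bounded in [1, 1000] ms. With exactly two
echoes the closed-form two-point solution is used and flagged; a
non-decaying sequence pins T2 at the upper bound and is flagged. PDFF is the
TE = 0 fat area over fat plus narrow water; the broad water component never
enters, because it does not represent marrow water proton density.

## CT morphometry

Calibration regresses nominal phantom densities on measured mean HU
(ordinary least squares; at least two rods with distinct HU). The density
volume is an element-wise affine map of the HU volume.

The analysis ROI is a 12 × 12 mm² in-plane window over the 20 most central
slices, centred on the specimen-mask centroid (automated in place of manual
placement, for reproducibility). Window sizes round to the nearest voxel
with ties rounded up (12 mm / 0.23 mm → 52 voxels).

Binarization uses a global threshold of 200 mg/cm³; the boundary is
inclusive (density ≥ threshold is bone), a choice that conventions leave
open and that is documented and tested. BV/TV is the bone voxel fraction.

Trabecular number comes from the mean intercept length: one test line per
voxel row along each requested axis-aligned direction, physical (anisotropy
aware) lengths, and wrap-free counting of bone intercepts (a run starting at
the line origin counts once). MIL_d is total bone length divided by
intercept count; Tb.Th* is the mean MIL over the requested directions and
TbN = (BV/TV)/Tb.Th*, the standard plate-model closure. The closure is
isolated in one function so alternatives (e.g. intersections per unit
length) can be swapped. For perfect axis-aligned plate fixtures the
plate-parallel directions are degenerate — lines never exit the bone phase,
making MIL the full line length — so lattice fixtures are evaluated along
the plate normal; isotropic or real structures should use all three axes.
Rotated direction sets are out of scope.

The fractal dimension is computed per binarized transverse slice by box
counting — grid anchored at the origin, sides 2…64 px by powers of two,
partial border boxes counted, the bone mask itself (not its edge) counted —
and FD is the least-squares slope of log N(s) versus log(1/s), averaged over
slices containing bone (empty slices are excluded with a warning). A filled
plane gives exactly 2 and a one-pixel line exactly 1. Whether the original
texture analyses used the mask, its boundary or grayscale texture is not
recoverable; the mask variant is the default and the box-size set is
configurable.

Cross-sectional areas are per-slice pixel counts times the in-plane pixel
area, reported as mean and minimum over nonempty slices (cm²).

## Failure load

The failure load is the first local maximum M of the load–displacement curve
whose subsequent minimum — up to the point where the load first exceeds M
again, or the end of the record — falls strictly below 0.9·M. ">10%" is
read as strictly greater, and the drop window is bounded by re-exceedance so
the drop belongs to that peak and not a later structure; both choices are
boundary-tested. Detection can run on a centred moving average (rig jitter),
but the reported load is always the unsmoothed value at the detected index;
the default applies no smoothing. No qualifying peak yields an explicit
no-failure result, not an exception. Normalized failure load is the simple
quotient by the minimum cross-sectional area.

## Statistics

Normality screening is a one-sample KS test against a normal with
sample-estimated parameters, Lilliefors-corrected by default because the
parameters come from the same data; the uncorrected variant is available via
a flag for comparability with packages that report it. Regressions are
ordinary least squares with Pearson r and a two-sided p from the t
distribution with n−2 df. Bootstrap validation resamples specimens (cases)
with replacement — matching the resampling of small ex-vivo cohorts — with
1000 replicates by default; degenerate replicates with constant x are
redrawn and counted. The bootstrap p-value is by default the sign-crossing
proportion 2·min(frac(B* ≤ 0), frac(B* ≥ 0)), floored at 2/n_boot; a normal
approximation B/se_boot is available as an option. No multiple-testing
correction is applied, and the summary table reports both the plain and the
bootstrap p — published analyses of this design have quoted either, and the
two can legitimately differ (e.g. 0.009 vs 0.013 at n = 10).

In the pairwise regression table, percent-scaled predictors (fat fraction,
BV/TV) enter as fractions by default so slope magnitudes are comparable with
the conventional reporting; r and p are unit-free either way.

Table-style summaries use the sample SD (n−1 denominator).

## Synthetic generators

The generators define the study conditions; every default is either the
protocol value or a documented choice:

- **Spectra**: four echoes at 12/15/20/25 ms, 4096 points, 5 kHz, 3 T,
  fat T2 80 ms, water T2 25 ms (water relaxing faster than fat, as observed
  in marrow), fat/narrow-water linewidths 30 Hz, broad water 150 Hz,
  broad-water fraction 0.2 of total water. Noise is additive white Gaussian
  on the complex signal, with SNR defined against the tallest fat peak
  (1.30 ppm) at the shortest echo. The broad water pool shares the water T2
  across echoes; its decay never enters PDFF. The generating TE = 0 areas
  reproduce the requested PDFF to 1e−12 by construction.
- **Volumes**: axis-aligned plate or rod lattices (closed-form ground truth;
  oblique lattices deferred) at 0.23 × 0.23 × 0.6 mm voxels, bone
  400 mg/cm³, marrow 50 mg/cm³, phantom rods at 0/100/200/400 mg/cm³ in a
  reserved strip, encoded to HU by inverting a configurable affine
  calibration, optional HU noise. Sub-voxel plate thickness or spacing is
  rejected (ground truth undefined under discretization) unless overridden.
- **Curves**: piecewise-linear rise to the true failure load, a controlled
  fractional drop, then a secondary rise; the detection rule recovers the
  generating load exactly on noiseless curves with drops above 10% and
  detects nothing at or below 10%.
- **Cohorts**: multivariate normal over eight variables (fat fraction %,
  BMD, BV/TV %, TbN, FD, normalized FL, min and mean area), defaults being
  the measured cohort means/SDs (fat 32 ± 5 %, BMD 121.5 ± 34.3 mg/cm³,
  BV/TV 38.8 ± 10.8 %, TbN 1.13 ± 0.11 mm⁻¹, FD 1.57 ± 0.07, normalized FL
  442 ± 251 N/cm², mean area 6.5 ± 1.5 cm²; min area 5.8 ± 1.4 cm² chosen
  so that normalized FL × min area reproduces the measured mean failure
  load of ~2580 N). The Gaussian model reflects the observed non-rejection
  of normality for all variables. The correlation matrix fixes the measured
  pairs (fat vs normalized FL −0.77, fat vs BMD −0.72, fat vs BV/TV −0.64,
  fat vs TbN −0.62, fat vs FD −0.36, normalized FL vs BMD/BV/TV/TbN/FD
  0.90/0.88/0.89/0.83) and fills the unmeasured CT-parameter pairs with
  values typical of trabecular bone (0.70–0.90), areas correlated 0.90 with
  each other and independent of the rest; the matrix is positive definite
  (smallest eigenvalue 0.025). Absolute failure load is derived as
  normalized FL × min area for internal consistency.

What the generators do **not** emulate: scanner physics (J-coupling
evolution, eddy currents, chemical-shift displacement), CT beam hardening
and reconstruction kernels, soft-tissue segmentation, irregular vertebral
shapes, and the spatial heterogeneity of real marrow. Passing tests
therefore demonstrate correctness of the analysis chain under its stated
model, not robustness to every artifact of real acquisitions.

## Pipeline

One global seed deterministically derives per-stage, per-specimen seeds via
a seed sequence, so stages are independently reproducible and a rerun is
byte-identical. Drawn cohort values are clipped to loose physical floors
(fat fraction 0.5–99.5 %, BV/TV 5–95 %, min area ≥ 1 cm², normalized FL ≥
10 N/cm²) before simulation, because the unbounded Gaussian can produce
non-physical draws at small n; the `*_true` columns report the clipped
values. Specimen volumes realise the drawn BV/TV with a plate lattice of
period 5 voxels (quantizing the achievable fractions) and choose phase
densities so the ROI mean matches the drawn BMD; measured TbN and FD
therefore describe the synthetic lattice, not the drawn cohort values. A
manifest with the config snapshot, version, output checksums and timestamps
is written on success and on failure.

Default problem sizes (ten specimens, 144 × 156 × 24 voxel volumes, 1000
bootstrap replicates, 1000-volume oracle sweeps at edge lengths 4–12) keep a
full run in the tens of seconds on one CPU while exercising every code path;
all sizes are configurable.

## Known limitations

- The spectral model is Gaussian-only; Lorentzian or Voigt lines are not
  offered.
- MIL directions are axis-aligned; anisotropy tensors from rotated line
  grids are not computed.
- Micro-CT-grade metrics (Tb.Sp, SMI, connectivity density) and vertebral
  contour segmentation from real scans are out of scope.
- The bootstrap-SE check against the analytic OLS SE is a convergence
  statement; single draws at 1000 replicates carry ~3% resampling noise, so
  comparisons average over replicate datasets.
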