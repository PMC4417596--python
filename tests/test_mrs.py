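"""Spectral fitting: phasing, constrained Gaussian fit, T2 correction, PDFF."""

import numpy as np
import pytest

from marrowlab.fatmodel import GROUPS
from marrowlab.mrs import (
    PeakModel,
    Spectrum,
    compute_pdff,
    estimate_pdff,
    fit_peaks,
    phase_spectrum,
    t2_correct,
)
from marrowlab.synthetic import SpectrumGenSpec, generate_spectrum


class TestPhasing:
    def test_phase_rotation_is_inverted(self, noiseless_spectra):
        spectra, _ = noiseless_spectra
        s = spectra[0]
        rotated = Spectrum(ppm=s.ppm, signal=np.asarray(s.signal) * np.exp(1j * np.pi / 2),
                           te=s.te, field_strength=s.field_strength,
                           bandwidth=s.bandwidth)
        recovered = phase_spectrum(rotated)
        assert np.abs(recovered.signal - np.real(s.signal)).max() < 1e-9

    def test_idempotent_on_phased_spectrum(self, noiseless_spectra):
        spectra, _ = noiseless_spectra
        once = phase_spectrum(spectra[0])
        twice = phase_spectrum(once)
        assert np.array_equal(once.signal, twice.signal)

    def test_random_phase_recovers_noiseless_template(self):
        spectra, truth = generate_spectrum(SpectrumGenSpec(snr=200.0, seed=42))
        s = spectra[0]
        rotated = Spectrum(ppm=s.ppm, signal=np.asarray(s.signal) * np.exp(1j * 1.234),
                           te=s.te)
        phased = phase_spectrum(rotated)
        noise_floor = np.abs(np.asarray(s.signal) - truth.noiseless_real[0]).max()
        assert np.abs(phased.signal - truth.noiseless_real[0]).max() < 3 * noise_floor

    def test_all_zero_spectrum_rejected(self):
        s = Spectrum(ppm=np.linspace(8, -2, 512), signal=np.zeros(512, complex), te=12.0)
        with pytest.raises(ValueError, match="zero"):
            phase_spectrum(s)


class TestFitPeaks:
    def test_noiseless_group_areas_recovered(self, noiseless_fit):
        _, fits, truth = noiseless_fit
        for fit in fits:
            decay = np.exp(-fit.te / truth.t2_fat)
            for g in GROUPS:
                expected = truth.group_areas_te0[g] * decay
                assert fit.group_areas[g] == pytest.approx(expected, rel=1e-4)
            wn = truth.area_water_narrow_te0 * np.exp(-fit.te / truth.t2_water)
            assert fit.group_areas["water_narrow"] == pytest.approx(wn, rel=1e-4)

    def test_zero_water_spectrum(self):
        spectra, _ = generate_spectrum(SpectrumGenSpec(pdff_true=1.0, snr=np.inf))
        fit = fit_peaks(spectra[0])
        total_fat = sum(fit.group_areas[g] for g in GROUPS)
        assert fit.group_areas["water_narrow"] < 1e-6 * total_fat
        assert fit.group_areas["water_broad"] < 1e-6 * total_fat

    def test_single_gaussian_closed_form_area(self):
        # one isolated Gaussian at the water position (the only location the
        # model can represent without the E/F tie forcing extra area)
        ppm = np.linspace(10, -4, 4096)
        hz_per_ppm = 3.0 * 42.577
        fwhm = 30.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        amp = 5.0
        area_true = amp * sigma * np.sqrt(2 * np.pi)
        signal = amp * np.exp(-0.5 * ((ppm - 4.70) * hz_per_ppm / sigma) ** 2)
        fit = fit_peaks(Spectrum(ppm=ppm, signal=signal.astype(complex), te=12.0))
        total = sum(fit.group_areas[g] for g in GROUPS) + \
            fit.group_areas["water_narrow"] + fit.group_areas["water_broad"]
        assert total == pytest.approx(area_true, rel=1e-6)

    def test_constraint_satisfied_to_machine_precision(self, noiseless_fit):
        _, fits, truth = noiseless_fit
        r_e, r_f = truth.constraint_ratios
        for fit in fits:
            ab = fit.group_areas["A"] + fit.group_areas["B"]
            assert fit.group_areas["E"] - r_e * ab == 0.0
            assert fit.group_areas["F"] - r_f * ab == 0.0

    def test_spectrum_not_covering_model_rejected(self):
        ppm = np.linspace(3.0, 1.0, 512)
        with pytest.raises(ValueError, match="0–6 ppm"):
            fit_peaks(Spectrum(ppm=ppm, signal=np.ones(512), te=12.0))

    def test_scale_equivariance(self, noiseless_spectra):
        spectra, _ = noiseless_spectra
        s = spectra[0]
        base = fit_peaks(s)
        scaled = fit_peaks(Spectrum(ppm=s.ppm, signal=np.asarray(s.signal) * 3.5,
                                    te=s.te))
        for key, val in base.group_areas.items():
            assert scaled.group_areas[key] == pytest.approx(3.5 * val, rel=1e-6,
                                                            abs=1e-12)


class TestT2Correction:
    def test_two_point_closed_form(self):
        from marrowlab.mrs import PeakFitResult
        areas = {te: np.exp(-te / 50.0) for te in (12.0, 25.0)}
        fits = [
            PeakFitResult(te=te, group_areas={**{g: 0.0 for g in GROUPS},
                                              "A": areas[te],
                                              "water_narrow": areas[te],
                                              "water_broad": 0.0},
                          linewidth_fat=30, linewidth_water_narrow=30,
                          linewidth_water_broad=150, fat_locations={},
                          water_locations=(4.7, 4.7), residual_norm=0.0,
                          converged=True)
            for te in (12.0, 25.0)
        ]
        res = t2_correct(fits, [12.0, 25.0])
        assert res.t2_fat == pytest.approx(50.0, rel=1e-12)
        assert res.area_fat_te0 == pytest.approx(1.0, rel=1e-12)
        assert any("two_point" in f for f in res.flags)

    def test_four_te_recovery(self, noiseless_fit):
        result, _, truth = noiseless_fit
        assert result.t2_fat == pytest.approx(truth.t2_fat, rel=5e-3)
        assert result.t2_water == pytest.approx(truth.t2_water, rel=5e-3)

    def test_equal_areas_give_half_pdff(self):
        spectra, _ = generate_spectrum(SpectrumGenSpec(
            pdff_true=0.5, t2_fat=60.0, t2_water=60.0,
            broad_water_fraction=0.0, snr=np.inf))
        result, _ = estimate_pdff(spectra)
        assert result.pdff == pytest.approx(0.5, abs=1e-3)

    def test_increasing_areas_flagged_at_bound(self):
        from marrowlab.mrs import PeakFitResult
        fits = []
        for te, a in zip((12.0, 15.0, 20.0, 25.0), (1.0, 1.1, 1.2, 1.3)):
            fits.append(PeakFitResult(
                te=te, group_areas={**{g: 0.0 for g in GROUPS}, "A": a,
                                    "water_narrow": a, "water_broad": 0.0},
                linewidth_fat=30, linewidth_water_narrow=30,
                linewidth_water_broad=150, fat_locations={},
                water_locations=(4.7, 4.7), residual_norm=0.0, converged=True))
        res = t2_correct(fits, [12.0, 15.0, 20.0, 25.0])
        assert any("upper_bound" in f for f in res.flags)

    def test_negative_areas_rejected(self):
        from marrowlab.mrs import PeakFitResult
        fits = [PeakFitResult(te=te, group_areas={**{g: 0.0 for g in GROUPS},
                                                  "A": -1.0, "water_narrow": 1.0,
                                                  "water_broad": 0.0},
                              linewidth_fat=30, linewidth_water_narrow=30,
                              linewidth_water_broad=150, fat_locations={},
                              water_locations=(4.7, 4.7), residual_norm=0.0,
                              converged=True)
                for te in (12.0, 15.0, 20.0)]
        with pytest.raises(ValueError, match="negative"):
            t2_correct(fits, [12.0, 15.0, 20.0])


class TestPdff:
    def test_boundary_values(self):
        assert compute_pdff(0.0, 1.0) == 0.0
        assert compute_pdff(2.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            compute_pdff(0.0, 0.0)
        with pytest.raises(ValueError):
            compute_pdff(-1.0, 1.0)

    def test_default_cohort_spectrum_recovered_at_snr50(self):
        spectra, _ = generate_spectrum(SpectrumGenSpec(pdff_true=0.32, snr=50,
                                                       seed=17))
        result, _ = estimate_pdff(spectra)
        assert result.pdff == pytest.approx(0.32, abs=0.01)

    def test_monotone_recovery_over_pdff_grid(self):
        estimates = []
        for pdff in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6):
            spectra, _ = generate_spectrum(SpectrumGenSpec(pdff_true=pdff,
                                                           snr=np.inf))
            result, _ = estimate_pdff(spectra)
            estimates.append(result.pdff)
        assert np.all(np.diff(estimates) > 0)

    def test_single_te_fat_fraction_biased_up_without_t2_correction(self):
        # water relaxes faster than fat, so the uncorrected signal fat
        # fraction at any TE > 0 overestimates the proton-density value
        spectra, truth = generate_spectrum(SpectrumGenSpec(
            pdff_true=0.32, t2_fat=80.0, t2_water=25.0, snr=np.inf))
        fit = fit_peaks(spectra[-1])
        sff = fit.fat_area / (fit.fat_area + fit.group_areas["water_narrow"])
        assert sff > truth.pdff_true + 0.02
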