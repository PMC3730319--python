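"""Alignment, scaling, water removal, baseline, normalization, binning."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import trim_mean

from hypoxmet.errors import (
    CoverageError,
    DegenerateSpectrumError,
    ReferenceNotFoundError,
)
from hypoxmet.spectra import Spectrum
from hypoxmet.spectra_prep import (
    GLUCOSE_REF,
    PrepParams,
    align_to_reference,
    asymmetric_least_squares,
    baseline_correct,
    bin_centers,
    bin_edges,
    bin_matrix,
    bin_spectrum,
    preprocess,
    remove_water,
    robust_mean_normalize,
    scale_to_tmsp,
)
from hypoxmet.synthdata import RenderParams, render_spectrum


def _clean_spectrum(concs, shift=0.0, gain=1.0):
    p = RenderParams(noise_sd=0.0, drift_amplitude=0.0, ppm_shift=shift, gain=gain)
    return render_spectrum(concs, params=p)


class TestSpectrumIO:
    def test_round_trip(self, tmp_path):
        s = Spectrum(
            ppm=np.linspace(10, -0.5, 101),
            intensity=np.arange(101.0),
            sample_id="X1",
            condition="hypoxia",
            time_point=24,
            replicate=3,
        )
        path = tmp_path / "s.txt"
        s.write(path)
        r = Spectrum.read(path)
        np.testing.assert_allclose(r.ppm, s.ppm, atol=1e-6)
        np.testing.assert_allclose(r.intensity, s.intensity, rtol=1e-7)
        assert (r.sample_id, r.condition, r.time_point, r.replicate) == (
            "X1", "hypoxia", 24, 3,
        )

    def test_ascending_axis_flipped_to_descending(self):
        s = Spectrum(ppm=np.array([1.0, 2.0, 3.0]), intensity=np.array([1.0, 2.0, 3.0]))
        assert s.ppm[0] == 3.0 and s.intensity[0] == 3.0

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(ppm=np.array([1.0, 3.0, 2.0]), intensity=np.zeros(3))


class TestAlignment:
    def test_plant_and_recover_shift(self):
        planted = 0.003
        s = _clean_spectrum({"glucose": 2.0}, shift=planted)
        aligned = align_to_reference(s)
        # after alignment the glucose anomeric apex sits at its nominal ppm
        mask = aligned.window(GLUCOSE_REF - 0.05, GLUCOSE_REF + 0.05)
        apex = aligned.ppm[mask][np.argmax(aligned.intensity[mask])]
        assert apex == pytest.approx(GLUCOSE_REF, abs=5e-4)

    def test_fallback_to_tmsp_without_glucose(self):
        s = _clean_spectrum({"lactate": 1.0}, shift=0.002)
        aligned = align_to_reference(s)  # glucose absent -> TMSP fallback
        mask = aligned.window(-0.05, 0.05)
        apex = aligned.ppm[mask][np.argmax(aligned.intensity[mask])]
        assert apex == pytest.approx(0.0, abs=5e-4)

    def test_no_reference_raises(self):
        s = Spectrum(ppm=np.linspace(10, -0.5, 10501), intensity=np.zeros(10501))
        with pytest.raises(ReferenceNotFoundError):
            align_to_reference(s, fallback_tmsp=False)
        with pytest.raises(ReferenceNotFoundError):
            align_to_reference(s)  # fallback finds no TMSP either

    def test_unknown_mode_rejected(self):
        s = _clean_spectrum({"glucose": 1.0})
        with pytest.raises(ValueError):
            align_to_reference(s, mode="lactate_1.33")


class TestScaling:
    def test_gain_invariance(self):
        a = scale_to_tmsp(_clean_spectrum({"lactate": 1.0}, gain=1.0))
        b = scale_to_tmsp(_clean_spectrum({"lactate": 1.0}, gain=4.0))
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-9)

    def test_drift_free_height_estimate(self):
        # a strong additive offset at 0 ppm must not change the scale
        # factor: the scaled spectra differ only by a constant
        clean = _clean_spectrum({"lactate": 1.0})
        shifted = clean.copy()
        shifted.intensity = clean.intensity + 40.0  # constant "drift"
        a, b = scale_to_tmsp(clean), scale_to_tmsp(shifted)
        diff = b.intensity - a.intensity
        assert diff.std() < 1e-9 * abs(diff.mean())


class TestWaterRemoval:
    def test_501_point_oracle(self):
        # 501 points spanning 0-5 ppm at 0.01 spacing: [4.5, 5.0] holds
        # exactly 51 points, so 450 survive
        s = Spectrum(ppm=np.linspace(5.0, 0.0, 501), intensity=np.ones(501))
        out = remove_water(s)
        assert out.n_points == 450
        assert not out.window(4.5, 5.0).any()

    def test_invalid_window(self):
        s = Spectrum(ppm=np.linspace(5, 0, 11), intensity=np.zeros(11))
        with pytest.raises(ValueError):
            remove_water(s, lo=5.0, hi=4.5)


class TestBaseline:
    def test_recovers_quadratic_drift(self):
        x = np.linspace(0, 1, 2000)
        drift = 5.0 + 3.0 * x - 4.0 * x**2
        peaks = np.zeros_like(x)
        for c in (0.2, 0.5, 0.8):
            peaks += 50.0 * np.exp(-0.5 * ((x - c) / 0.002) ** 2)
        z = asymmetric_least_squares(drift + peaks)
        off_peak = np.all(
            np.abs(x[:, None] - np.array([0.2, 0.5, 0.8])[None, :]) > 0.02, axis=1
        )
        assert np.abs(z - drift)[off_peak].max() < 0.2

    def test_flat_spectrum_unchanged(self):
        s = Spectrum(ppm=np.linspace(10, 0, 1000), intensity=np.full(1000, 7.0))
        out = baseline_correct(s)
        # the asymmetric reweighting leaves a tiny residual (<1e-5 relative)
        assert np.abs(out.intensity).max() < 1e-4 * 7.0

    def test_too_few_points(self):
        s = Spectrum(ppm=np.linspace(10, 0, 50), intensity=np.zeros(50))
        with pytest.raises(ValueError):
            baseline_correct(s)


class TestNormalization:
    def test_trimmed_mean_oracle(self):
        vals = np.arange(20.0) + 1.0  # 1..20 on a ppm axis inside the window
        s = Spectrum(ppm=np.linspace(4.0, 2.0, 20), intensity=vals)
        out = robust_mean_normalize(s)
        expected = trim_mean(vals, 0.05)
        np.testing.assert_allclose(out.intensity, vals / expected)
        assert trim_mean(out.intensity, 0.05) == pytest.approx(1.0)

    def test_no_points_in_window(self):
        s = Spectrum(ppm=np.linspace(9, 8, 10), intensity=np.ones(10))
        with pytest.raises(CoverageError):
            robust_mean_normalize(s)

    def test_nonpositive_divisor(self):
        s = Spectrum(ppm=np.linspace(4.0, 2.0, 20), intensity=np.full(20, -1.0))
        with pytest.raises(DegenerateSpectrumError):
            robust_mean_normalize(s)


class TestBinning:
    def test_exactly_420_bins(self):
        assert bin_edges().size - 1 == 420
        s = _clean_spectrum({"lactate": 1.0})
        assert bin_spectrum(s).size == 420

    def test_sum_conservation(self):
        s = _clean_spectrum({"lactate": 1.0, "glucose": 2.0})
        binned = bin_spectrum(s)
        in_range = s.intensity[(s.ppm >= 0.2) & (s.ppm <= 4.4)].sum()
        assert binned.sum() == pytest.approx(in_range, rel=1e-9)

    def test_centers_between_edges(self):
        e, c = bin_edges(), bin_centers()
        np.testing.assert_allclose(c, (e[:-1] + e[1:]) / 2)

    def test_coverage_error(self):
        s = Spectrum(ppm=np.linspace(4.0, 1.0, 100), intensity=np.ones(100))
        with pytest.raises(CoverageError):
            bin_spectrum(s)

    def test_non_integral_width(self):
        with pytest.raises(ValueError):
            bin_edges(0.2, 4.4, 0.013)


class TestChainInvariance:
    def test_gain_and_shift_invariance(self):
        # the same sample measured with different receiver gain and a small
        # calibration error lands on nearly the same binned profile
        concs = {"lactate": 2.0, "glucose": 1.5, "alanine": 0.8}
        a = preprocess(_clean_spectrum(concs, shift=0.0, gain=1.0))
        b = preprocess(_clean_spectrum(concs, shift=0.004, gain=1.8))
        va, vb = bin_spectrum(a), bin_spectrum(b)
        rms = np.sqrt(np.mean((va - vb) ** 2)) / np.sqrt(np.mean(va**2))
        assert rms < 0.02

    def test_bin_matrix_shape_and_meta(self, spectra, binned48):
        assert binned48.values.shape == (18, 420)
        assert binned48.n_bins == 420
        assert set(binned48.meta["condition"]) == {"hypoxia", "normoxia"}
        assert binned48.values.index.equals(binned48.meta.index)

    def test_mismatched_meta_rejected(self, binned48):
        import pandas as pd

        from hypoxmet.spectra_prep import BinnedMatrix

        with pytest.raises(ValueError):
            BinnedMatrix(
                binned48.values, binned48.meta.iloc[:-1], binned48.edges
            )
        with pytest.raises(ValueError):
            BinnedMatrix(binned48.values.iloc[:, :-1], binned48.meta, binned48.edges)

    def test_prep_params_frozen(self):
        p = PrepParams()
        with pytest.raises(dataclasses.FrozenInstanceError):
            p.bin_lo = 0.1
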