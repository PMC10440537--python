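"""Welch spectra on the canonical grid and alpha-peak parametrization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal

from prtms.eeg_io import EEGRecording, standard_montage
from prtms.spectral import (
    ALPHA_BAND,
    FREQ_GRID,
    PowerSpectrum,
    alpha_fwhm,
    alpha_peak,
    band_mean_amplitude,
    region_average_spectrum,
    welch_psd,
)

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TestWelchGrid:
    def test_grid_contract(self, white_recording):
        spec = welch_psd(white_recording())
        assert spec.freqs[0] == 2.0
        assert spec.freqs[-1] == 20.0
        assert spec.freqs.size == 181
        np.testing.assert_allclose(np.diff(spec.freqs), 0.1, rtol=0, atol=1e-12)
        assert np.all(spec.power >= 0)

    def test_zero_signal_gives_zero_power(self):
        rec = EEGRecording(data=np.zeros((19, 30 * 125)), fs=125.0)
        spec = welch_psd(rec)
        assert np.all(spec.power == 0)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        # direct DFT oracle: a 10.0 Hz unit sinusoid concentrates its power
        # in the 10.0 Hz bin of a 10 s rectangular DFT (bin-exact frequency)
        fs, dur = 250.0, 240.0
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        seg = x[: int(fs * 10)]
        dft = np.abs(np.fft.rfft(seg))
        oracle_f = np.fft.rfftfreq(seg.size, 1 / fs)[np.argmax(dft)]
        assert oracle_f == pytest.approx(10.0, abs=1e-9)

        rec = EEGRecording(data=np.tile(x, (19, 1)), fs=fs)
        spec = welch_psd(rec)
        for lead in ("O1", "Cz"):
            i = np.argmax(spec.lead_power(lead))
            assert spec.freqs[i] == pytest.approx(10.0, abs=1e-9)

    def test_matches_scipy_welch_on_clean_data(self, white_recording):
        rec = white_recording(duration_s=40.0, fs=125.0, seed=3)
        spec = welch_psd(rec, clip_uv=None)
        nperseg = int(125.0 * 10)
        f_ref, p_ref = signal.welch(
            rec.data, fs=125.0, window="hann", nperseg=nperseg,
            noverlap=nperseg // 2, detrend="constant", scaling="density",
        )
        i0 = int(round(2.0 / (f_ref[1] - f_ref[0])))
        np.testing.assert_allclose(spec.power, p_ref[:, i0:i0 + 181], rtol=1e-10)

    def test_clipped_segments_are_dropped(self, white_recording):
        rec = white_recording(duration_s=40.0, fs=125.0, seed=4)
        n_clean = welch_psd(rec).n_segments
        rec.data[5, 2000] = 500.0  # one artifact spike
        spec = welch_psd(rec)
        assert spec.n_segments < n_clean
        with_kept = welch_psd(rec, clip_uv=None)
        assert with_kept.n_segments == n_clean

    def test_short_recording_rejected(self):
        rec = EEGRecording(data=np.zeros((19, 5 * 125)), fs=125.0)
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(rec)

    def test_variance_shrinks_with_more_segments(self):
        # Welch consistency: doubling the data (hence segments) lowers the
        # bin-wise variance of the estimate for a stationary signal
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fs = 125.0
            x_long = rng.normal(0, 20, size=(19, int(fs * 60)))
            rec_s = EEGRecording(data=x_long[:, : int(fs * 30)], fs=fs)
            rec_l = EEGRecording(data=x_long, fs=fs)
            var_s = welch_psd(rec_s).power.var()
            var_l = welch_psd(rec_l).power.var()
            ratios.append(var_l / var_s)
        assert np.median(ratios) < 1.0


class TestAlphaPeak:
    def test_symmetric_gaussian_on_flat_background(self, gaussian_spectrum):
        spec = gaussian_spectrum(center=10.2, amp=2.0, sigma=0.5, baseline=0.1)
        pk = alpha_peak(spec, "x")
        assert pk.center_freq == pytest.approx(10.2, abs=0.05)
        assert not pk.low_prominence

    def test_two_bumps_argmax_wins(self):
        # grid argmax oracle: the taller 9.0 Hz bump must win
        p = (2.0 * np.exp(-((FREQ_GRID - 9.0) ** 2) / (2 * 0.4 ** 2))
             + 1.5 * np.exp(-((FREQ_GRID - 11.5) ** 2) / (2 * 0.4 ** 2)))
        oracle = FREQ_GRID[(FREQ_GRID >= 8) & (FREQ_GRID <= 13)][
            np.argmax(p[(FREQ_GRID >= 8) & (FREQ_GRID <= 13)])]
        assert oracle == pytest.approx(9.0)
        spec = PowerSpectrum(freqs=FREQ_GRID.copy(), power=p[None, :],
                             leads=("x",), fs=250.0)
        assert alpha_peak(spec, "x").center_freq == pytest.approx(9.0, abs=0.05)

    def test_ties_break_toward_lower_frequency(self):
        p = np.zeros_like(FREQ_GRID)
        p[(FREQ_GRID > 8.95) & (FREQ_GRID < 9.05)] = 2.0
        p[(FREQ_GRID > 10.95) & (FREQ_GRID < 11.05)] = 2.0
        spec = PowerSpectrum(freqs=FREQ_GRID.copy(), power=p[None, :],
                             leads=("x",), fs=250.0)
        assert alpha_peak(spec, "x").center_freq == pytest.approx(9.0, abs=0.05)

    def test_monotone_band_flagged_low_prominence(self):
        p = 1.0 / FREQ_GRID  # strictly decreasing, no alpha peak
        spec = PowerSpectrum(freqs=FREQ_GRID.copy(), power=p[None, :],
                             leads=("x",), fs=250.0)
        pk = alpha_peak(spec, "x")
        assert pk.low_prominence
        assert pk.center_freq == pytest.approx(8.0, abs=0.05)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           center=st.floats(min_value=8.5, max_value=12.5),
           sigma=st.floats(min_value=0.3, max_value=1.2))
    def test_scale_invariance(self, scale, center, sigma):
        p = 0.5 + 2.0 * np.exp(-((FREQ_GRID - center) ** 2) / (2 * sigma ** 2))
        a = PowerSpectrum(freqs=FREQ_GRID.copy(), power=p[None, :],
                          leads=("x",), fs=250.0)
        b = PowerSpectrum(freqs=FREQ_GRID.copy(), power=(scale * p)[None, :],
                          leads=("x",), fs=250.0)
        pa, pb = alpha_peak(a, "x"), alpha_peak(b, "x")
        assert pa.center_freq == pytest.approx(pb.center_freq, abs=1e-9)
        wa, wb = alpha_fwhm(a, "x", pa), alpha_fwhm(b, "x", pb)
        if np.isnan(wa) or np.isnan(wb):  # band-clipped for both or neither
            assert np.isnan(wa) and np.isnan(wb)
        else:
            assert wa == pytest.approx(wb, abs=1e-9)

    @pytest.mark.parametrize("center", [9.0, 9.55, 10.2, 11.87])
    def test_peak_localization_error_bounds(self, gaussian_spectrum, center):
        spec = gaussian_spectrum(center=center, amp=2.0, sigma=0.6, baseline=0.2)
        tol = 0.05 if round(center * 10) == center * 10 else 0.1
        assert alpha_peak(spec, "x").center_freq == pytest.approx(center, abs=tol)


class TestFWHM:
    def test_gaussian_closed_form(self, gaussian_spectrum):
        spec = gaussian_spectrum(center=10.0, amp=2.0, sigma=0.5, baseline=0.0)
        w = alpha_fwhm(spec, "x")
        assert w == pytest.approx(FWHM_FACTOR * 0.5, rel=0.01)

    def test_asymmetric_peak_matches_dense_grid_oracle(self):
        # piecewise-linear peak: exact crossings are hand-computable and a
        # 0.001 Hz brute-force grid provides the independent oracle
        def shape(f):
            f = np.asarray(f, dtype=float)
            left = np.clip((f - 8.5) / (10.0 - 8.5), 0, 1)
            right = np.clip((11.0 - f) / (11.0 - 10.0), 0, 1)
            return 2.0 * np.minimum(left, right)

        dense = np.arange(8.0, 13.0, 0.001)
        yd = shape(dense)
        above = dense[yd >= 1.0]  # half max = 1.0
        oracle = above[-1] - above[0]
        assert oracle == pytest.approx((10.5 - 9.25), abs=0.005)

        spec = PowerSpectrum(freqs=FREQ_GRID.copy(),
                             power=shape(FREQ_GRID)[None, :],
                             leads=("x",), fs=250.0)
        w = alpha_fwhm(spec, "x", alpha_peak(spec, "x"))
        assert w == pytest.approx(oracle, abs=0.02)

    def test_band_clipped_peak_is_undefined(self, gaussian_spectrum):
        spec = gaussian_spectrum(center=8.2, amp=2.0, sigma=1.0)
        w = alpha_fwhm(spec, "x", alpha_peak(spec, "x"))
        assert np.isnan(w)

    def test_baseline_subtraction_recovers_width_on_sloped_background(self):
        from prtms.aperiodic import fit_aperiodic
        aper = 20.0 * FREQ_GRID ** -0.7
        p = aper + 2.0 * aper[80] * np.exp(-((FREQ_GRID - 9.6) ** 2) / (2 * 1.0))
        spec = PowerSpectrum(freqs=FREQ_GRID.copy(), power=p[None, :],
                             leads=("x",), fs=250.0)
        fit = fit_aperiodic(spec)
        w = alpha_fwhm(spec, "x", alpha_peak(spec, "x"), baseline=fit)
        assert w == pytest.approx(FWHM_FACTOR * 1.0, rel=0.03)


class TestRegionAverage:
    def test_idempotent_on_identical_channels(self, white_recording):
        spec = welch_psd(white_recording(seed=5))
        spec.power[:] = spec.power[0]
        avg = region_average_spectrum(spec, ["O1", "O2", "T5"])
        np.testing.assert_allclose(avg.power[0], spec.power[0])

    def test_linearity(self):
        p = np.ones_like(FREQ_GRID)
        spec = PowerSpectrum(freqs=FREQ_GRID.copy(),
                             power=np.vstack([p, 3 * p]),
                             leads=("a", "b"), fs=250.0)
        avg = region_average_spectrum(spec, ["a", "b"])
        np.testing.assert_allclose(avg.power[0], 2 * p)

    def test_matches_manual_mean_of_frontal_rows(self, white_recording, montage):
        from prtms.eeg_io import region_leads
        spec = welch_psd(white_recording(seed=6))
        frontal = region_leads(montage, "frontal")
        avg = region_average_spectrum(spec, frontal)
        manual = np.mean([spec.lead_power(l) for l in frontal], axis=0)
        np.testing.assert_allclose(avg.power[0], manual)

    def test_empty_lead_list_rejected(self, white_recording):
        spec = welch_psd(white_recording())
        with pytest.raises(ValueError, match="nonempty"):
            region_average_spectrum(spec, [])


class TestBandMeanAmplitude:
    def test_flat_spectrum_returns_constant(self):
        p = np.full((19, 181), 3.5)
        spec = PowerSpectrum(freqs=FREQ_GRID.copy(), power=p,
                             leads=standard_montage().leads, fs=250.0)
        mean, samples = band_mean_amplitude(spec)
        assert mean == pytest.approx(3.5)

    def test_alpha_band_sample_count_is_19x51(self, white_recording):
        spec = welch_psd(white_recording())
        _, samples = band_mean_amplitude(spec, band=ALPHA_BAND)
        assert samples.size == 19 * 51

    def test_band_outside_spectrum_rejected(self, white_recording):
        spec = welch_psd(white_recording())
        with pytest.raises(ValueError, match="outside"):
            band_mean_amplitude(spec, band=(1.0, 13.0))
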