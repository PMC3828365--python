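"""Spectrogram scaling, state spectra, band power and β-peak detection."""

import numpy as np
import pytest

import betasleep as bs
from betasleep.errors import EmptyStateError, InputSizeError, RangeError
from betasleep.io import Hypnogram, REM, SWS
from betasleep.spectral import (
    Spectrogram,
    Spectrum,
    band_power,
    compute_spectrogram,
    detect_beta_peak,
    peak_in_band,
    state_spectrum,
)

MIN_REM_WINDOWS = 30


def brute_force_spectrogram(trace, fs, window_len_s=4.0, hop_s=2.0):
    """Independent oracle: explicit DFT matrix, windowed segments, no FFT."""
    trace = np.asarray(trace, dtype=float)
    nper = int(round(window_len_s * fs))
    hop = int(round(hop_s * fs))
    n_windows = (len(trace) - nper) // hop + 1
    k = np.arange(nper)
    sigma = nper / 6.0
    w = np.exp(-0.5 * ((k - (nper - 1) / 2.0) / sigma) ** 2)
    n_freq = nper // 2 + 1
    dft = np.exp(-2j * np.pi * np.outer(np.arange(n_freq), k) / nper)
    out = np.empty((n_windows, n_freq))
    for i in range(n_windows):
        seg = trace[i * hop : i * hop + nper] * w
        X = dft @ seg
        p = np.abs(X) ** 2 / np.sum(w**2)
        p[1:] *= 2.0
        if nper % 2 == 0:
            p[-1] /= 2.0
        out[i] = p
    return out


class TestSpectrogram:
    def test_zero_trace_shape_and_power(self):
        spg = compute_spectrogram(np.zeros(60 * 500), 500.0)
        assert spg.n_windows == 29  # floor((60 - 4) / 2) + 1
        assert np.all(spg.power == 0.0)
        assert spg.df == 0.25
        assert spg.freqs[0] == 0.0 and spg.freqs[-1] == 250.0

    def test_pure_tone_peaks_in_every_window(self):
        fs = 500.0
        t = np.arange(60 * fs) / fs
        spg = compute_spectrogram(np.sin(2 * np.pi * 25.0 * t), fs)
        argmax = spg.freqs[np.argmax(spg.power, axis=1)]
        assert np.all(argmax == 25.0)

    def test_single_window_boundary(self):
        spg = compute_spectrogram(np.ones(4 * 500), 500.0)
        assert spg.n_windows == 1
        with pytest.raises(InputSizeError):
            compute_spectrogram(np.ones(4 * 500 - 1), 500.0)

    def test_matches_brute_force_dft(self, rng):
        fs = 500.0
        trace = rng.standard_normal(int(10 * fs))
        spg = compute_spectrogram(trace, fs)
        oracle = brute_force_spectrogram(trace, fs)
        err = np.abs(spg.power - oracle) / np.maximum(oracle, oracle.max() * 1e-12)
        assert err.max() < 1e-8


class TestStateSpectrum:
    def test_constant_spectrogram_normalizes_to_unit_sum(self, rng):
        col = rng.uniform(0.1, 1.0, size=401)
        freqs = np.arange(401) * 0.25
        spg = Spectrogram(np.tile(col, (20, 1)), freqs, 2.0 + 2.0 * np.arange(20))
        hyp = Hypnogram(np.full(21, SWS))
        spec = state_spectrum(spg, hyp, SWS)
        sel = (freqs >= 0.5) & (freqs <= 100)
        assert np.isclose(spec.values[sel].sum(), 1.0, atol=1e-9)
        expected = col / col[sel].sum()
        np.testing.assert_allclose(spec.values, expected)

    def test_states_separate_their_tones(self):
        # first half SWS with a 10 Hz tone, second half REM with 30 Hz
        fs = 500.0
        t = np.arange(120 * fs) / fs
        trace = np.where(t < 60, np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 30 * t))
        spg = compute_spectrogram(trace, fs)
        hyp = Hypnogram(np.array([SWS] * 30 + [REM] * 30))
        f_sws, _ = peak_in_band(state_spectrum(spg, hyp, SWS), 1, 55)
        f_rem, _ = peak_in_band(state_spectrum(spg, hyp, REM), 1, 55)
        assert f_sws == 10.0 and f_rem == 30.0

    def test_empty_state_raises(self):
        spg = compute_spectrogram(np.ones(10 * 500), 500.0)
        hyp = Hypnogram(np.full(5, SWS))
        with pytest.raises(EmptyStateError):
            state_spectrum(spg, hyp, REM)


def _flat_spectrum():
    freqs = np.arange(0, 125.25, 0.25)
    values = np.ones_like(freqs)
    sel = (freqs >= 0.5) & (freqs <= 100)
    return Spectrum(values / values[sel].sum(), freqs, SWS)


class TestBandPower:
    def test_flat_spectrum_band_share_is_bin_ratio(self):
        spec = _flat_spectrum()
        n_band = np.sum((spec.freqs >= 15) & (spec.freqs <= 40))
        n_norm = np.sum((spec.freqs >= 0.5) & (spec.freqs <= 100))
        assert np.isclose(band_power(spec, 15, 40), n_band / n_norm)

    def test_concentrated_mass(self):
        freqs = np.arange(0, 125.25, 0.25)
        values = np.zeros_like(freqs)
        values[freqs == 25.0] = 1.0
        spec = Spectrum(values, freqs, REM)
        assert band_power(spec, 15, 40) == 1.0

    def test_normalization_identity(self, wt_runs):
        for run in wt_runs[:3]:
            for by_state in run.result.spectra.values():
                for spec in by_state.values():
                    assert np.isclose(band_power(spec, 0.5, 100), 1.0, atol=1e-9)

    def test_band_outside_axis_raises(self):
        with pytest.raises(RangeError):
            band_power(_flat_spectrum(), 130, 150)


class TestPeakInBand:
    def test_single_tone(self):
        freqs = np.arange(0, 125.25, 0.25)
        values = np.exp(-0.5 * ((freqs - 7.5) / 0.3) ** 2)
        assert peak_in_band(Spectrum(values, freqs, REM), 4, 9)[0] == 7.5

    def test_larger_of_two_tones_wins(self):
        freqs = np.arange(0, 125.25, 0.25)
        values = np.zeros_like(freqs)
        values[freqs == 20.0] = 2.0
        values[freqs == 30.0] = 1.0
        assert peak_in_band(Spectrum(values, freqs, REM), 15, 40)[0] == 20.0

    def test_tie_breaks_to_lowest_frequency(self):
        freqs = np.arange(0, 125.25, 0.25)
        values = np.zeros_like(freqs)
        values[freqs == 20.0] = 1.0
        values[freqs == 30.0] = 1.0
        assert peak_in_band(Spectrum(values, freqs, REM), 15, 40)[0] == 20.0


def _one_over_f2(bump_freq=None, bump_gain=0.0):
    freqs = np.arange(0.25, 125.25, 0.25)
    values = freqs**-2.0
    if bump_freq is not None:
        bg_at_bump = float(np.interp(bump_freq, freqs, values))
        values = values + bump_gain * bg_at_bump * np.exp(
            -0.5 * ((freqs - bump_freq) / 1.0) ** 2
        )
    sel = (freqs >= 0.5) & (freqs <= 100)
    return Spectrum(values / values[sel].sum(), freqs, REM)


class TestBetaPeakDetection:
    def test_pure_power_law_has_no_peak(self):
        peak = detect_beta_peak(_one_over_f2())
        assert not peak.present

    def test_five_fold_bump_at_25_is_detected(self):
        peak = detect_beta_peak(_one_over_f2(25.0, 4.0))  # peak 5x background
        assert peak.present
        assert abs(peak.peak_freq - 25.0) <= 0.25
        assert peak.prominence > 2.0

    def test_sub_threshold_bump_rejected(self):
        peak = detect_beta_peak(_one_over_f2(25.0, 0.5))  # peak 1.5x background
        assert not peak.present
        assert 1.0 < peak.prominence < 2.0

    def test_detection_separates_genotypes(self, wt_runs, r61_runs):
        # on well-sampled REM spectra the detector must be essentially
        # error-free in both directions across seeds
        wt = [
            r.result.beta_by_state[REM].present
            for r in wt_runs
            if r.n_rem >= MIN_REM_WINDOWS
        ]
        tg = [
            r.result.beta_by_state[REM].present
            for r in r61_runs
            if r.n_rem >= MIN_REM_WINDOWS
        ]
        assert len(wt) >= 5 and len(tg) >= 5
        assert np.mean(wt) <= 0.05
        assert np.mean(tg) >= 0.95

    def test_peak_frequency_invariant_when_present(self, r61_runs):
        for run in r61_runs:
            for peak in run.result.beta_by_state.values():
                if peak.present:
                    assert 15.0 <= peak.peak_freq <= 40.0
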