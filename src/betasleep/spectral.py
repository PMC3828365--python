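"""Spectrograms, state-conditioned normalized spectra and β-peak detection.

The workhorse estimate is a short-time periodogram on 4-s Gaussian-tapered
windows with 50% overlap, giving 0.25 Hz frequency resolution.  Power is
scaled so that the one-sided spectrum of a window sums to the taper-weighted
mean square of the signal (Parseval for the tapered window):

    P[k] = c_k |X[k]|^2 / sum(w^2),   c_k = 2 except DC and Nyquist,

with X the DFT of the tapered segment.  Absolute scale cancels downstream:
state spectra are normalized to unit sum over a wide reference band, which
makes every derived quantity invariant to gain differences between probes
and animals.

β-peak presence is decided against the aperiodic 1/f background: a straight
line is fitted to log power vs log frequency outside the β band, and a peak
is declared when a local maximum inside the band rises at least
``prominence_threshold``-fold above the fitted background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import gaussian as _gaussian_window

from .errors import EmptyStateError, InputSizeError, RangeError
from .io import Hypnogram

# Frequency bands used throughout (Hz).  The β *summation* band is wide
# (15–40); the narrower 20–35 band is the descriptive/display band for the
# rhythm itself.
BETA_SUM_BAND = (15.0, 40.0)
BETA_DISPLAY_BAND = (20.0, 35.0)
THETA_SUM_BAND = (4.0, 8.0)
THETA_PEAK_BAND = (4.0, 9.0)
DELTA_COMOD_BAND = (2.0, 5.0)
NORMALIZATION_BAND = (0.5, 100.0)


@dataclass
class Spectrogram:
    """Time–frequency power matrix, one row per analysis window."""

    power: np.ndarray  # [n_windows, n_freq_bins], one-sided
    freqs: np.ndarray  # Hz
    window_times: np.ndarray  # window centre times, s
    window_len_s: float = 4.0
    hop_s: float = 2.0

    @property
    def n_windows(self) -> int:
        return self.power.shape[0]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class Spectrum:
    """State-averaged power spectrum, normalized to unit sum over a band."""

    values: np.ndarray
    freqs: np.ndarray
    state: str = ""
    normalization_range: tuple[float, float] = NORMALIZATION_BAND


@dataclass
class BetaPeak:
    """Result of β-peak detection over the fitted 1/f background."""

    present: bool
    peak_freq: float
    peak_power: float
    prominence: float
    band: tuple[float, float] = BETA_SUM_BAND


def band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean mask of bins with lo <= f <= hi (inclusive edges)."""
    if not lo < hi:
        raise RangeError(f"empty band ({lo}, {hi})")
    freqs = np.asarray(freqs)
    if lo > freqs[-1] or hi < freqs[0]:
        raise RangeError(f"band ({lo}, {hi}) outside frequency axis")
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def compute_spectrogram(
    trace, fs: float, window_len_s: float = 4.0, hop_s: float = 2.0
) -> Spectrogram:
    """Short-time periodogram with a Gaussian taper (σ = window length / 6).

    Windows start at 0 and advance by ``hop_s``; the number of windows is
    ``floor((duration − window_len) / hop) + 1``.
    """
    trace = np.asarray(trace, dtype=float)
    nper = int(round(window_len_s * fs))
    hop = int(round(hop_s * fs))
    if trace.ndim != 1 or len(trace) < nper:
        raise InputSizeError(f"trace must hold at least one {window_len_s}-s window")
    n_windows = (len(trace) - nper) // hop + 1
    w = _gaussian_window(nper, std=nper / 6.0, sym=True)
    segs = np.lib.stride_tricks.sliding_window_view(trace, nper)[:: hop][:n_windows]
    X = np.fft.rfft(segs * w, axis=1)
    power = (X.real**2 + X.imag**2) / np.sum(w**2)
    power[:, 1:] *= 2.0
    if nper % 2 == 0:  # Nyquist bin is not doubled
        power[:, -1] *= 0.5
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    times = window_len_s / 2.0 + hop_s * np.arange(n_windows)
    return Spectrogram(power, freqs, times, window_len_s, hop_s)


def windows_in_state(spg: Spectrogram, hyp: Hypnogram, states) -> np.ndarray:
    """Boolean mask over windows whose *centre time* falls in `states` epochs.

    A window straddling a state transition inherits the state at its centre.
    """
    if isinstance(states, str):
        states = (states,)
    idx = hyp.epoch_index(spg.window_times)
    mask = (idx >= 0) & (idx < hyp.n_epochs)
    mask[mask] = np.isin(hyp.labels[idx[mask]], list(states))
    return mask


def state_spectrum(
    spg: Spectrogram,
    hyp: Hypnogram,
    state,
    normalization_range: tuple[float, float] = NORMALIZATION_BAND,
) -> Spectrum:
    """Mean spectrum over windows in `state`, normalized to unit band sum."""
    mask = windows_in_state(spg, hyp, state)
    if not mask.any():
        raise EmptyStateError(f"no spectrogram window in state {state}")
    mean = spg.power[mask].mean(axis=0)
    norm = mean[band_mask(spg.freqs, *normalization_range)].sum()
    if norm <= 0:
        raise EmptyStateError("zero power in normalization range")
    label = state if isinstance(state, str) else "+".join(state)
    return Spectrum(mean / norm, spg.freqs.copy(), label, tuple(normalization_range))


def band_power(spec: Spectrum, lo: float, hi: float) -> float:
    """Summed normalized power over lo <= f <= hi (inclusive edges)."""
    return float(spec.values[band_mask(spec.freqs, lo, hi)].sum())


def peak_in_band(spec: Spectrum, lo: float, hi: float) -> tuple[float, float]:
    """(frequency, power) of the maximum bin in the band; ties -> lowest f."""
    mask = band_mask(spec.freqs, lo, hi)
    vals = spec.values[mask]
    f = spec.freqs[mask]
    i = int(np.argmax(vals))  # argmax returns the first (lowest-f) maximum
    return float(f[i]), float(vals[i])


def fit_aperiodic_background(
    spec: Spectrum,
    fit_range: tuple[float, float] = (10.0, 55.0),
    exclude: tuple[float, float] = BETA_SUM_BAND,
) -> np.ndarray:
    """Power-law background: straight-line fit of log P vs log f.

    Fitted over `fit_range` with the (presumed oscillatory) `exclude` band
    left out; evaluated at every frequency bin (NaN at f = 0).
    """
    mask = band_mask(spec.freqs, *fit_range) & ~band_mask(spec.freqs, *exclude)
    f = spec.freqs[mask]
    p = np.clip(spec.values[mask], 1e-300, None)
    slope, intercept = np.polyfit(np.log(f), np.log(p), 1)
    with np.errstate(divide="ignore"):
        logf = np.log(spec.freqs, where=spec.freqs > 0, out=np.full_like(spec.freqs, np.nan))
    return np.exp(intercept + slope * logf)


def detect_beta_peak(
    spec: Spectrum,
    band: tuple[float, float] = BETA_SUM_BAND,
    fit_range: tuple[float, float] = (10.0, 55.0),
    prominence_threshold: float = 2.0,
) -> BetaPeak:
    """Detect a β peak riding on the 1/f background.

    A peak is *present* when some local maximum of the spectrum inside
    `band` exceeds ``prominence_threshold`` times the fitted background.
    Always returns a :class:`BetaPeak`; when nothing qualifies, the most
    prominent in-band bin is still reported with ``present=False``.
    """
    if spec.freqs[0] > fit_range[0] or spec.freqs[-1] < fit_range[1]:
        raise RangeError(f"spectrum must cover {fit_range} Hz")
    background = fit_aperiodic_background(spec, fit_range, exclude=band)
    in_band = np.flatnonzero(band_mask(spec.freqs, *band))
    with np.errstate(invalid="ignore"):
        ratio = spec.values / background
    v = spec.values
    local_max = np.zeros(len(v), dtype=bool)
    local_max[1:-1] = (v[1:-1] >= v[:-2]) & (v[1:-1] >= v[2:])
    candidates = in_band[local_max[in_band]]
    if candidates.size:
        best = candidates[int(np.argmax(ratio[candidates]))]
        prominence = float(ratio[best])
        present = prominence >= prominence_threshold
    else:
        best = in_band[int(np.argmax(ratio[in_band]))]
        prominence = float(ratio[best])
        present = False
    return BetaPeak(
        present=present,
        peak_freq=float(spec.freqs[best]),
        peak_power=float(spec.values[best]),
        prominence=prominence,
        band=tuple(band),
    )


def spectrum_to_frame(spec: Spectrum):
    """Spectrum as a two-column table (freq_hz, power) for CSV export."""
    import pandas as pd

    return pd.DataFrame({"freq_hz": spec.freqs, "power": spec.values})
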