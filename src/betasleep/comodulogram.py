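"""Cross-channel power–power comodulograms.

For two simultaneously recorded channels, each frequency bin of each
spectrogram yields a power time series over analysis windows.  Restricting
to the windows scored in a given vigilance state, the comodulogram is the
matrix of Pearson correlation coefficients between every frequency pair
(f_A on channel A, f_B on channel B), with two-sided p-values from the
t transform.  Correlations are computed on log power by default, which
tames the heavy right tail of spectral power and makes r invariant to any
positive rescaling of either channel.

p-values are reported raw (no multiple-comparison correction across bin
pairs); treat the matrix as descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import AlignmentError, InsufficientDataError, RangeError
from .io import Hypnogram, WAKE_STATES
from .spectral import Spectrogram, band_mask, windows_in_state

MIN_WINDOWS = 10


@dataclass
class Comodulogram:
    """Pearson r (and p) between per-frequency power series of two channels."""

    r: np.ndarray  # [n_freq_A, n_freq_B]
    p: np.ndarray
    freqs_a: np.ndarray
    freqs_b: np.ndarray
    state: str
    n_windows: int


def compute_comodulogram(
    spg_a: Spectrogram,
    spg_b: Spectrogram,
    hyp: Hypnogram,
    state=WAKE_STATES,
    freq_range: tuple[float, float] = (1.0, 55.0),
    log_power: bool = True,
) -> Comodulogram:
    """Comodulogram between channels A (rows) and B (columns) in `state`.

    `state` may be one label or a sequence (default: the combined waking
    mask, active + quiet wake).
    """
    if spg_a.n_windows != spg_b.n_windows or not np.allclose(
        spg_a.window_times, spg_b.window_times
    ):
        raise AlignmentError("spectrograms are not on the same window grid")
    mask = windows_in_state(spg_a, hyp, state)
    n = int(mask.sum())
    if n < MIN_WINDOWS:
        raise InsufficientDataError(f"only {n} windows in state (need >= {MIN_WINDOWS})")

    sel_a = band_mask(spg_a.freqs, *freq_range)
    sel_b = band_mask(spg_b.freqs, *freq_range)
    A = spg_a.power[np.ix_(mask, sel_a)]
    B = spg_b.power[np.ix_(mask, sel_b)]
    if log_power:
        tiny = 1e-300
        A = np.log10(A + tiny)
        B = np.log10(B + tiny)

    def zscore(M):
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (M - mu) / sd

    Za, Zb = zscore(A), zscore(B)
    r = (Za.T @ Zb) / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 2)
    label = state if isinstance(state, str) else "+".join(state)
    return Comodulogram(r, p, spg_a.freqs[sel_a], spg_b.freqs[sel_b], label, n)


def band_extrema(
    com: Comodulogram,
    band_a: tuple[float, float],
    band_b: tuple[float, float],
    mode: str = "max",
) -> tuple[float, float, float]:
    """Location (f_A, f_B) and value of the extremal r in a band pair.

    Ties break toward the lowest (f_A, f_B) in row-major order.
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    ma = band_mask(com.freqs_a, *band_a)
    mb = band_mask(com.freqs_b, *band_b)
    if not ma.any() or not mb.any():
        raise RangeError("empty comodulogram sub-matrix")
    sub = com.r[np.ix_(ma, mb)]
    flat = int(np.argmax(sub) if mode == "max" else np.argmin(sub))
    i, j = np.unravel_index(flat, sub.shape)
    return (
        float(com.freqs_a[ma][i]),
        float(com.freqs_b[mb][j]),
        float(sub[i, j]),
    )


def band_mean(com: Comodulogram, band_a, band_b) -> float:
    """Mean r over a band pair (descriptive summary)."""
    ma = band_mask(com.freqs_a, *band_a)
    mb = band_mask(com.freqs_b, *band_b)
    if not ma.any() or not mb.any():
        raise RangeError("empty comodulogram sub-matrix")
    return float(com.r[np.ix_(ma, mb)].mean())


def comodulogram_to_frame(com: Comodulogram):
    """r matrix as a DataFrame (rows f_A, columns f_B) for CSV export."""
    import pandas as pd

    return pd.DataFrame(com.r, index=com.freqs_a, columns=com.freqs_b)
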