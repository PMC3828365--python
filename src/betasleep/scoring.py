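"""Automated vigilance-state scoring.

Epochs are classified by a fixed decision cascade over three feature
streams — locomotion speed, neck-EMG RMS and hippocampal spectral shape —
mirroring the criteria under which such recordings are scored by eye:

1. moving (speed above threshold)                        -> active wake
2. atonic EMG and θ dominating δ                         -> REM
3. atonic EMG and a large 2–8 Hz share of total power    -> SWS
4. otherwise                                             -> quiet wake

followed by a majority filter over a short, odd number of epochs.  Each
scored epoch corresponds to one spectrogram window; the θ/δ ratio uses a
non-overlapping δ band (default 2–4 Hz) so that a strong θ rhythm can
actually dominate the ratio.

The thresholds are operational choices (the physiology fixes only their
ordering); all are exposed in :class:`ScoringThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError
from .io import ACTIVE_WAKE, QUIET_WAKE, REM, STATES, SWS, Hypnogram, SessionRecording, compute_movement
from .spectral import Spectrogram, band_mask


@dataclass
class ScoringThresholds:
    """Decision thresholds for the scoring cascade."""

    speed_active: float = 2.0  # cm/s
    emg_low: float = 14.0  # RMS µV: at or below -> candidate sleep epoch
    emg_light: float = 25.0  # RMS µV: nominal quiet-wake muscle tone ceiling
    theta_ratio_rem: float = 1.5  # θ/δ power ratio for REM
    broadband_sws: float = 0.5  # 2–8 Hz fraction of total power for SWS
    smoothing_epochs: int = 3  # odd majority-filter width
    theta_band: tuple = (4.0, 9.0)
    delta_band: tuple = (2.0, 4.0)
    sws_band: tuple = (2.0, 8.0)
    total_band: tuple = (0.5, 100.0)

    def __post_init__(self) -> None:
        if not self.emg_low < self.emg_light:
            raise ConfigError("emg_low must be below emg_light")
        if min(self.speed_active, self.emg_low, self.theta_ratio_rem, self.broadband_sws) <= 0:
            raise ConfigError("thresholds must be positive")
        if self.smoothing_epochs < 1 or self.smoothing_epochs % 2 == 0:
            raise ConfigError("smoothing_epochs must be a positive odd integer")


def epoch_emg_rms(
    emg, fs: float, n_epochs: int, epoch_len_s: float = 2.0, subwin_s: float = 0.5
) -> np.ndarray:
    """Per-epoch EMG tone: RMS in 0.5-s sub-windows, averaged per epoch."""
    emg = np.asarray(emg, dtype=float)
    sub = int(round(subwin_s * fs))
    per_epoch = int(round(epoch_len_s / subwin_s))
    need = n_epochs * per_epoch * sub
    if len(emg) < need:
        raise AlignmentError("EMG trace shorter than the epoch grid")
    rms = np.sqrt(np.mean(emg[:need].reshape(-1, sub) ** 2, axis=1))
    return rms.reshape(n_epochs, per_epoch).mean(axis=1)


def epoch_speed(speed, fs_position: float, n_epochs: int, epoch_len_s: float = 2.0) -> np.ndarray:
    """Mean smoothed speed per epoch."""
    speed = np.asarray(speed, dtype=float)
    per = int(round(epoch_len_s * fs_position))
    need = n_epochs * per
    if len(speed) < need:
        raise AlignmentError("speed trace shorter than the epoch grid")
    return speed[:need].reshape(n_epochs, per).mean(axis=1)


def _majority_filter(labels: np.ndarray, width: int) -> np.ndarray:
    """Sliding majority vote; the window shrinks at the edges and ties keep
    the original centre label, so no state absent from a window is created."""
    if width <= 1:
        return labels.copy()
    half = width // 2
    out = labels.copy()
    n = len(labels)
    for i in range(n):
        win = labels[max(0, i - half) : min(n, i + half + 1)]
        states, counts = np.unique(win, return_counts=True)
        best = counts.max()
        winners = states[counts == best]
        if len(winners) == 1:
            out[i] = winners[0]
    return out


def score_states(
    spg_hippocampus: Spectrogram,
    emg_rms: np.ndarray,
    speed: np.ndarray,
    thr: ScoringThresholds | None = None,
) -> Hypnogram:
    """Classify each spectrogram window into a vigilance state.

    Inputs must be epoch-aligned: one EMG-RMS value and one mean speed per
    spectrogram window.  The returned hypnogram has one epoch per window,
    ``epoch_len_s`` equal to the hop and epochs centred on window centres.
    """
    thr = thr or ScoringThresholds()
    n = spg_hippocampus.n_windows
    emg_rms = np.asarray(emg_rms, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if len(emg_rms) != n or len(speed) != n:
        raise AlignmentError(
            f"epoch features must have length {n}, got {len(emg_rms)} and {len(speed)}"
        )
    freqs = spg_hippocampus.freqs
    p = spg_hippocampus.power
    p_theta = p[:, band_mask(freqs, *thr.theta_band)].sum(axis=1)
    p_delta = p[:, band_mask(freqs, *thr.delta_band)].sum(axis=1)
    p_sws = p[:, band_mask(freqs, *thr.sws_band)].sum(axis=1)
    p_total = p[:, band_mask(freqs, *thr.total_band)].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_ratio = np.where(p_delta > 0, p_theta / p_delta, np.inf)
        sws_frac = np.where(p_total > 0, p_sws / p_total, 0.0)

    labels = np.full(n, QUIET_WAKE, dtype="U11")
    sleep_tone = emg_rms <= thr.emg_low
    labels[sleep_tone & (sws_frac >= thr.broadband_sws)] = SWS
    labels[sleep_tone & (theta_ratio >= thr.theta_ratio_rem)] = REM
    labels[speed > thr.speed_active] = ACTIVE_WAKE
    labels = _majority_filter(labels, thr.smoothing_epochs)

    start = float(spg_hippocampus.window_times[0] - spg_hippocampus.hop_s / 2.0)
    return Hypnogram(labels, spg_hippocampus.hop_s, start)


def session_epoch_features(
    rec: SessionRecording, spg_hippocampus: Spectrogram, thr: ScoringThresholds | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(EMG RMS, mean speed) per scored epoch for a session.

    Features are computed on the 2-s epoch each window labels (the interval
    centred on the window centre), not on the full 4-s window.
    """
    n = spg_hippocampus.n_windows
    hop = spg_hippocampus.hop_s
    start = spg_hippocampus.window_times[0] - hop / 2.0
    # shift traces so epoch 0 starts at `start`
    i0_sig = int(round(start * rec.fs_signal))
    emg = rec.channels["emg"][i0_sig:]
    emg_rms = epoch_emg_rms(emg, rec.fs_signal, n, epoch_len_s=hop)
    speed_trace = compute_movement(rec.position, rec.fs_position)
    i0_pos = int(round(start * rec.fs_position))
    speed = epoch_speed(speed_trace[i0_pos:], rec.fs_position, n, epoch_len_s=hop)
    return emg_rms, speed


def scoring_accuracy(predicted: Hypnogram, truth: Hypnogram) -> dict:
    """Confusion matrix and agreement fractions of two aligned hypnograms."""
    same_grid = (
        predicted.n_epochs == truth.n_epochs
        and np.isclose(predicted.epoch_len_s, truth.epoch_len_s)
        and np.isclose(predicted.start_time_s, truth.start_time_s)
    )
    if not same_grid:
        raise AlignmentError("hypnograms are not on the same epoch grid")
    confusion = pd.DataFrame(0, index=list(STATES), columns=list(STATES), dtype=int)
    for t, p in zip(truth.labels, predicted.labels):
        confusion.loc[t, p] += 1
    overall = float(np.mean(predicted.labels == truth.labels))
    recall = {}
    for st in STATES:
        n_true = int(confusion.loc[st].sum())
        recall[st] = float(confusion.loc[st, st] / n_true) if n_true else np.nan
    return {"overall": overall, "recall": recall, "confusion": confusion}
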