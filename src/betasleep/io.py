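"""Domain containers and standard-format I/O.

A recording session couples three electrophysiology channels (frontal EEG,
hippocampal LFP, neck EMG, all in microvolts) with a 2-D position track in
centimetres.  Vigilance states live in a :class:`Hypnogram`: a run of labels
over the four-state alphabet on a uniform epoch grid, each epoch the
half-open interval ``[t, t + epoch_len_s)``.

Signals travel as EDF files; hypnograms, clasping observations and session
manifests as small CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import edf
from .errors import AlignmentError, ChannelError, FormatError, InputSizeError

ACTIVE_WAKE = "ACTIVE_WAKE"
QUIET_WAKE = "QUIET_WAKE"
SWS = "SWS"
REM = "REM"
STATES = (ACTIVE_WAKE, QUIET_WAKE, SWS, REM)
WAKE_STATES = (ACTIVE_WAKE, QUIET_WAKE)

GENOTYPES = ("R6/1", "WT")

#: channel names every session must provide
REQUIRED_CHANNELS = ("frontal_eeg", "hippocampus_lfp", "emg")

_POSITION_LABELS = ("pos_x", "pos_y")


@dataclass
class SessionRecording:
    """One recording session of one mouse.

    ``channels`` maps channel name -> voltage trace in µV at ``fs_signal``;
    ``position`` is an ``(n, 2)`` array of (x, y) in cm at ``fs_position``.
    """

    mouse_id: str
    genotype: str
    age_weeks: float
    channels: dict[str, np.ndarray]
    fs_signal: float = 2000.0
    position: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    fs_position: float = 50.0
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise FormatError(f"unknown genotype {self.genotype!r}")
        if not self.age_weeks > 0:
            raise FormatError("age_weeks must be positive")
        if not self.duration_s > 0:
            raise FormatError("duration_s must be positive")
        if self.fs_position > self.fs_signal:
            raise FormatError("fs_position must not exceed fs_signal")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channels]
        if missing:
            raise ChannelError(f"missing channels: {missing}")
        n_expected = int(round(self.duration_s * self.fs_signal))
        for name, trace in self.channels.items():
            trace = np.asarray(trace, dtype=float)
            self.channels[name] = trace
            if trace.ndim != 1 or len(trace) != n_expected:
                raise FormatError(
                    f"channel {name!r} has {len(trace)} samples, expected {n_expected}"
                )
        self.position = np.asarray(self.position, dtype=float)
        if self.position.size and self.position.shape[1] != 2:
            raise FormatError("position must be an (n, 2) array")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_signal))


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels on a uniform grid."""

    labels: np.ndarray
    epoch_len_s: float = 2.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U11")
        if self.labels.size == 0:
            raise FormatError("hypnogram has no epochs")
        if not self.epoch_len_s > 0:
            raise FormatError("epoch_len_s must be positive")
        bad = set(self.labels) - set(STATES)
        if bad:
            raise FormatError(f"unknown state labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def epoch_index(self, times_s) -> np.ndarray:
        """Epoch index containing each time (may fall outside [0, n))."""
        t = np.asarray(times_s, dtype=float)
        return np.floor((t - self.start_time_s) / self.epoch_len_s + 1e-9).astype(int)

    def label_at(self, times_s) -> np.ndarray:
        idx = self.epoch_index(times_s)
        if np.any((idx < 0) | (idx >= self.n_epochs)):
            raise AlignmentError("time outside hypnogram extent")
        return self.labels[idx]

    def resampled(self, start_time_s: float, epoch_len_s: float, n_epochs: int) -> "Hypnogram":
        """Labels looked up at the midpoints of a different epoch grid."""
        mids = start_time_s + epoch_len_s * (np.arange(n_epochs) + 0.5)
        return Hypnogram(self.label_at(mids), epoch_len_s, start_time_s)

    def runs(self) -> list[tuple[str, float, float]]:
        """Contiguous same-state runs as (state, start_s, end_s)."""
        out = []
        start = 0
        for i in range(1, self.n_epochs + 1):
            if i == self.n_epochs or self.labels[i] != self.labels[start]:
                out.append(
                    (
                        str(self.labels[start]),
                        self.start_time_s + start * self.epoch_len_s,
                        self.start_time_s + i * self.epoch_len_s,
                    )
                )
                start = i
        return out

    def state_fraction(self, state: str) -> float:
        return float(np.mean(self.labels == state))


@dataclass
class ClaspingRecord:
    """Monthly hindlimb-clasping observations for one mouse."""

    mouse_id: str
    observations: list[tuple[float, bool]]

    def __post_init__(self) -> None:
        ages = [a for a, _ in self.observations]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise FormatError(f"ages not strictly increasing for {self.mouse_id}")

    def clasp_onset(self) -> float | None:
        """Age at the first observation with clasping, or None if never seen."""
        for age, clasped in self.observations:
            if clasped:
                return age
        return None


# ---------------------------------------------------------------------------
# EDF session I/O


def write_session(rec: SessionRecording, path) -> None:
    """Write a session to ``path`` as EDF (signals in µV, position in cm)."""
    fs = int(round(rec.fs_signal))
    fsp = int(round(rec.fs_position))
    signals = [
        edf.EdfSignal(name, rec.channels[name], fs, "uV") for name in REQUIRED_CHANNELS
    ]
    if rec.position.size:
        for j, label in enumerate(_POSITION_LABELS):
            signals.append(edf.EdfSignal(label, rec.position[:, j], fsp, "cm"))
    edf.write_edf(
        path,
        signals,
        patient_id=rec.mouse_id,
        recording_id=f"{rec.genotype} {rec.age_weeks:g}w",
    )


def read_session(path, metadata: Mapping) -> SessionRecording:
    """Read an EDF session back into a :class:`SessionRecording`.

    ``metadata`` supplies ``mouse_id``, ``genotype`` and ``age_weeks`` (a
    manifest CSV row works directly).
    """
    signals = {s.label: s for s in edf.read_edf(path)}
    missing = [c for c in REQUIRED_CHANNELS if c not in signals]
    if missing:
        raise ChannelError(f"EDF at {path} lacks channels: {missing}")
    fs = {signals[c].sample_rate for c in REQUIRED_CHANNELS}
    if len(fs) != 1:
        raise FormatError("signal channels have inconsistent sampling rates")
    fs_signal = float(fs.pop())
    lengths = {len(signals[c].data) for c in REQUIRED_CHANNELS}
    if len(lengths) != 1:
        raise FormatError("signal channels have inconsistent lengths")
    duration = lengths.pop() / fs_signal

    if all(lbl in signals for lbl in _POSITION_LABELS):
        position = np.column_stack([signals[lbl].data for lbl in _POSITION_LABELS])
        fs_position = float(signals[_POSITION_LABELS[0]].sample_rate)
    else:
        position = np.zeros((0, 2))
        fs_position = 50.0

    return SessionRecording(
        mouse_id=str(metadata["mouse_id"]),
        genotype=str(metadata["genotype"]),
        age_weeks=float(metadata["age_weeks"]),
        channels={c: signals[c].data for c in REQUIRED_CHANNELS},
        fs_signal=fs_signal,
        position=position,
        fs_position=fs_position,
        duration_s=duration,
    )


# ---------------------------------------------------------------------------
# Movement


def compute_movement(position, fs_position: float):
    """Instantaneous speed (cm/s) from a 2-D track, 1-s moving average.

    The first speed sample duplicates the second so the output matches the
    track length; edges of the moving average taper toward zero coverage.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 2 or position.shape[0] < 2:
        raise InputSizeError("need at least 2 position samples")
    steps = np.linalg.norm(np.diff(position, axis=0), axis=1) * fs_position
    speed = np.concatenate([[steps[0]], steps])
    win = max(1, int(round(fs_position)))  # 1-s smoothing window
    return np.convolve(speed, np.ones(win) / win, mode="same")


# ---------------------------------------------------------------------------
# CSV I/O


def _write_csv(df: pd.DataFrame, path, header_meta: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_meta:
            meta = " ".join(f"{k}={v}" for k, v in header_meta.items())
            fh.write(f"# betasleep {meta}\n")
        df.to_csv(fh, index=False)


def write_hypnogram(hyp: Hypnogram, path, header_meta: Mapping | None = None) -> None:
    starts = hyp.start_time_s + hyp.epoch_len_s * np.arange(hyp.n_epochs)
    df = pd.DataFrame({"start_s": starts, "state": hyp.labels})
    _write_csv(df, path, header_meta)


def read_hypnogram(path) -> Hypnogram:
    df = pd.read_csv(path, comment="#")
    if not {"start_s", "state"} <= set(df.columns):
        raise FormatError("hypnogram CSV needs columns start_s,state")
    starts = df["start_s"].to_numpy(dtype=float)
    if len(starts) > 1:
        steps = np.diff(starts)
        if not np.allclose(steps, steps[0]):
            raise FormatError("hypnogram epochs are not uniform")
        epoch_len = float(steps[0])
    else:
        epoch_len = 2.0
    return Hypnogram(df["state"].to_numpy(), epoch_len, float(starts[0]))


def write_clasping(records: Iterable[ClaspingRecord], path, header_meta=None) -> None:
    rows = [
        {"mouse_id": r.mouse_id, "age_weeks": age, "clasp": int(clasped)}
        for r in records
        for age, clasped in r.observations
    ]
    _write_csv(pd.DataFrame(rows, columns=["mouse_id", "age_weeks", "clasp"]), path, header_meta)


def read_clasping(path) -> list[ClaspingRecord]:
    df = pd.read_csv(path, comment="#")
    records = []
    for mouse_id, grp in df.groupby("mouse_id", sort=False):
        grp = grp.sort_values("age_weeks")
        obs = [(float(a), bool(c)) for a, c in zip(grp["age_weeks"], grp["clasp"])]
        records.append(ClaspingRecord(str(mouse_id), obs))
    return records


def write_manifest(df: pd.DataFrame, path, header_meta=None) -> None:
    _write_csv(df[["mouse_id", "genotype", "age_weeks", "path"]], path, header_meta)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    need = {"mouse_id", "genotype", "age_weeks", "path"}
    if not need <= set(df.columns):
        raise FormatError(f"manifest CSV needs columns {sorted(need)}")
    return df
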