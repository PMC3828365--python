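"""Minimal EDF (European Data Format) reader and writer.

EDF stores each signal as 16-bit little-endian integers inside fixed-duration
data records, with an ASCII header mapping digital counts to physical units.
This module implements exactly the subset the package needs: continuous
signals, one-second data records, per-signal sampling rates and physical
dimensions.  Quantization error per sample is (physical range)/65535.

The header start date/time default to fixed values so that writing the same
data twice produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

__all__ = ["EdfSignal", "write_edf", "read_edf"]

_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass
class EdfSignal:
    """One continuous signal destined for (or read from) an EDF file.

    Parameters
    ----------
    label : channel name (max 16 ASCII chars).
    data : samples in physical units; length must be a multiple of
        ``sample_rate`` and equal across signals in seconds.
    sample_rate : integer samples per second (per one-second data record).
    physical_dim : unit string, e.g. ``"uV"`` or ``"cm"``.
    """

    label: str
    data: np.ndarray
    sample_rate: int
    physical_dim: str = "uV"
    physical_min: float | None = field(default=None)
    physical_max: float | None = field(default=None)

    def duration_s(self) -> float:
        return len(self.data) / self.sample_rate


def _ascii_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    if not s.isascii():
        raise FormatError(f"non-ASCII header field: {value!r}")
    return s.ljust(width).encode("ascii")


def _fmt_float(value: float, width: int = 8) -> str:
    """Format a float into an 8-char EDF header field, parse-compatible."""
    for fmt in (f"{{:.{width - 2}g}}", "{:.4g}", "{:.3g}", "{:.2g}"):
        s = fmt.format(float(value))
        if len(s) <= width:
            return s
    raise FormatError(f"cannot format {value} in {width} chars")


def write_edf(
    path,
    signals: list[EdfSignal],
    patient_id: str = "X",
    recording_id: str = "betasleep",
) -> None:
    """Write signals to ``path`` as a plain EDF file with 1-s data records."""
    if not signals:
        raise FormatError("no signals to write")
    durations = {round(s.duration_s(), 9) for s in signals}
    if len(durations) != 1:
        raise FormatError(f"signals have unequal durations: {sorted(durations)}")
    duration = durations.pop()
    n_records = int(round(duration))
    if abs(duration - n_records) > 1e-9 or n_records < 1:
        raise FormatError(f"duration must be a whole number of seconds, got {duration}")
    for s in signals:
        if int(s.sample_rate) != s.sample_rate or s.sample_rate < 1:
            raise FormatError(f"sample rate must be a positive integer: {s.sample_rate}")

    ns = len(signals)
    header = bytearray()
    header += _ascii_field("0", 8)
    header += _ascii_field(patient_id, 80)
    header += _ascii_field(recording_id, 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(str(256 * (ns + 1)), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(str(n_records), 8)
    header += _ascii_field("1", 8)
    header += _ascii_field(str(ns), 4)

    # Per-signal scaling: symmetric physical range covering the data; the
    # range actually used is the one *as printed* in the header, so writer
    # and reader agree exactly.
    pmins, pmaxs, gains = [], [], []
    for s in signals:
        data = np.asarray(s.data, dtype=float)
        if s.physical_min is not None and s.physical_max is not None:
            lo, hi = float(s.physical_min), float(s.physical_max)
        else:
            a = float(np.max(np.abs(data))) if data.size else 0.0
            a = a if a > 0 else 1.0
            lo, hi = -a, a
        lo = float(_fmt_float(lo))
        hi = float(_fmt_float(hi))
        if not hi > lo:
            raise FormatError(f"degenerate physical range for {s.label}")
        pmins.append(lo)
        pmaxs.append(hi)
        gains.append((hi - lo) / (_DIG_MAX - _DIG_MIN))

    for s in signals:
        header += _ascii_field(s.label, 16)
    for s in signals:
        header += _ascii_field("", 80)  # transducer
    for s in signals:
        header += _ascii_field(s.physical_dim, 8)
    for lo in pmins:
        header += _ascii_field(_fmt_float(lo), 8)
    for hi in pmaxs:
        header += _ascii_field(_fmt_float(hi), 8)
    for _ in signals:
        header += _ascii_field(str(_DIG_MIN), 8)
    for _ in signals:
        header += _ascii_field(str(_DIG_MAX), 8)
    for s in signals:
        header += _ascii_field("", 80)  # prefiltering
    for s in signals:
        header += _ascii_field(str(int(s.sample_rate)), 8)
    for _ in signals:
        header += _ascii_field("", 32)

    digitized = []
    for s, lo, hi, g in zip(signals, pmins, pmaxs, gains):
        data = np.asarray(s.data, dtype=float)
        d = np.round((data - lo) / g) + _DIG_MIN
        digitized.append(np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec in range(n_records):
            for s, d in zip(signals, digitized):
                sr = int(s.sample_rate)
                fh.write(d[rec * sr : (rec + 1) * sr].tobytes())


def read_edf(path) -> list[EdfSignal]:
    """Read a plain EDF file written by :func:`write_edf` (or compatible)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise FormatError("file too short for an EDF header")

    def fld(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        header_bytes = int(fld(184, 8))
        n_records = int(fld(236, 8))
        record_dur = float(fld(244, 8))
        ns = int(fld(252, 4))
    except ValueError as exc:
        raise FormatError(f"malformed EDF header: {exc}") from exc
    if header_bytes != 256 * (ns + 1) or len(raw) < header_bytes:
        raise FormatError("EDF header size mismatch")

    base = 256

    def sig_fld(block: int, width: int, i: int) -> str:
        return fld(base + block + i * width, width)

    # per-signal blocks are laid out field-by-field
    offs = [0, 16 * ns, 96 * ns, 104 * ns, 112 * ns, 120 * ns, 128 * ns, 136 * ns, 216 * ns]
    labels = [sig_fld(offs[0], 16, i) for i in range(ns)]
    dims = [sig_fld(offs[2], 8, i) for i in range(ns)]
    pmins = [float(sig_fld(offs[3], 8, i)) for i in range(ns)]
    pmaxs = [float(sig_fld(offs[4], 8, i)) for i in range(ns)]
    dmins = [int(sig_fld(offs[5], 8, i)) for i in range(ns)]
    dmaxs = [int(sig_fld(offs[6], 8, i)) for i in range(ns)]
    srates = [int(sig_fld(offs[8], 8, i)) for i in range(ns)]

    rec_len = sum(srates)
    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    if len(body) < n_records * rec_len:
        raise FormatError("EDF body shorter than header declares")
    body = body[: n_records * rec_len].reshape(n_records, rec_len)

    signals = []
    col = 0
    for i in range(ns):
        sr = srates[i]
        d = body[:, col : col + sr].reshape(-1).astype(float)
        col += sr
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        data = (d - dmins[i]) * gain + pmins[i]
        if record_dur != 1.0:
            sr = sr / record_dur
        signals.append(
            EdfSignal(
                label=labels[i],
                data=data,
                sample_rate=int(sr) if float(sr).is_integer() else sr,
                physical_dim=dims[i],
                physical_min=pmins[i],
                physical_max=pmaxs[i],
            )
        )
    return signals
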