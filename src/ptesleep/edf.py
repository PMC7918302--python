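"""Minimal EDF (European Data Format) reader/writer.

Supports plain EDF with a common integer sampling rate across channels,
16-bit samples and 1-second data records — sufficient for the rodent
EEG/EMG recordings this package analyses and generates.  Implemented
in-package so the pipeline has no binary-format dependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .exceptions import UnsupportedFormatError

_HDR_FIXED = 256
_HDR_PER_SIGNAL = 256

DIG_MIN = -32768
DIG_MAX = 32767


@dataclass
class EdfSignalHeader:
    label: str
    physical_dim: str
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    samples_per_record: int


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    signals: dict[str, np.ndarray],
    fs: float,
    start: datetime | None = None,
    physical_dim: str = "uV",
    patient_id: str = "X",
    recording_id: str = "X",
) -> None:
    """Write channels (µV float arrays, one common ``fs``) as 16-bit EDF.

    Signals are truncated to a whole number of 1-second records; each
    channel gets a symmetric physical range covering its data, so the
    quantization step is ``(2*max|x|)/65535``.
    """
    if not signals:
        raise ValueError("no signals to write")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise UnsupportedFormatError(f"EDF writer needs an integer fs, got {fs}")
    fs = int(round(fs))
    if start is None:
        start = datetime(2021, 1, 1, 6, 30, 0)

    n = min(len(v) for v in signals.values())
    n_records = n // fs
    if n_records < 1:
        raise ValueError("signal shorter than one data record")

    headers = []
    digitized = []
    for label, x in signals.items():
        x = np.asarray(x, dtype=float)[: n_records * fs]
        amax = float(np.max(np.abs(x))) if x.size else 0.0
        phys = max(amax, 1.0)
        scale = DIG_MAX / phys
        d = np.clip(np.round(x * scale), DIG_MIN, DIG_MAX).astype("<i2")
        headers.append(
            EdfSignalHeader(
                label=label,
                physical_dim=physical_dim,
                physical_min=-phys,
                physical_max=phys,
                digital_min=-DIG_MAX,  # symmetric around 0
                digital_max=DIG_MAX,
                samples_per_record=fs,
            )
        )
        digitized.append(d)

    ns = len(headers)
    header_bytes = _HDR_FIXED + ns * _HDR_PER_SIGNAL
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(patient_id, 80))
        fh.write(_field(recording_id, 80))
        fh.write(_field(start.strftime("%d.%m.%y"), 8))
        fh.write(_field(start.strftime("%H.%M.%S"), 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field("1", 8))
        fh.write(_field(str(ns), 4))
        for getter, width in (
            (lambda h: h.label, 16),
            (lambda h: "", 80),
            (lambda h: h.physical_dim, 8),
            (lambda h: f"{h.physical_min:.6g}", 8),
            (lambda h: f"{h.physical_max:.6g}", 8),
            (lambda h: str(h.digital_min), 8),
            (lambda h: str(h.digital_max), 8),
            (lambda h: "", 80),
            (lambda h: str(h.samples_per_record), 8),
            (lambda h: "", 32),
        ):
            for h in headers:
                fh.write(_field(getter(h), width))
        # data records: channel blocks interleaved per record
        for r in range(n_records):
            for d in digitized:
                fh.write(d[r * fs : (r + 1) * fs].tobytes())


def read_edf(path) -> tuple[dict[str, np.ndarray], float, datetime]:
    """Read an EDF file; returns (signals in physical units, fs, start)."""
    with open(path, "rb") as fh:
        raw = fh.read()

    def txt(off, width):
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    startdate = txt(168, 8)
    starttime = txt(176, 8)
    try:
        start = datetime.strptime(startdate + " " + starttime, "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = datetime(2000, 1, 1)
    n_records = int(txt(236, 8))
    record_dur = float(txt(244, 8))
    ns = int(txt(252, 4))

    off = _HDR_FIXED

    def sig_fields(width):
        nonlocal off
        vals = [txt(off + i * width, width) for i in range(ns)]
        off += ns * width
        return vals

    labels = sig_fields(16)
    sig_fields(80)  # transducer
    sig_fields(8)  # physical dim
    phys_min = [float(v) for v in sig_fields(8)]
    phys_max = [float(v) for v in sig_fields(8)]
    dig_min = [int(float(v)) for v in sig_fields(8)]
    dig_max = [int(float(v)) for v in sig_fields(8)]
    sig_fields(80)  # prefilter
    spr = [int(v) for v in sig_fields(8)]
    sig_fields(32)  # reserved

    if len(set(s / record_dur for s in spr)) != 1:
        raise UnsupportedFormatError("channels have unequal sampling rates")
    fs = spr[0] / record_dur

    data_off = _HDR_FIXED + ns * _HDR_PER_SIGNAL
    rec_len = sum(spr)
    all_dig = np.frombuffer(
        raw, dtype="<i2", count=n_records * rec_len, offset=data_off
    ).reshape(n_records, rec_len)

    signals: dict[str, np.ndarray] = {}
    col = 0
    for i, label in enumerate(labels):
        d = all_dig[:, col : col + spr[i]].reshape(-1).astype(float)
        col += spr[i]
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        signals[label] = (d - dig_min[i]) * gain + phys_min[i]
    return signals, fs, start
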