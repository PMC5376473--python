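"""Minimal EDF (European Data Format) codec for EEG recordings.

EDF stores each signal as 16-bit integers with a per-signal linear
mapping between digital and physical (microvolt) ranges, so a
write-then-read round trip is exact only to the 16-bit quantization
step ``(phys_max - phys_min) / 65535``.

The writer emits a single data record spanning the whole recording
(legal EDF; the record duration field carries the total duration),
which avoids padding partial records. The reader accepts any record
layout but requires one sampling rate shared by every signal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .io import EEGRecording

__all__ = ["read_edf", "write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width} bytes")
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{{:.{p}g}}" for p in range(width - 1, 0, -1)):
        s = fmt.format(value)
        if len(s) <= width:
            return _field(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF."""
    path = Path(path)
    n_sig = len(rec.channels)
    n_samp = rec.n_samples
    phys_min = rec.data.min(axis=0)
    phys_max = rec.data.max(axis=0)
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_sig)), 8),
            _field("", 44),
            _field("1", 8),  # one record holding the whole recording
            _num(n_samp / rec.fs, 8),
            _field(str(n_sig), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_field(name, 16) for name in rec.channels),
            b"".join(_field("", 80) for _ in range(n_sig)),
            b"".join(_field("uV", 8) for _ in range(n_sig)),
            b"".join(_num(phys_min[i], 8) for i in range(n_sig)),
            b"".join(_num(phys_max[i], 8) for i in range(n_sig)),
            b"".join(_num(_DIG_MIN, 8) for _ in range(n_sig)),
            b"".join(_num(_DIG_MAX, 8) for _ in range(n_sig)),
            b"".join(_field("", 80) for _ in range(n_sig)),
            b"".join(_field(str(n_samp), 8) for _ in range(n_sig)),
            b"".join(_field("", 32) for _ in range(n_sig)),
        ]
    )

    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.rint((rec.data - phys_min) / scale + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        # record layout: all samples of signal 0, then signal 1, ...
        fh.write(np.ascontiguousarray(digital.T).tobytes())
    return path


def _read_fields(raw: bytes, offset: int, width: int, count: int) -> list[str]:
    return [
        raw[offset + i * width : offset + (i + 1) * width].decode("ascii").strip()
        for i in range(count)
    ]


def read_edf(path: str | Path) -> EEGRecording:
    """Read a (plain) EDF file into an :class:`EEGRecording`."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError("truncated EDF header")
    n_records = int(raw[236:244].decode("ascii").strip())
    record_dur = float(raw[244:252].decode("ascii").strip())
    n_sig = int(raw[252:256].decode("ascii").strip())
    if n_sig == 0:
        raise ValueError("EDF with zero signals")

    off = 256
    labels = _read_fields(raw, off, 16, n_sig)
    off += n_sig * (16 + 80 + 8)
    phys_min = np.array([float(v) for v in _read_fields(raw, off, 8, n_sig)])
    off += n_sig * 8
    phys_max = np.array([float(v) for v in _read_fields(raw, off, 8, n_sig)])
    off += n_sig * 8
    dig_min = np.array([float(v) for v in _read_fields(raw, off, 8, n_sig)])
    off += n_sig * 8
    dig_max = np.array([float(v) for v in _read_fields(raw, off, 8, n_sig)])
    off += n_sig * (8 + 80)
    n_per_rec = np.array([int(v) for v in _read_fields(raw, off, 8, n_sig)])

    keep = [i for i, lab in enumerate(labels) if lab != "EDF Annotations"]
    if not keep:
        raise ValueError("EDF contains no signal channels")
    rates = n_per_rec[keep] / record_dur
    if not np.allclose(rates, rates[0]):
        raise ValueError(f"non-constant sampling rates across channels: {rates}")
    fs = float(rates[0])

    header_bytes = 256 * (1 + n_sig)
    rec_len = int(n_per_rec.sum())
    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    if body.size < n_records * rec_len:
        raise ValueError("EDF data shorter than header declares")
    body = body[: n_records * rec_len].reshape(n_records, rec_len)

    starts = np.concatenate([[0], np.cumsum(n_per_rec)])
    columns = []
    for i in keep:
        sig = body[:, starts[i] : starts[i + 1]].reshape(-1).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        columns.append(phys_min[i] + (sig - dig_min[i]) * gain)
    data = np.column_stack(columns)
    return EEGRecording([labels[i] for i in keep], fs, data)
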