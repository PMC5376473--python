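"""Multichannel EEG recordings and plain-text I/O.

The in-memory container is :class:`EEGRecording`: a samples x channels
matrix in microvolts with a fixed sampling rate, named channels and a
list of timed annotations (LOC/ROC marks, infusion events).

Supported on-disk formats:

* CSV — one header row naming the channels, one row per sample. The
  sampling rate comes from an ``fs`` argument or a YAML sidecar
  (``<stem>.yaml`` with an ``fs`` key).
* EDF — via :mod:`doaflow.io_edf` (16-bit European Data Format).
* annotations — a two-column CSV ``time_s,label``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

__all__ = [
    "EEGRecording",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "lowpass_filter",
]


@dataclass
class EEGRecording:
    """A fixed-rate multichannel signal in microvolts.

    Parameters
    ----------
    channels : sequence of str
        Unique channel names, in column order of ``data``.
    fs : float
        Sampling rate in Hz, constant over the recording.
    data : ndarray, shape (n_samples, n_channels)
        Signal values in microvolts.
    annotations : list of (float, str)
        Timed event marks, e.g. ``(312.5, "LOC")``. Times in seconds
        from record start, within ``[0, duration]``.
    """

    channels: list[str]
    fs: float
    data: np.ndarray
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = [str(c) for c in self.channels]
        if len(self.channels) == 0:
            raise ValueError("recording must have at least one channel")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels"
            )
        for t, _label in self.annotations:
            if not 0 <= t <= self.duration_s:
                raise ValueError(f"annotation time {t} outside [0, {self.duration_s}]")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.fs

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        """Column indices of the given channel names (order preserved)."""
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        return np.array([self.channels.index(n) for n in names], dtype=int)

    def get(self, names: Sequence[str]) -> np.ndarray:
        """Samples x len(names) view of the selected channels."""
        return self.data[:, self.channel_index(names)]

    def annotation_time(self, label: str) -> float:
        for t, lab in self.annotations:
            if lab == label:
                return t
        raise KeyError(f"no annotation labelled {label!r}")


def _sidecar_fs(path: Path) -> float | None:
    side = path.with_suffix(".yaml")
    if side.exists():
        meta = yaml.safe_load(side.read_text())
        if isinstance(meta, dict) and "fs" in meta:
            return float(meta["fs"])
    return None


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    fill: float | None = None,
) -> EEGRecording:
    """Read a recording from CSV or EDF.

    ``format`` is inferred from the suffix when omitted. For CSV the
    sampling rate must come from ``fs`` or a ``<stem>.yaml`` sidecar.
    NaNs raise unless a ``fill`` value is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "edf":
        from .io_edf import read_edf

        return read_edf(path)
    if format == "csv":
        frame = pd.read_csv(path, float_precision="round_trip")
        if frame.shape[1] == 0:
            raise ValueError("CSV has no channel columns")
        if fs is None:
            fs = _sidecar_fs(path)
        if fs is None:
            raise ValueError("CSV input needs a sampling rate (fs= or YAML sidecar)")
        data = frame.to_numpy(dtype=float)
        if np.isnan(data).any():
            if fill is None:
                raise ValueError("CSV contains NaN and no fill policy was given")
            data = np.nan_to_num(data, nan=fill)
        if not np.isfinite(data).all():
            raise ValueError("CSV contains non-finite values")
        return EEGRecording(list(frame.columns), float(fs), data)
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording to CSV (plus YAML sidecar) or EDF."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "edf":
        from .io_edf import write_edf

        write_edf(rec, path)
        return path
    if format == "csv":
        # %.17g round-trips IEEE doubles exactly
        pd.DataFrame(rec.data, columns=rec.channels).to_csv(
            path, index=False, float_format="%.17g"
        )
        path.with_suffix(".yaml").write_text(yaml.safe_dump({"fs": float(rec.fs)}))
        return path
    raise ValueError(f"unknown recording format {format!r}")


def read_annotations(path: str | Path) -> list[tuple[float, str]]:
    frame = pd.read_csv(path)
    return [(float(t), str(lab)) for t, lab in zip(frame["time_s"], frame["label"])]


def write_annotations(annotations: Sequence[tuple[float, str]], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(annotations, columns=["time_s", "label"]).to_csv(path, index=False)
    return path


def lowpass_filter(
    rec: EEGRecording, cutoff_hz: float = 50.0, order: int = 9
) -> EEGRecording:
    """Butterworth low-pass the whole recording, zero phase.

    A digital Butterworth of the given order is designed at
    ``cutoff_hz`` (bilinear transform, -3 dB at the cutoff) and applied
    forward-backward (``sosfiltfilt``), which cancels group delay so
    window alignment is preserved but doubles the effective order: the
    magnitude response is |H(f)|^2.
    """
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={rec.fs / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=0)
    return EEGRecording(list(rec.channels), rec.fs, filtered, list(rec.annotations))


def lowpass_attenuation_db(
    freq_hz: float, fs: float, cutoff_hz: float = 50.0, order: int = 9
) -> float:
    """Predicted attenuation (dB, positive) of the zero-phase filter at freq_hz."""
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    # forward-backward application squares the magnitude response
    return -20.0 * math.log10(abs(h[0]) ** 2)
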