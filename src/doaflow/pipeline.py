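"""Index time courses over a recording.

Each depth-of-anesthesia index is evaluated window by window (60 s of
data every 30 s by default) to yield an :class:`IndexCourse`. The TE
lag defaults to 2 samples, i.e. 7.8 ms at the clinical 256 Hz rate.
Recordings are conventionally divided into five sections A-E around
the infusion (pre-infusion baseline, concentration increase,
maintenance, decrease, recovery) for summary statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import spectral
from .bipartition import (
    Bipartition,
    index_tmax,
    index_tmean,
    index_tmin,
    te_table,
)
from .infotheory import transfer_entropy
from .io import EEGRecording
from .windows import Window, make_windows

__all__ = [
    "IndexCourse",
    "compute_course",
    "compute_te_courses",
    "pairwise_course",
    "summarize_sections",
    "default_sections",
    "DEFAULT_TAU",
]

#: TE prediction lag in samples: 2 samples = 7.8 ms at 256 Hz
DEFAULT_TAU = 2

TE_INDICES = ("tmax", "tmin", "tmean", "arbitrary")
SPECTRAL_INDICES = ("sef", "spe", "sfs")


@dataclass
class IndexCourse:
    """One index value per analysis window, with full provenance."""

    name: str
    times_s: np.ndarray
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("window times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"time_s": self.times_s, "value": self.values}).to_csv(
            path, index=False
        )
        return path

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "params": self.params,
                "times_s": self.times_s.tolist(),
                "values": self.values.tolist(),
            }
        )


def _course_params(window_s, step_s, tau, mode, rule) -> dict:
    return {
        "window_s": window_s,
        "step_s": step_s,
        "tau_samples": tau,
        "mode": mode,
        "tmin_rule": rule,
    }


def compute_te_courses(
    rec: EEGRecording,
    channels: Sequence[str] | None = None,
    window_s: float = 60.0,
    step_s: float = 30.0,
    tau: int = DEFAULT_TAU,
    mode: str = "disjoint_pairs",
    rule: str = "min",
) -> dict[str, IndexCourse]:
    """T_max, T_min and T_mean in one bipartition scan per window.

    All three indices derive from the same per-window TE table, so
    computing them together costs one pooled covariance and one scan.
    """
    channels = list(channels) if channels is not None else list(rec.channels)
    windows = make_windows(rec, window_s, step_s)
    times = np.array([w.start_s for w in windows])
    out = {name: np.empty(len(windows)) for name in ("tmax", "tmin", "tmean")}
    for i, w in enumerate(windows):
        table = te_table(rec, w, channels, tau=tau, mode=mode)
        out["tmax"][i] = index_tmax(table)[0]
        out["tmin"][i] = index_tmin(table, rule=rule)[0]
        out["tmean"][i] = index_tmean(table)
    params = _course_params(window_s, step_s, tau, mode, rule)
    return {
        name: IndexCourse(name, times, vals, dict(params, channels=channels))
        for name, vals in out.items()
    }


def compute_course(
    rec: EEGRecording,
    index: str,
    channels: Sequence[str] | None = None,
    window_s: float = 60.0,
    step_s: float = 30.0,
    tau: int = DEFAULT_TAU,
    mode: str = "disjoint_pairs",
    rule: str = "min",
    bipartition: Bipartition | None = None,
    spectral_channel: str = "Fp1",
) -> IndexCourse:
    """Time course of one named index.

    ``index`` is one of tmax/tmin/tmean (bipartition TE indices),
    ``arbitrary`` (TE of one fixed user-supplied bipartition), or
    sef/spe/sfs (single-channel spectral comparators, computed from
    ``spectral_channel``).
    """
    if index not in TE_INDICES and index not in SPECTRAL_INDICES:
        raise ValueError(f"unknown index {index!r}")
    if index in ("tmax", "tmin", "tmean"):
        return compute_te_courses(rec, channels, window_s, step_s, tau, mode, rule)[index]
    windows = make_windows(rec, window_s, step_s)
    times = np.array([w.start_s for w in windows])
    values = np.empty(len(windows))
    params = _course_params(window_s, step_s, tau, mode, rule)
    if index == "arbitrary":
        if bipartition is None:
            raise ValueError("index 'arbitrary' needs a fixed bipartition")
        for i, w in enumerate(windows):
            values[i] = transfer_entropy(
                rec, bipartition.target, bipartition.source, w, tau
            )
        params["bipartition"] = str(bipartition)
    elif index in SPECTRAL_INDICES:
        col = rec.channel_index([spectral_channel])[0]
        fn = {
            "sef": lambda x: spectral.sef(x, rec.fs),
            "spe": lambda x: spectral.spectral_entropy(x, rec.fs),
            "sfs": lambda x: spectral.sfs(x, rec.fs),
        }[index]
        for i, w in enumerate(windows):
            values[i] = fn(rec.data[w.start_idx : w.end_idx, col])
        params["channel"] = spectral_channel
    return IndexCourse(index, times, values, params)


def pairwise_course(
    rec: EEGRecording,
    src: str,
    dst: str,
    window_s: float = 60.0,
    step_s: float = 30.0,
    tau: int = DEFAULT_TAU,
) -> IndexCourse:
    """Single-channel-to-single-channel TE course (e.g. F3 -> P3)."""
    if src == dst:
        raise ValueError("source and destination channels must differ")
    windows = make_windows(rec, window_s, step_s)
    times = np.array([w.start_s for w in windows])
    values = np.array(
        [transfer_entropy(rec, [dst], [src], w, tau) for w in windows]
    )
    return IndexCourse(
        f"te_{src}->{dst}",
        times,
        values,
        dict(_course_params(window_s, step_s, tau, "pairwise", "-"), src=src, dst=dst),
    )


#: standard section durations in minutes, anchored at infusion start
SECTION_MINUTES = {"A": 4.0, "B": 20.0, "C": 15.0, "D": 20.0, "E": 10.0}


def default_sections(infusion_start_s: float) -> dict[str, tuple[float, float]]:
    """A-E section intervals: A ends at infusion start, B-E follow it."""
    bounds = {}
    t = infusion_start_s - SECTION_MINUTES["A"] * 60.0
    for label, minutes in SECTION_MINUTES.items():
        bounds[label] = (t, t + minutes * 60.0)
        t += minutes * 60.0
    return bounds


def summarize_sections(
    course: IndexCourse,
    sections: Mapping[str, tuple[float, float]],
    normalize_by: str | None = None,
) -> pd.DataFrame:
    """Per-section mean and SD of window values.

    Windows whose start time falls in ``[start, end)`` belong to the
    section. ``normalize_by="A"`` divides every statistic by section
    A's mean (per-subject normalization of the published analyses).
    """
    rows = []
    for label, (start, end) in sections.items():
        mask = (course.times_s >= start) & (course.times_s < end)
        if not mask.any():
            raise ValueError(f"section {label!r} [{start}, {end}) contains no windows")
        vals = course.values[mask]
        rows.append(
            {"section": label, "n": int(mask.sum()),
             "mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
        )
    frame = pd.DataFrame(rows).set_index("section")
    if normalize_by is not None:
        ref = frame.loc[normalize_by, "mean"]
        if ref == 0:
            raise ValueError("cannot normalize by a zero-mean section")
        frame["mean"] /= ref
        frame["sd"] /= abs(ref)
    return frame
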