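"""Windowing and the index-sampling schedule.

The TE indices are computed on sliding windows — by default 60 s of
data every 30 s. Around an infusion the clinical sampling schedule is
denser: selection times follow two grids, one anchored at infusion
start (every 30 s for 10 min, then every 1 min for 60 min) and one at
infusion end (every 30 s for 20 min, every 1 min for the next 20 min,
every 2 min for the next 20 min), merged and clipped to the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import EEGRecording

__all__ = ["Window", "make_windows", "selection_schedule"]


@dataclass(frozen=True)
class Window:
    """Half-open sample range [start_idx, end_idx) with its time span."""

    start_s: float
    length_s: float
    start_idx: int
    end_idx: int

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


def make_windows(
    rec: EEGRecording, length_s: float = 60.0, step_s: float = 30.0
) -> list[Window]:
    """Sliding windows at starts 0, step, 2*step, ...; no partial windows.

    The last window is the final one fully contained in the recording;
    a recording shorter than one window is an error.
    """
    if length_s <= 0 or step_s <= 0:
        raise ValueError("window length and step must be positive")
    n_len = round(length_s * rec.fs)
    n_step = round(step_s * rec.fs)
    if n_len > rec.n_samples:
        raise ValueError(
            f"window of {length_s} s exceeds recording of {rec.duration_s} s"
        )
    windows = []
    start = 0
    while start + n_len <= rec.n_samples:
        windows.append(
            Window(start / rec.fs, length_s, start, start + n_len)
        )
        start += n_step
    return windows


# (interval length seconds, spacing seconds) clauses of the two grids
_POST_START = [(600.0, 30.0), (3600.0, 60.0)]
_POST_END = [(1200.0, 30.0), (1200.0, 60.0), (1200.0, 120.0)]


def _grid(anchor: float, clauses: list[tuple[float, float]]) -> list[float]:
    times = []
    offset = 0.0
    for span, spacing in clauses:
        t = offset
        # a clause boundary belongs to the later, coarser grid
        while t < offset + span:
            times.append(anchor + t)
            t += spacing
        offset += span
    times.append(anchor + offset)  # closing endpoint of the last clause
    return times


def selection_schedule(
    infusion_start_s: float, infusion_end_s: float, duration_s: float
) -> list[float]:
    """Index-selection times around an infusion, clipped to the recording.

    Returns the sorted union of the post-infusion-start grid
    (30 s x 10 min then 1 min x 60 min) and the post-infusion-end grid
    (30 s x 20 min, 1 min x 20 min, 2 min x 20 min), deduplicated.
    """
    if not infusion_start_s < infusion_end_s <= duration_s:
        raise ValueError("need infusion start < infusion end <= duration")
    times = _grid(infusion_start_s, _POST_START) + _grid(infusion_end_s, _POST_END)
    return sorted({t for t in times if t <= duration_s})
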