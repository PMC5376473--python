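"""Bipartition scan of the channel set and the three flow indices.

A bipartition is an ordered pair (source group B, target group A) of
disjoint non-empty channel subsets. Two enumeration modes:

* ``disjoint_pairs`` — every ordered pair of disjoint non-empty
  subsets; the union need not cover the channel set. For n channels
  there are 3^n - 2^(n+1) + 1 such pairs (12 for n=3, 1932 for n=7).
* ``covering`` — ordered two-block set partitions (source and target
  together exhaust the channels): 2^n - 2 pairs (126 for n=7).

Scanning all bipartitions of a window costs one pass over the samples:
the pooled lagged covariance is computed once and every TE is a
combination of log-determinants of its sub-blocks.

The dominant-flow indices over a window's TE table are T_max (largest
TE over all bipartitions), T_min (the minimum information bipartition)
and T_mean (mean over all bipartitions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .infotheory import lagged_covariance, te_from_lagged_cov
from .io import EEGRecording
from .windows import Window

__all__ = [
    "Bipartition",
    "TETable",
    "enumerate_bipartitions",
    "n_bipartitions",
    "te_table",
    "te_table_from_cov",
    "index_tmax",
    "index_tmin",
    "index_tmean",
]


@dataclass(frozen=True)
class Bipartition:
    """Ordered (source, target) pair of disjoint non-empty channel groups."""

    source: tuple[str, ...]
    target: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("source and target must be non-empty")
        if set(self.source) & set(self.target):
            raise ValueError("source and target must be disjoint")

    def __str__(self) -> str:
        return f"{'+'.join(self.source)}->{'+'.join(self.target)}"


def n_bipartitions(n: int, mode: str = "disjoint_pairs") -> int:
    """Closed-form count of bipartitions of n channels."""
    if mode == "disjoint_pairs":
        return 3**n - 2 ** (n + 1) + 1
    if mode == "covering":
        return 2**n - 2
    raise ValueError(f"unknown mode {mode!r}")


def _subsets(order: Sequence[int]) -> Iterable[tuple[int, ...]]:
    # non-empty subsets in canonical order: by size, then positionally
    for size in range(1, len(order) + 1):
        yield from combinations(order, size)


def enumerate_bipartitions(
    channels: Sequence[str], mode: str = "disjoint_pairs"
) -> list[Bipartition]:
    """All bipartitions in a deterministic canonical order.

    Sources are ordered by size then position in ``channels``; for each
    source, targets follow the same order over the remaining channels.
    """
    if len(channels) < 2:
        raise ValueError("need at least 2 channels to bipartition")
    if len(set(channels)) != len(channels):
        raise ValueError("channel names must be unique")
    if mode not in ("disjoint_pairs", "covering"):
        raise ValueError(f"unknown mode {mode!r}")
    idx = list(range(len(channels)))
    out: list[Bipartition] = []
    for src in _subsets(idx):
        rest = [i for i in idx if i not in src]
        if not rest:
            continue
        if mode == "covering":
            targets: Iterable[tuple[int, ...]] = [tuple(rest)]
        else:
            targets = _subsets(rest)
        for tgt in targets:
            out.append(
                Bipartition(
                    tuple(channels[i] for i in src),
                    tuple(channels[i] for i in tgt),
                )
            )
    return out


@dataclass
class TETable:
    """Per-window TE of every bipartition, in canonical order."""

    window: Window | None
    bipartitions: list[Bipartition]
    values: np.ndarray
    mode: str = "disjoint_pairs"
    tau: int = 2
    channels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.bipartitions) != len(self.values):
            raise ValueError("one TE value per bipartition required")
        if len(self.bipartitions) == 0:
            raise ValueError("empty TE table")

    def __len__(self) -> int:
        return len(self.bipartitions)

    def __getitem__(self, bp: Bipartition) -> float:
        key = (frozenset(bp.source), frozenset(bp.target))
        for other, value in zip(self.bipartitions, self.values):
            if (frozenset(other.source), frozenset(other.target)) == key:
                return float(value)
        raise KeyError(f"bipartition {bp} not in table")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        start = self.window.start_s if self.window is not None else 0.0
        lines = ["window_start_s,source,target,te_nats"]
        for bp, v in zip(self.bipartitions, self.values):
            lines.append(f"{start},{'+'.join(bp.source)},{'+'.join(bp.target)},{v!r}")
        path.write_text("\n".join(lines) + "\n")
        return path

    def to_json(self) -> str:
        return json.dumps(
            {
                "window_start_s": self.window.start_s if self.window else 0.0,
                "mode": self.mode,
                "tau": self.tau,
                "channels": list(self.channels),
                "entries": [
                    {"source": list(bp.source), "target": list(bp.target), "te": float(v)}
                    for bp, v in zip(self.bipartitions, self.values)
                ],
            }
        )


def te_table(
    rec: EEGRecording,
    window: Window | None = None,
    channels: Sequence[str] | None = None,
    tau: int = 2,
    mode: str = "disjoint_pairs",
) -> TETable:
    """TE of every bipartition of ``channels`` over one window."""
    channels = list(channels) if channels is not None else list(rec.channels)
    cols = rec.channel_index(channels)
    data = rec.data if window is None else rec.data[window.start_idx : window.end_idx]
    cov2n = lagged_covariance(data[:, cols], tau)
    return _scan(cov2n, channels, window, tau, mode)


def te_table_from_cov(
    cov2n: np.ndarray,
    channels: Sequence[str],
    tau: int = 1,
    mode: str = "disjoint_pairs",
) -> TETable:
    """Bipartition scan on a population lagged covariance (analytic use)."""
    return _scan(np.asarray(cov2n, dtype=float), list(channels), None, tau, mode)


def _scan(
    cov2n: np.ndarray,
    channels: list[str],
    window: Window | None,
    tau: int,
    mode: str,
) -> TETable:
    n = len(channels)
    if cov2n.shape != (2 * n, 2 * n):
        raise ValueError(f"expected {2*n}x{2*n} lagged covariance, got {cov2n.shape}")
    pos = {name: i for i, name in enumerate(channels)}
    bps = enumerate_bipartitions(channels, mode)
    values = np.empty(len(bps))
    for i, bp in enumerate(bps):
        values[i] = te_from_lagged_cov(
            cov2n, n, [pos[c] for c in bp.target], [pos[c] for c in bp.source]
        )
    return TETable(window, bps, values, mode=mode, tau=tau, channels=tuple(channels))


def index_tmax(table: TETable) -> tuple[float, Bipartition]:
    """Largest TE over all bipartitions; ties broken by canonical order."""
    i = int(np.argmax(table.values))  # argmax returns the first (canonical) maximum
    return float(table.values[i]), table.bipartitions[i]


def index_tmin(table: TETable, rule: str = "min") -> tuple[float, Bipartition]:
    """Minimum information bipartition.

    ``rule="min"`` (default): the bipartition with the smallest TE.
    ``rule="maxmin"``: for each unordered channel-group pair take the
    weaker of the two directed flows, then select the pair whose weak
    direction is strongest and report that weak-direction value.
    """
    if rule == "min":
        i = int(np.argmin(table.values))
        return float(table.values[i]), table.bipartitions[i]
    if rule != "maxmin":
        raise ValueError(f"unknown T_min rule {rule!r}")
    groups: dict[frozenset, tuple[float, Bipartition]] = {}
    for bp, v in zip(table.bipartitions, table.values):
        key = frozenset({frozenset(bp.source), frozenset(bp.target)})
        if key not in groups or v < groups[key][0]:
            groups[key] = (float(v), bp)
    return max(groups.values(), key=lambda pair: pair[0])


def index_tmean(table: TETable) -> float:
    """Arithmetic mean TE over all bipartitions."""
    return float(np.mean(table.values))
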