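"""Core containers shared across the pipeline.

All event intervals are half-open ``[start_s, end_s)`` in seconds from
recording start.  Masks follow the convention ``True == excluded``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Event:
    """A typed interval: arousal, desaturation, artifact span, obstructive episode."""

    start_s: float
    end_s: float
    kind: str = ""
    value: float | None = None  # e.g. drop size (ms) or desaturation depth (%)

    def __post_init__(self) -> None:
        if not self.end_s >= self.start_s:
            raise ValueError(f"event end {self.end_s} before start {self.start_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


EventList = list


@dataclass
class BeatPttSeries:
    """Timestamped per-beat pulse transit time.

    beat_time_s is the R-wave midpoint time of each beat; ptt_ms the transit
    time to the 50%-amplitude point of the following pleth upstroke.  Beats
    for which no pulse wave could be matched carry ``valid == False``.
    """

    beat_time_s: np.ndarray
    ptt_ms: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_time_s = np.asarray(self.beat_time_s, dtype=float)
        self.ptt_ms = np.asarray(self.ptt_ms, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.beat_time_s.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.beat_time_s) == len(self.ptt_ms) == len(self.valid)):
            raise ValueError("beat_time_s, ptt_ms and valid must have equal length")
        if len(self.beat_time_s) > 1 and not np.all(np.diff(self.beat_time_s) > 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.ptt_ms[self.valid] <= 0):
            raise ValueError("valid PTT values must be positive")

    def __len__(self) -> int:
        return len(self.beat_time_s)

    @property
    def span_s(self) -> tuple[float, float]:
        return float(self.beat_time_s[0]), float(self.beat_time_s[-1])


@dataclass
class UniformSeries:
    """Regularly sampled signal with an exclusion mask (True = excluded)."""

    start_time_s: float
    step_s: float
    values: np.ndarray
    artifact_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.values.shape, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != self.values.shape:
            raise ValueError("mask and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time_s + self.step_s * np.arange(len(self.values))

    @property
    def end_time_s(self) -> float:
        """End of the sampled span (half-open)."""
        return self.start_time_s + self.step_s * len(self.values)

    @property
    def unmasked_hours(self) -> float:
        return float(np.sum(~self.artifact_mask)) * self.step_s / 3600.0

    def with_mask(self, mask: np.ndarray) -> "UniformSeries":
        return replace(self, artifact_mask=np.asarray(mask, dtype=bool).copy())


def merge_events(events: Iterable[Event], kind: str | None = None) -> list[Event]:
    """Merge overlapping or touching half-open intervals into maximal spans."""
    evs = sorted(events, key=lambda e: (e.start_s, e.end_s))
    out: list[Event] = []
    for e in evs:
        if out and e.start_s <= out[-1].end_s:
            prev = out[-1]
            out[-1] = Event(prev.start_s, max(prev.end_s, e.end_s), kind or prev.kind)
        else:
            out.append(Event(e.start_s, e.end_s, kind or e.kind))
    return out


def events_to_mask(series: UniformSeries, events: Sequence[Event]) -> np.ndarray:
    """Boolean mask over series samples covered by any event (half-open)."""
    mask = np.zeros(len(series), dtype=bool)
    n = len(series)
    for e in events:
        i0 = int(np.ceil((e.start_s - series.start_time_s) / series.step_s - 1e-9))
        i1 = int(np.ceil((e.end_s - series.start_time_s) / series.step_s - 1e-9))
        mask[max(i0, 0) : min(max(i1, 0), n)] = True
    return mask


def mask_to_events(series: UniformSeries, mask: np.ndarray, kind: str = "") -> list[Event]:
    """Contiguous True runs of ``mask`` as half-open events in time coordinates."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(series),):
        raise ValueError("mask length must match series")
    out: list[Event] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(np.int8)))
    for i0, i1 in zip(idx[::2], idx[1::2]):
        out.append(
            Event(
                series.start_time_s + i0 * series.step_s,
                series.start_time_s + i1 * series.step_s,
                kind,
            )
        )
    return out


def contiguous_unmasked_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges ``[i0, i1)`` of consecutive unmasked samples."""
    keep = ~np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(np.diff(np.concatenate(([False], keep, [False])).astype(np.int8)))
    return [(int(a), int(b)) for a, b in zip(idx[::2], idx[1::2])]
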