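"""PTT2 smoothing, artifact masking, arousal detection and respiratory swing.

The analysis channel PTT2 is the raw 5 Hz PTT channel under a centered
17-point (~3.4 s) moving mean.  A PTT arousal is a drop of >= 15 ms in PTT2
completed within 5-45 s while the channel sits in the physiological
150-500 ms range; the arousal index (PTT-AI) is arousals per artifact-free
hour.  The respiratory swing is the mean inspiratory-trough to
expiratory-peak rise of a separately derived channel (1 Hz interpolation,
3-sample moving mean), in ms — a surrogate for inspiratory effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    BeatPttSeries,
    Event,
    UniformSeries,
    contiguous_unmasked_segments,
    events_to_mask,
    mask_to_events,
    merge_events,
)

__all__ = [
    "PttFeatureSet",
    "smooth_ptt2",
    "detect_ptt_artifact",
    "detect_arousals",
    "arousal_index",
    "respiratory_swing",
    "ptt_features_for_record",
    "NoSwingError",
]

VALID_PTT_RANGE_MS = (150.0, 500.0)


class NoSwingError(ValueError):
    """Raised when no trough-to-peak pairs exist (e.g. a constant channel)."""


@dataclass
class PttFeatureSet:
    """Per-study PTT summary."""

    ptt_arousal_count: int
    ptt_arousal_index: float  # events / artifact-free hour
    respiratory_swing_ms: float
    artifact_free_hours: float
    arousal_events: list[Event] = field(default_factory=list)
    artifact_spans: list[Event] = field(default_factory=list)


def smooth_ptt2(raw: UniformSeries, window: int = 17) -> UniformSeries:
    """Centered moving mean over unmasked samples.

    An output sample is masked when more than half of its window is masked,
    or when the window is truncated at a series edge (no partial-window
    output for the arousal channel).
    """
    n = len(raw)
    if n < window:
        raise ValueError(f"series of {n} samples shorter than smoothing window {window}")
    half = window // 2
    good = ~raw.artifact_mask
    v = np.where(good, raw.values, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(v)))
    ccnt = np.concatenate(([0], np.cumsum(good.astype(np.int64))))
    out = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    idx = np.arange(half, n - half)
    tot = csum[idx + half + 1] - csum[idx - half]
    cnt = ccnt[idx + half + 1] - ccnt[idx - half]
    ok = cnt >= (window - window // 2)  # > 50% of the window unmasked
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = tot / cnt
    out[idx[ok]] = vals[ok]
    mask[idx[ok]] = False
    out[np.isnan(out)] = 0.0
    return UniformSeries(raw.start_time_s, raw.step_s, out, mask)


def detect_ptt_artifact(
    raw: UniformSeries,
    *,
    spike_ms: float = 50.0,
    valid_range_ms: tuple[float, float] = VALID_PTT_RANGE_MS,
    pad_s: float = 2.0,
) -> list[Event]:
    """Artifact spans in the raw uniform PTT channel.

    A sample is artifactual when the sample-to-sample jump exceeds
    ``spike_ms`` or when it leaves the physiological ``valid_range_ms``
    (signal dropout rails the channel out of range).  Spans are dilated by
    ``pad_s`` on each side (spikes corrupt the smoothed channel beyond
    their own samples) and merged.
    """
    v = raw.values
    n = len(v)
    bad = np.zeros(n, dtype=bool)
    if n > 1:
        jump = np.abs(np.diff(v)) > spike_ms
        bad[:-1] |= jump
        bad[1:] |= jump
    lo, hi = valid_range_ms
    bad |= (v < lo) | (v > hi) | ~np.isfinite(v)
    bad |= raw.artifact_mask
    if not bad.any():
        return []
    spans = mask_to_events(raw, bad, kind="ptt_artifact")
    padded = [
        Event(max(e.start_s - pad_s, raw.start_time_s), min(e.end_s + pad_s, raw.end_time_s), "ptt_artifact")
        for e in spans
    ]
    return merge_events(padded, kind="ptt_artifact")


def _extrema(values: np.ndarray) -> tuple[list[int], list[int]]:
    """Strict local maxima/minima with plateau handling.

    Runs of equal samples are compressed; a plateau maximum is placed at its
    falling edge and a plateau minimum at its leading edge, so the time
    between a maximum and the following minimum measures only the transition
    between them.
    """
    n = len(values)
    if n < 3:
        return [], []
    change = np.flatnonzero(np.diff(values) != 0)
    if len(change) == 0:
        return [], []
    starts = np.concatenate(([0], change + 1))  # first index of each run
    ends = np.concatenate((change, [n - 1]))  # last index of each run
    rv = values[starts]
    maxima: list[int] = []
    minima: list[int] = []
    # a boundary plateau (>= 2 equal samples at a segment edge) counts as an
    # extremum; a single boundary sample does not, so noisy segment edges do
    # not spawn events
    if len(rv) >= 2 and rv[0] > rv[1] and ends[0] > starts[0]:
        maxima.append(int(ends[0]))
    for k in range(1, len(rv) - 1):
        if rv[k] > rv[k - 1] and rv[k] > rv[k + 1]:
            maxima.append(int(ends[k]))
        elif rv[k] < rv[k - 1] and rv[k] < rv[k + 1]:
            minima.append(int(starts[k]))
    if len(rv) >= 2 and rv[-1] < rv[-2] and ends[-1] > starts[-1]:
        minima.append(int(starts[-1]))
    return maxima, minima


def detect_arousals(
    ptt2: UniformSeries,
    *,
    drop_ms: float = 15.0,
    window_s: tuple[float, float] = (5.0, 45.0),
    valid_range_ms: tuple[float, float] = VALID_PTT_RANGE_MS,
    transition_compensation_s: float | None = None,
) -> list[Event]:
    """PTT arousals: drops >= ``drop_ms`` in PTT2 completed within ``window_s``.

    The smoothing that produces PTT2 widens every transition by its window
    span, so the duration gate is applied to the maximum-to-minimum time
    minus ``transition_compensation_s`` (default: 16 sample periods, the
    span of the 17-point mean).  Events are found by a greedy left-to-right
    scan over local extrema; after the first qualifying minimum the event
    end is extended through successive lower minima (a single slow drop with
    respiratory ripple superimposed must not count twice), and scanning
    resumes past the accepted minimum.  The whole event interval must be
    unmasked and both endpoints inside ``valid_range_ms``.
    """
    if transition_compensation_s is None:
        transition_compensation_s = 16 * ptt2.step_s
    lo_t, hi_t = window_s
    if not lo_t < hi_t:
        raise ValueError("arousal window must be (low, high) with low < high")
    lo_v, hi_v = valid_range_ms
    step = ptt2.step_s
    events: list[Event] = []
    for i0, i1 in contiguous_unmasked_segments(ptt2.artifact_mask):
        seg = ptt2.values[i0:i1]
        maxima, minima = _extrema(seg)
        if not maxima or not minima:
            continue
        mi_ptr = 0  # first usable minimum (indices into minima list)
        last_min_idx = -1  # scanning resumes past the last accepted minimum
        for imax in maxima:
            if imax <= last_min_idx:
                continue
            while mi_ptr < len(minima) and minima[mi_ptr] <= imax:
                mi_ptr += 1
            if mi_ptr >= len(minima):
                break
            vmax = seg[imax]
            if not (lo_v <= vmax <= hi_v):
                continue
            chosen = None
            for j in range(mi_ptr, len(minima)):
                imin = minima[j]
                dt = (imin - imax) * step - transition_compensation_s
                if dt > hi_t:
                    break
                vmin = seg[imin]
                if dt >= lo_t and vmax - vmin >= drop_ms and lo_v <= vmin <= hi_v:
                    chosen = j
                    break
            if chosen is None:
                continue
            # extend to the lowest minimum reached before the channel recovers
            # by drop_ms above it (hysteresis): one slow drop with breathing
            # ripple superimposed must count once, not once per ripple cycle
            jb = chosen
            k = chosen
            while k + 1 < len(minima):
                nxt = minima[k + 1]
                if np.max(seg[minima[k] : nxt + 1]) > seg[minima[jb]] + drop_ms:
                    break
                k += 1
                if seg[nxt] < seg[minima[jb]]:
                    jb = k
            imin = minima[jb]
            events.append(
                Event(
                    ptt2.start_time_s + (i0 + imax) * step,
                    ptt2.start_time_s + (i0 + imin) * step,
                    "arousal",
                    value=float(vmax - seg[imin]),
                )
            )
            mi_ptr = jb + 1
            last_min_idx = imin
    return events


def arousal_index(events: list[Event], artifact_free_hours: float) -> float:
    """Arousals per artifact-free hour."""
    if artifact_free_hours <= 0:
        raise ValueError("artifact_free_hours must be positive")
    return len(events) / artifact_free_hours


def respiratory_swing(
    raw_beats: BeatPttSeries,
    artifact_spans: list[Event] | None = None,
    *,
    prominence_ms: float = 1.0,
) -> float:
    """Mean trough-to-peak rise of the breath-cycle PTT oscillation, in ms.

    The per-beat channel is linearly interpolated to 1 Hz, a centered
    3-sample moving mean applied (shrinking at the edges), and alternating
    local minima (inspiratory troughs) and maxima (expiratory peaks) found
    with a 1 ms prominence floor.  Pairs inside or spanning an artifact
    interval are discarded; the swing is the mean of (peak - immediately
    preceding trough).
    """
    from scipy.signal import find_peaks

    artifact_spans = artifact_spans or []
    vt = raw_beats.beat_time_s[raw_beats.valid]
    vv = raw_beats.ptt_ms[raw_beats.valid]
    if len(vt) < 4:
        raise NoSwingError("too few valid beats for a swing estimate")
    t0 = float(np.ceil(vt[0]))
    t1 = float(np.floor(vt[-1]))
    grid = np.arange(t0, t1 + 0.5, 1.0)
    if len(grid) < 3:
        raise NoSwingError("record too short for a swing estimate")
    x = np.interp(grid, vt, vv)
    # centered 3-sample mean, shrinking to 2-sample means at the edges
    sm = x.copy()
    sm[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    sm[0] = (x[0] + x[1]) / 2.0
    sm[-1] = (x[-2] + x[-1]) / 2.0
    peaks, _ = find_peaks(sm, prominence=prominence_ms)
    troughs, _ = find_peaks(-sm, prominence=prominence_ms)
    if len(peaks) == 0 or len(troughs) == 0:
        raise NoSwingError("no trough-to-peak pairs found (channel effectively flat)")

    # merge and enforce alternation, keeping the more extreme of same-type runs
    idx = np.concatenate([peaks, troughs])
    typ = np.concatenate([np.ones(len(peaks), dtype=np.int8), -np.ones(len(troughs), dtype=np.int8)])
    order = np.argsort(idx)
    idx, typ = idx[order], typ[order]
    run_starts = np.flatnonzero(np.diff(np.concatenate(([2], typ))) != 0)
    run_typ = typ[run_starts]
    vals = sm[idx]
    # representative value per run: max for peak runs, min for trough runs
    key = np.where(typ == 1, vals, -vals)
    run_best = np.maximum.reduceat(key, run_starts)
    run_vals = np.where(run_typ == 1, run_best, -run_best)
    trough_first = run_typ[:-1] == -1
    if not artifact_spans:
        rises = (run_vals[1:] - run_vals[:-1])[trough_first]
    else:
        # need the extremum positions to test artifact overlap
        bounds = np.concatenate((run_starts, [len(idx)]))
        run_pos = np.empty(len(run_starts), dtype=np.int64)
        for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            run_pos[k] = idx[a + int(np.argmax(key[a:b]))]
        t_lo = grid[run_pos[:-1]]
        t_hi = grid[run_pos[1:]]
        clean = np.ones(len(t_lo), dtype=bool)
        for e in artifact_spans:
            clean &= ~((e.start_s < t_hi) & (t_lo < e.end_s))
        rises = (run_vals[1:] - run_vals[:-1])[trough_first & clean]
    if len(rises) == 0:
        raise NoSwingError("no artifact-free trough-to-peak pairs")
    return float(np.mean(rises))


def ptt_features_for_record(
    raw_beats: BeatPttSeries,
    *,
    resample_hz: float = 5.0,
    smooth_window: int = 17,
    drop_ms: float = 15.0,
    arousal_window_s: tuple[float, float] = (5.0, 45.0),
    valid_range_ms: tuple[float, float] = VALID_PTT_RANGE_MS,
    spike_ms: float = 50.0,
    artifact_pad_s: float = 2.0,
) -> PttFeatureSet:
    """Full per-record PTT feature chain.

    resample -> artifact spans -> PTT2 -> arousals -> index -> swing.  The
    arousal index denominator is artifact-free PTT hours.  A channel with no
    respiratory oscillation reports a swing of 0.0.
    """
    from .extraction import resample_ptt

    raw = resample_ptt(raw_beats, target_hz=resample_hz)
    artifact_spans = detect_ptt_artifact(
        raw, spike_ms=spike_ms, valid_range_ms=valid_range_ms, pad_s=artifact_pad_s
    )
    mask = raw.artifact_mask | events_to_mask(raw, artifact_spans)
    raw = raw.with_mask(mask)
    artifact_free_hours = raw.unmasked_hours
    ptt2 = smooth_ptt2(raw, window=smooth_window)
    arousals = detect_arousals(
        ptt2,
        drop_ms=drop_ms,
        window_s=arousal_window_s,
        valid_range_ms=valid_range_ms,
        transition_compensation_s=(smooth_window - 1) * raw.step_s,
    )
    index = arousal_index(arousals, artifact_free_hours) if artifact_free_hours > 0 else 0.0
    try:
        swing = respiratory_swing(raw_beats, artifact_spans)
    except NoSwingError:
        swing = 0.0
    return PttFeatureSet(
        ptt_arousal_count=len(arousals),
        ptt_arousal_index=index,
        respiratory_swing_ms=swing,
        artifact_free_hours=artifact_free_hours,
        arousal_events=arousals,
        artifact_spans=artifact_spans,
    )
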