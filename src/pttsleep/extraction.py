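"""Per-beat PTT derivation from ECG and plethysmograph timing.

The transit time of one beat runs from the R-wave midpoint on the ECG to the
point where the following pleth pulse upstroke crosses 50% of its amplitude
(foot + 0.5 * (peak - foot)).  The R-peak detector here is an amplitude
threshold adequate for clean or synthetic signals; it is a pluggable stage,
not a clinical-grade QRS detector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BeatPttSeries, UniformSeries

__all__ = [
    "detect_r_peaks",
    "pleth_half_max_times",
    "compute_beat_ptt",
    "resample_ptt",
    "beat_windows_from_r",
    "read_beat_csv",
    "write_beat_csv",
    "read_spo2_csv",
    "read_edf_channels",
]


def detect_r_peaks(
    ecg: np.ndarray,
    sampling_hz: float,
    *,
    window_s: float = 10.0,
    threshold_frac: float = 0.6,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """R-peak times (s) by local amplitude thresholding.

    The threshold is ``threshold_frac`` times the 99th-percentile amplitude
    within consecutive ``window_s`` blocks; a refractory period suppresses
    double detections.  A flat signal yields an empty array.
    """
    from scipy.signal import find_peaks

    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 10 * sampling_hz:
        raise ValueError("need at least 10 s of ECG signal")
    n = len(ecg)
    block = max(int(round(window_s * sampling_hz)), 1)
    nblocks = int(np.ceil(n / block))
    thr = np.empty(n)
    for b in range(nblocks):
        seg = ecg[b * block : (b + 1) * block]
        thr[b * block : (b + 1) * block] = threshold_frac * np.percentile(seg, 99)
    # flat / near-zero signal: nothing to detect
    if np.max(thr) <= 1e-12:
        return np.array([])
    peaks, _ = find_peaks(ecg, height=thr, distance=max(int(round(refractory_s * sampling_hz)), 1))
    return peaks / sampling_hz


def beat_windows_from_r(r_times: np.ndarray, end_time_s: float | None = None) -> list[tuple[float, float]]:
    """Half-open search windows, one per beat: [r_i, r_{i+1})."""
    r = np.asarray(r_times, dtype=float)
    if len(r) == 0:
        return []
    if end_time_s is None:
        med = np.median(np.diff(r)) if len(r) > 1 else 1.0
        end_time_s = float(r[-1] + med)
    bounds = np.concatenate([r, [end_time_s]])
    return [(float(bounds[i]), float(bounds[i + 1])) for i in range(len(r))]


def pleth_half_max_times(
    pleth: np.ndarray,
    sampling_hz: float,
    beat_windows: list[tuple[float, float]],
    *,
    amplitude_floor_frac: float = 0.05,
) -> np.ndarray:
    """Upstroke half-maximum times, one per beat window where resolvable.

    Per window the pulse peak and the preceding foot (minimum before the
    peak) define the amplitude; the returned time is where the upstroke first
    crosses foot + 0.5*(peak - foot), linearly interpolated between the
    bracketing samples.  Windows whose amplitude falls below
    ``amplitude_floor_frac`` of the median beat amplitude (perfusion
    dropout) yield no event.
    """
    pleth = np.asarray(pleth, dtype=float)
    n = len(pleth)
    spans: list[tuple[int, int]] = []
    for t0, t1 in beat_windows:
        i0 = int(np.ceil(t0 * sampling_hz - 1e-9))
        i1 = int(np.ceil(t1 * sampling_hz - 1e-9))
        if i0 < 0 or i1 > n:
            raise ValueError(f"beat window [{t0}, {t1}) outside signal span")
        spans.append((i0, i1))

    amps = []
    feats = []
    for i0, i1 in spans:
        seg = pleth[i0:i1]
        if len(seg) < 2:
            feats.append(None)
            amps.append(0.0)
            continue
        ipk = int(np.argmax(seg))
        foot = float(np.min(seg[: ipk + 1]))
        amp = float(seg[ipk]) - foot
        feats.append((i0, ipk, foot, amp, seg))
        amps.append(amp)

    median_amp = float(np.median([a for a in amps if a > 0])) if any(a > 0 for a in amps) else 0.0
    out = []
    for feat, amp in zip(feats, amps):
        if feat is None or median_amp <= 0 or amp < amplitude_floor_frac * median_amp:
            continue
        i0, ipk, foot, amp, seg = feat
        level = foot + 0.5 * amp
        up = seg[: ipk + 1]
        # search from the pulse foot (last pre-peak minimum), not the window
        # start: the decaying tail of the previous pulse may still sit above
        # the half-maximum level
        ifoot = int(len(up) - 1 - np.argmin(up[::-1]))
        above = np.flatnonzero(up[ifoot:] >= level) + ifoot
        if len(above) == 0:
            continue
        j = int(above[0])
        if j == ifoot:
            t_cross = i0 + j
        else:
            frac = (level - up[j - 1]) / (up[j] - up[j - 1])
            t_cross = i0 + (j - 1) + frac
        out.append(t_cross / sampling_hz)
    return np.asarray(out)


def compute_beat_ptt(r_times: np.ndarray, pleth_times: np.ndarray) -> BeatPttSeries:
    """Match each R peak to the first pleth event after it and before the next R.

    Unmatched beats are flagged invalid, never dropped, so the beat grid
    stays aligned with the ECG.
    """
    r = np.asarray(r_times, dtype=float)
    p = np.sort(np.asarray(pleth_times, dtype=float))
    ptt = np.full(len(r), np.nan)
    valid = np.zeros(len(r), dtype=bool)
    for i, rt in enumerate(r):
        upper = r[i + 1] if i + 1 < len(r) else np.inf
        j = int(np.searchsorted(p, rt, side="right"))
        if j < len(p) and p[j] < upper:
            ptt[i] = (p[j] - rt) * 1000.0
            valid[i] = True
    ptt[~valid] = 1.0  # placeholder; invalid beats carry no information
    return BeatPttSeries(beat_time_s=r, ptt_ms=ptt, valid=valid)


def resample_ptt(series: BeatPttSeries, target_hz: float = 5.0) -> UniformSeries:
    """Linear interpolation of valid beats onto a uniform grid.

    Grid samples whose bracketing interval spans one or more invalid beats
    are masked: interpolation across a dropout would fabricate values.
    """
    vt = series.beat_time_s[series.valid]
    vv = series.ptt_ms[series.valid]
    if len(vt) < 2:
        raise ValueError("need at least 2 valid beats to resample")
    step = 1.0 / target_hz
    t0 = float(vt[0])
    n = int(np.floor((vt[-1] - t0) / step)) + 1
    grid = t0 + step * np.arange(n)
    vals = np.interp(grid, vt, vv)
    mask = np.zeros(n, dtype=bool)
    for bt in series.beat_time_s[~series.valid]:
        j = int(np.searchsorted(vt, bt))
        lo = vt[j - 1] if j > 0 else -np.inf
        hi = vt[j] if j < len(vt) else np.inf
        # mask grid points strictly between the neighbouring valid beats
        i0 = int(np.floor((lo - t0) / step + 1e-9)) + 1 if np.isfinite(lo) else 0
        i1 = int(np.ceil((hi - t0) / step - 1e-9)) if np.isfinite(hi) else n
        mask[max(i0, 0) : min(max(i1, 0), n)] = True
    return UniformSeries(start_time_s=t0, step_s=step, values=vals, artifact_mask=mask)


# ---------------------------------------------------------------------------
# I/O


def write_beat_csv(series: BeatPttSeries, path) -> None:
    pd.DataFrame(
        {"beat_time_s": series.beat_time_s, "ptt_ms": series.ptt_ms, "valid": series.valid}
    ).to_csv(path, index=False)


def read_beat_csv(path) -> BeatPttSeries:
    df = pd.read_csv(path)
    return BeatPttSeries(
        beat_time_s=df["beat_time_s"].to_numpy(float),
        ptt_ms=df["ptt_ms"].to_numpy(float),
        valid=df["valid"].to_numpy(bool) if "valid" in df else None,
    )


def read_spo2_csv(path) -> UniformSeries:
    """Read a `time_s,spo2_pct` trace; the grid step is inferred from the times."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("SpO2 trace too short")
    step = float(np.median(np.diff(t)))
    return UniformSeries(start_time_s=float(t[0]), step_s=step, values=df["spo2_pct"].to_numpy(float))


def read_edf_channels(path, channels: dict[str, str]) -> dict[str, tuple[np.ndarray, float]]:
    """Read named channels from an EDF recording via mne.

    ``channels`` maps logical names (e.g. "ecg", "pleth", "spo2") to EDF
    channel labels; returns ``{name: (samples, sampling_hz)}``.
    """
    import mne  # optional dependency

    raw = mne.io.read_raw_edf(path, include=list(channels.values()), preload=True, verbose="error")
    out = {}
    for name, label in channels.items():
        if label not in raw.ch_names:
            raise KeyError(f"channel {label!r} not present in {path}")
        data = raw.get_data(picks=[label])[0]
        out[name] = (np.asarray(data, dtype=float), float(raw.info["sfreq"]))
    return out
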