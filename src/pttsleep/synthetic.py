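"""Synthetic multi-channel sleep-study cohorts with known ground truth.

Each child gets a per-beat PTT series (optionally rendered to ECG + pleth
waveforms), a 1 Hz SpO2 trace, and a video/sound annotation bundle, all
consistent with a per-child diagnostic category:

* normal - no snoring, no obstructive episodes, normal oximetry;
* primary snoring - snoring, fewer than 3 obstructive episodes;
* UARS - >= 3 arousal-linked obstructive episodes, normal/inconclusive
  oximetry, high respiratory swing and arousal rate;
* OSA - as UARS plus oximetry meeting the abnormal risk criteria.

The respiratory-swing targets are expressed on the scale of the *measured*
statistic (1 Hz interpolation + 3-sample moving mean): the planted
breath-cycle modulation is pre-compensated by the known gain of that filter
chain, (1 + 2 cos(2*pi/T)) / 3 at breath period T, so a child with target
swing s ms yields a computed swing close to s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BeatPttSeries, Event, UniformSeries
from .classification import VideoAnnotations

__all__ = [
    "CategoryParams",
    "CohortConfig",
    "GroundTruth",
    "SyntheticChild",
    "Cohort",
    "generate_cohort",
    "synthesize_waveforms",
    "plant_arousal",
    "ConfigError",
]

CATEGORIES = ("normal", "primary_snoring", "uars", "osa")


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CategoryParams:
    """Per-category generative settings.

    swing_mean/sd are the target measured respiratory swing (trough-to-peak,
    ms); arousal and desaturation rates are events per hour; desat_depth is
    the dip depth below the SpO2 baseline in percentage points.
    """

    swing_mean_ms: float
    swing_sd_ms: float
    arousal_rate_per_hour: float
    desat_rate_per_hour: float
    desat_depth_pct: tuple[float, float]
    spo2_baseline_pct: float
    snoring: bool
    episode_range: tuple[int, int]
    episodes_arousal_linked: bool


DEFAULT_CATEGORY_PARAMS: dict[str, CategoryParams] = {
    "normal": CategoryParams(12.0, 3.0, 8.0, 0.5, (4.5, 5.5), 97.0, False, (0, 0), False),
    "primary_snoring": CategoryParams(12.0, 3.0, 8.0, 0.5, (4.5, 5.5), 97.0, True, (0, 2), False),
    "uars": CategoryParams(22.0, 4.0, 25.0, 2.0, (4.5, 5.5), 97.0, True, (3, 12), True),
    "osa": CategoryParams(22.0, 4.0, 25.0, 8.0, (7.0, 13.0), 95.0, True, (3, 12), True),
}

# cohort mix: ~35% UARS/OSA, like the 130/368 split of the reference cohort
DEFAULT_CATEGORY_PROBS = {"normal": 0.25, "primary_snoring": 0.40, "uars": 0.24, "osa": 0.11}


@dataclass
class CohortConfig:
    n_children: int = 368
    seed: int = 0
    category_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS))
    study_hours: float = 8.0
    category_params: dict[str, CategoryParams] = field(
        default_factory=lambda: {k: replace(v) for k, v in DEFAULT_CATEGORY_PARAMS.items()}
    )
    ptt_baseline_ms: tuple[float, float] = (300.0, 30.0)  # mean, sd
    artifact_spike_rate_per_hour: float = 3.0
    spo2_dropout_rate_per_hour: float = 0.3
    breath_period_s: tuple[float, float] = (3.45, 3.55)
    heart_period_s: tuple[float, float] = (0.6, 0.75)
    osa_high_risk_fraction: float = 0.3
    beat_noise_ms: float = 2.0
    fidelity: str = "beats"  # "beats" or "waveforms"
    waveform_hz: float = 100.0
    channels: tuple[str, ...] = ("ptt", "spo2", "annotations")

    def validate(self) -> None:
        problems = []
        if self.n_children < 1:
            problems.append("n_children must be >= 1")
        if set(self.category_probs) - set(CATEGORIES):
            problems.append(f"unknown categories: {set(self.category_probs) - set(CATEGORIES)}")
        if abs(sum(self.category_probs.values()) - 1.0) > 1e-9:
            problems.append("category_probs must sum to 1 within 1e-9")
        if any(p < 0 for p in self.category_probs.values()):
            problems.append("category_probs must be non-negative")
        if not 150.0 <= self.ptt_baseline_ms[0] <= 500.0:
            problems.append("ptt baseline mean must lie in [150, 500] ms")
        for name, p in self.category_params.items():
            if p.arousal_rate_per_hour < 0 or p.desat_rate_per_hour < 0:
                problems.append(f"{name}: rates must be >= 0")
        if self.artifact_spike_rate_per_hour < 0:
            problems.append("artifact_spike_rate_per_hour must be >= 0")
        if self.study_hours <= 0:
            problems.append("study_hours must be positive")
        if self.fidelity not in ("beats", "waveforms"):
            problems.append("fidelity must be 'beats' or 'waveforms'")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class GroundTruth:
    """What was planted for one child."""

    category: str
    arousal_times_s: np.ndarray
    desat_intervals: list[tuple[float, float]]
    artifact_spans: list[tuple[float, float]]
    true_swing_ms: float
    n_obstructive: int
    study_hours: float

    def __post_init__(self) -> None:
        span = self.study_hours * 3600.0
        for t in np.atleast_1d(self.arousal_times_s):
            if not 0 <= t <= span:
                raise ValueError("planted arousal outside study duration")
        for a, b in self.desat_intervals + self.artifact_spans:
            if not (0 <= a <= b <= span):
                raise ValueError("planted interval outside study duration")


@dataclass
class SyntheticChild:
    child_id: str
    truth: GroundTruth
    beats: BeatPttSeries | None = None
    spo2: UniformSeries | None = None
    annotations: VideoAnnotations | None = None
    ecg: np.ndarray | None = None
    pleth: np.ndarray | None = None
    waveform_hz: float | None = None


@dataclass
class Cohort:
    config: CohortConfig
    children: list[SyntheticChild]

    def __iter__(self):
        return iter(self.children)

    def __len__(self) -> int:
        return len(self.children)


def plant_arousal(
    series: BeatPttSeries,
    at: float,
    drop_ms: float,
    fall_s: float,
    *,
    hold_s: float = 2.0,
    recover_s: float = 10.0,
) -> BeatPttSeries:
    """Superimpose one arousal-shaped excursion: fall, hold, linear recovery."""
    t0, t1 = series.span_s
    if not t0 <= at <= t1:
        raise ValueError(f"arousal time {at} outside series span [{t0}, {t1}]")
    ptt = series.ptt_ms.copy()
    _apply_arousal_inplace(series.beat_time_s, ptt, at, drop_ms, fall_s, hold_s, recover_s)
    return BeatPttSeries(series.beat_time_s, ptt, series.valid.copy())


def _apply_arousal_inplace(t: np.ndarray, ptt: np.ndarray, at: float, drop_ms: float,
                           fall_s: float, hold_s: float, recover_s: float) -> None:
    i0 = int(np.searchsorted(t, at))
    i1 = int(np.searchsorted(t, at + fall_s + hold_s + recover_s))
    rel = t[i0:i1] - at
    delta = np.where(
        rel < fall_s,
        -drop_ms * rel / fall_s,
        np.where(rel < fall_s + hold_s, -drop_ms, -drop_ms * (1 - (rel - fall_s - hold_s) / recover_s)),
    )
    ptt[i0:i1] += delta


def synthesize_waveforms(
    beat_times: np.ndarray,
    ptt_per_beat_ms: np.ndarray,
    sampling_hz: float,
    *,
    upstroke_s: float = 0.2,
    r_sigma_s: float = 0.008,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a beat/PTT series into ECG and plethysmograph waveforms.

    The ECG holds one Gaussian R wave per beat.  Each pleth pulse rises as a
    raised cosine over ``upstroke_s`` placed so the half-maximum (which by
    symmetry sits at the upstroke midpoint) falls exactly ``ptt`` after the
    R midpoint, then decays back to the foot before the next pulse.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    ptt_s = np.asarray(ptt_per_beat_ms, dtype=float) / 1000.0
    if len(beat_times) != len(ptt_s):
        raise ValueError("beat_times and ptt_per_beat_ms must have equal length")
    if np.any(ptt_s <= 0):
        raise ValueError("PTT values must be positive")
    if len(beat_times) > 1 and np.any(np.diff(beat_times) <= 0.3):
        raise ValueError("beat intervals must exceed 0.3 s")
    if sampling_hz * np.min(ptt_s) < 4:
        raise ValueError(
            f"sampling rate {sampling_hz} Hz too coarse to resolve PTT of {np.min(ptt_s)*1000:.0f} ms"
        )
    duration = beat_times[-1] + ptt_s[-1] + upstroke_s + 1.0
    n = int(np.ceil(duration * sampling_hz))
    tgrid = np.arange(n) / sampling_hz
    ecg = np.zeros(n)
    pleth = np.zeros(n)
    for i, (bt, ptt) in enumerate(zip(beat_times, ptt_s)):
        lo = max(int((bt - 4 * r_sigma_s) * sampling_hz), 0)
        hi = min(int((bt + 4 * r_sigma_s) * sampling_hz) + 1, n)
        ecg[lo:hi] += np.exp(-0.5 * ((tgrid[lo:hi] - bt) / r_sigma_s) ** 2)
        foot = bt + ptt - upstroke_s / 2.0
        peak = foot + upstroke_s
        next_foot = (
            beat_times[i + 1] + ptt_s[i + 1] - upstroke_s / 2.0
            if i + 1 < len(beat_times)
            else peak + 0.6
        )
        lo = max(int(foot * sampling_hz), 0)
        hi = min(int(np.ceil(peak * sampling_hz)) + 1, n)
        seg = tgrid[lo:hi]
        up = (seg >= foot) & (seg <= peak)
        pleth[lo:hi][up] = 0.5 * (1 - np.cos(np.pi * (seg[up] - foot) / upstroke_s))
        lo = hi - 1
        hi = min(int(np.ceil(next_foot * sampling_hz)), n)
        if hi > lo:
            seg = tgrid[lo:hi]
            down = (seg > peak) & (seg < next_foot)
            pleth[lo:hi][down] = 0.5 * (1 + np.cos(np.pi * (seg[down] - peak) / (next_foot - peak)))
    return ecg, pleth


def _poisson_times(rng: np.random.Generator, rate_per_hour: float, span_s: float,
                   margin_s: float, min_gap_s: float) -> np.ndarray:
    """Poisson event times thinned to a minimum separation."""
    lam = rate_per_hour * span_s / 3600.0
    n = rng.poisson(lam)
    if n == 0 or span_s <= 2 * margin_s:
        return np.array([])
    times = np.sort(rng.uniform(margin_s, span_s - margin_s, size=n))
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap_s:
            kept.append(t)
    return np.asarray(kept)


# Residual gain of the swing measurement beyond the 3-sample moving-mean
# attenuation: 1 Hz discretization does not sample the oscillation exactly at
# its crests, so the mean trough-to-peak rise of the discrete channel falls
# short of the continuous one.  Measured once on noiseless synthetic
# sinusoids over the default breath-period range.
SWING_CHAIN_CALIBRATION = 0.785


def _swing_gain(breath_period_s: float) -> float:
    """Gain of the 1 Hz + 3-sample moving-mean chain at the breath frequency."""
    analytic = (1.0 + 2.0 * math.cos(2.0 * math.pi / breath_period_s)) / 3.0
    return analytic * SWING_CHAIN_CALIBRATION


def _generate_child(config: CohortConfig, category: str, child_id: str,
                    rng: np.random.Generator) -> SyntheticChild:
    p = config.category_params[category]
    hours = config.study_hours * rng.uniform(0.85, 1.15)
    span = hours * 3600.0

    baseline_spo2 = p.spo2_baseline_pct
    depth_range = p.desat_depth_pct
    if category == "osa" and rng.uniform() < config.osa_high_risk_fraction:
        # high-risk flavour: depressed baseline and deep dips below 80%
        baseline_spo2 = 93.0
        depth_range = (14.0, 18.0)

    truth_kwargs: dict = {}

    beats = None
    if "ptt" in config.channels:
        period = rng.uniform(*config.heart_period_s)
        intervals = np.clip(rng.normal(period, 0.02, size=int(span / period) + 10), 0.35, None)
        t = np.cumsum(intervals)
        t = t[t < span]
        base_mean, base_sd = config.ptt_baseline_ms
        breath_t = rng.uniform(*config.breath_period_s)
        target_swing = max(rng.normal(p.swing_mean_ms, p.swing_sd_ms), 3.0)
        amp = min(target_swing / _swing_gain(breath_t) / 2.0, 140.0)
        # keep every planted excursion (breath trough + arousal drop + drift +
        # noise) inside the 150-500 ms validity window
        baseline = float(np.clip(rng.normal(base_mean, base_sd), 152.0 + amp + 45.0, 498.0 - amp - 15.0))
        drift = 5.0 * np.sin(2 * np.pi * t / 5400.0 + rng.uniform(0, 2 * np.pi))
        resp = amp * np.sin(2 * np.pi * t / breath_t + rng.uniform(0, 2 * np.pi))
        ptt_vals = np.clip(
            baseline + drift + resp + rng.normal(0.0, config.beat_noise_ms, size=len(t)),
            151.0,
            499.0,
        )
        arousal_times = _poisson_times(rng, p.arousal_rate_per_hour, span, 90.0, 120.0)
        for at in arousal_times:
            _apply_arousal_inplace(
                t,
                ptt_vals,
                at,
                drop_ms=rng.uniform(18.0, 30.0),
                fall_s=rng.uniform(8.0, 25.0),
                hold_s=2.0,
                recover_s=rng.uniform(8.0, 15.0),
            )
        spike_spans = []
        for st in _poisson_times(rng, config.artifact_spike_rate_per_hour, span, 10.0, 60.0):
            width = rng.integers(1, 4)
            i0 = int(np.searchsorted(t, st))
            i1 = min(i0 + width, len(t))
            if i0 >= i1:
                continue
            # dropout rails the channel above the 500 ms validity ceiling
            ptt_vals[i0:i1] = rng.uniform(505.0, 540.0, size=i1 - i0)
            spike_spans.append((float(t[i0]), float(t[i1 - 1])))
        beats = BeatPttSeries(t, ptt_vals)
        truth_kwargs.update(arousal_times_s=arousal_times, artifact_spans=spike_spans,
                            true_swing_ms=target_swing)
    else:
        truth_kwargs.update(arousal_times_s=np.array([]), artifact_spans=[], true_swing_ms=0.0)

    spo2 = None
    desat_intervals: list[tuple[float, float]] = []
    if "spo2" in config.channels:
        n = int(span)
        vals = baseline_spo2 + rng.normal(0.0, 0.2, size=n)
        tgrid = np.arange(n, dtype=float)
        ramp = 3.0
        for dt in _poisson_times(rng, p.desat_rate_per_hour, span, 30.0, 60.0):
            depth = rng.uniform(*depth_range)
            plateau = rng.uniform(10.0, 60.0)
            rel = tgrid - dt
            shape = np.zeros(n)
            rise = (rel >= 0) & (rel < ramp)
            shape[rise] = rel[rise] / ramp
            flat = (rel >= ramp) & (rel < ramp + plateau)
            shape[flat] = 1.0
            fall = (rel >= ramp + plateau) & (rel < 2 * ramp + plateau)
            shape[fall] = 1.0 - (rel[fall] - ramp - plateau) / ramp
            vals -= depth * shape
            desat_intervals.append((float(dt), float(min(dt + 2 * ramp + plateau, span))))
        for st in _poisson_times(rng, config.spo2_dropout_rate_per_hour, span, 10.0, 60.0):
            w = int(rng.uniform(2.0, 5.0))
            i0 = int(st)
            vals[i0 : min(i0 + w, n)] = np.nan
        spo2 = UniformSeries(start_time_s=0.0, step_s=1.0, values=np.clip(vals, 40.0, 100.0))

    annotations = None
    n_obstructive = 0
    if "annotations" in config.channels:
        lo, hi = p.episode_range
        n_obstructive = int(rng.integers(lo, hi + 1))
        episodes, flags = [], []
        for st in np.sort(rng.uniform(300.0, span - 300.0, size=n_obstructive)):
            dur = rng.uniform(10.0, 30.0)
            episodes.append(Event(float(st), float(st + dur), "obstructive"))
            flags.append(bool(p.episodes_arousal_linked))
        annotations = VideoAnnotations(p.snoring, episodes, flags)

    truth = GroundTruth(
        category=category,
        desat_intervals=desat_intervals,
        n_obstructive=n_obstructive,
        study_hours=hours,
        **truth_kwargs,
    )
    child = SyntheticChild(child_id=child_id, truth=truth, beats=beats, spo2=spo2,
                           annotations=annotations)
    if config.fidelity == "waveforms" and beats is not None:
        ecg, pleth = synthesize_waveforms(beats.beat_time_s, beats.ptt_ms, config.waveform_hz)
        child.ecg, child.pleth, child.waveform_hz = ecg, pleth, config.waveform_hz
    return child


def generate_cohort(config: CohortConfig) -> Cohort:
    """Deterministically generate a cohort (same config + seed => same cohort)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    cat_rng = np.random.default_rng(root.spawn(1)[0])
    names = list(CATEGORIES)
    probs = np.array([config.category_probs.get(c, 0.0) for c in names])
    labels = cat_rng.choice(names, size=config.n_children, p=probs / probs.sum())
    children = []
    for i, (label, ss) in enumerate(zip(labels, root.spawn(config.n_children + 1)[1:])):
        children.append(_generate_child(config, str(label), f"child{i:04d}", np.random.default_rng(ss)))
    return Cohort(config=config, children=children)
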