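"""Oximetry desaturation events, dip index, and the OSA risk category.

A desaturation (dip) is an excursion of more than 4 percentage points below
the baseline saturation lasting more than 5 s and less than 180 s; the dip
index is dips per artifact-free hour.  Baseline saturation is the median of
the artifact-free trace — robust, reproducible, and insensitive to the dips
themselves.  The four-way risk category (normal / inconclusive / abnormal
low-risk / abnormal high-risk) is the perioperative risk stratification used
by pediatric sleep services; "abnormal" means either abnormal tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import Event, UniformSeries, events_to_mask, mask_to_events, merge_events

__all__ = [
    "OximetryCategory",
    "OximetryFeatureSet",
    "detect_spo2_artifact",
    "detect_desaturations",
    "oximetry_summary",
    "categorize_oximetry",
    "oximetry_features_for_record",
]


class OximetryCategory(str, Enum):
    NORMAL = "normal"
    INCONCLUSIVE = "inconclusive"
    ABNORMAL_LOW_RISK = "abnormal_low_risk"
    ABNORMAL_HIGH_RISK = "abnormal_high_risk"

    @property
    def is_abnormal(self) -> bool:
        return self in (OximetryCategory.ABNORMAL_LOW_RISK, OximetryCategory.ABNORMAL_HIGH_RISK)


@dataclass
class OximetryFeatureSet:
    mean_spo2_pct: float
    min_spo2_pct: float
    baseline_spo2_pct: float
    dip_index_per_hour: float
    desat_events: list[Event] = field(default_factory=list)
    artifact_free_hours: float = 0.0
    category: OximetryCategory = OximetryCategory.NORMAL
    sufficient_data: bool = True  # >= 4 h artifact-free for a reportable study


def detect_spo2_artifact(
    spo2: UniformSeries,
    *,
    floor_pct: float = 50.0,
    max_rate_pct_per_s: float = 4.0,
) -> list[Event]:
    """Spans of physiologically impossible SpO2: dropout, <50%, or >4%/s jumps."""
    v = spo2.values
    n = len(v)
    bad = ~np.isfinite(v) | (v < floor_pct)
    if n > 1:
        jump = np.abs(np.diff(v)) > max_rate_pct_per_s * spo2.step_s
        bad[:-1] |= jump
        bad[1:] |= jump
    bad |= spo2.artifact_mask
    if not bad.any():
        return []
    return merge_events(mask_to_events(spo2, bad, kind="spo2_artifact"), kind="spo2_artifact")


def detect_desaturations(
    spo2: UniformSeries,
    baseline: float,
    *,
    drop_pct: float = 4.0,
    min_duration_s: float = 5.0,
    max_duration_s: float = 180.0,
) -> list[Event]:
    """Maximal artifact-free spans with SpO2 strictly below baseline - drop_pct.

    Spans must last more than ``min_duration_s`` and less than
    ``max_duration_s`` (both strict); longer excursions are baseline shifts
    or artifact, not discrete dips.
    """
    low = (spo2.values < baseline - drop_pct) & ~spo2.artifact_mask
    events = []
    for e in mask_to_events(spo2, low, kind="desaturation"):
        if min_duration_s < e.duration_s < max_duration_s:
            i0 = int(round((e.start_s - spo2.start_time_s) / spo2.step_s))
            i1 = int(round((e.end_s - spo2.start_time_s) / spo2.step_s))
            depth = baseline - float(np.min(spo2.values[i0:i1]))
            events.append(Event(e.start_s, e.end_s, "desaturation", value=depth))
    return events


def categorize_oximetry(baseline: float, dip_index: float, min_spo2: float) -> OximetryCategory:
    """Four-way OSA risk category from baseline, dip index and minimum saturation.

    Precedence: abnormal high-risk (min < 80 with dip index > 4/h and
    baseline < 94) -> abnormal low-risk (min <= 90) -> normal (baseline > 94
    and dip index < 4/h) -> inconclusive.  The function is total and never
    moves toward normal as the minimum saturation falls.
    """
    for x in (baseline, dip_index, min_spo2):
        if not np.isfinite(x):
            raise ValueError("oximetry category inputs must be finite")
    if min_spo2 < 80 and dip_index > 4 and baseline < 94:
        return OximetryCategory.ABNORMAL_HIGH_RISK
    if min_spo2 <= 90:
        return OximetryCategory.ABNORMAL_LOW_RISK
    if baseline > 94 and dip_index < 4:
        return OximetryCategory.NORMAL
    return OximetryCategory.INCONCLUSIVE


def oximetry_summary(
    spo2: UniformSeries,
    events: list[Event],
    *,
    min_hours: float = 4.0,
) -> OximetryFeatureSet:
    """Mean/min/baseline over unmasked samples plus dip index and category.

    Records with fewer than ``min_hours`` artifact-free are flagged
    ``sufficient_data=False`` — reported, never silently dropped.
    """
    good = ~spo2.artifact_mask
    if not good.any():
        raise ValueError("no artifact-free SpO2 samples")
    vals = spo2.values[good]
    hours = spo2.unmasked_hours
    dip_index = len(events) / hours if hours > 0 else 0.0
    baseline = float(np.median(vals))
    feats = OximetryFeatureSet(
        mean_spo2_pct=float(np.mean(vals)),
        min_spo2_pct=float(np.min(vals)),
        baseline_spo2_pct=baseline,
        dip_index_per_hour=dip_index,
        desat_events=list(events),
        artifact_free_hours=hours,
        category=categorize_oximetry(baseline, dip_index, float(np.min(vals))),
        sufficient_data=hours >= min_hours,
    )
    return feats


def oximetry_features_for_record(spo2: UniformSeries, *, min_hours: float = 4.0) -> OximetryFeatureSet:
    """Artifact mask -> baseline -> dips -> summary, as one call."""
    artifact = detect_spo2_artifact(spo2)
    masked = spo2.with_mask(spo2.artifact_mask | events_to_mask(spo2, artifact))
    good = ~masked.artifact_mask
    if not good.any():
        raise ValueError("no artifact-free SpO2 samples")
    baseline = float(np.median(masked.values[good]))
    events = detect_desaturations(masked, baseline)
    return oximetry_summary(masked, events, min_hours=min_hours)
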