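"""Sleep-study categories from oximetry plus video/sound annotations.

Video scoring is upstream of this package: annotations record whether
snoring was heard and the timed obstructive episodes (a pause in snoring
with continued respiratory effort, ending in an airway-opening noise), each
flagged when linked to a movement-plus-pulse-rate-rise arousal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

from .core import Event
from .oximetry import OximetryCategory, OximetryFeatureSet
from .ptt_features import PttFeatureSet

__all__ = [
    "StudyCategory",
    "VideoAnnotations",
    "StudyRecord",
    "classify_study",
    "apply_exclusions",
    "read_annotations_json",
    "write_annotations_json",
]


class StudyCategory(str, Enum):
    NORMAL = "normal"
    PRIMARY_SNORING = "primary_snoring"
    UARS = "uars"
    OSA = "osa"
    ABNORMAL_OTHER = "abnormal_other"


@dataclass
class VideoAnnotations:
    snoring_present: bool
    obstructive_episodes: list[Event] = field(default_factory=list)
    arousal_linked: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.arousal_linked) != len(self.obstructive_episodes):
            raise ValueError("arousal_linked must flag every obstructive episode")

    @property
    def n_episodes(self) -> int:
        return len(self.obstructive_episodes)

    @property
    def n_arousal_linked(self) -> int:
        return sum(self.arousal_linked)


def classify_study(
    oximetry_category: OximetryCategory,
    video: VideoAnnotations,
    *,
    uars_min_episodes: int = 3,
    osa_min_episodes: int = 1,
) -> StudyCategory:
    """Five-way study category.

    With abnormal oximetry: obstructed breathing with arousals (>=
    ``osa_min_episodes`` arousal-linked episodes) is OSA; no video evidence
    of obstruction is "abnormal other".  With normal/inconclusive oximetry:
    >= ``uars_min_episodes`` arousal-linked episodes is UARS; any snoring or
    lesser obstruction is primary snoring; otherwise normal.  Total over all
    inputs.
    """
    if oximetry_category.is_abnormal:
        if video.n_arousal_linked >= osa_min_episodes:
            return StudyCategory.OSA
        return StudyCategory.ABNORMAL_OTHER
    if video.n_arousal_linked >= uars_min_episodes:
        return StudyCategory.UARS
    if video.snoring_present or video.n_episodes > 0:
        return StudyCategory.PRIMARY_SNORING
    return StudyCategory.NORMAL


@dataclass
class StudyRecord:
    """One child's per-study summary with inclusion flags."""

    child_id: str
    oximetry: OximetryFeatureSet
    video: VideoAnnotations
    ptt: PttFeatureSet | None = None
    study_category: StudyCategory | None = None
    included_oximetry: bool = False
    included_ptt: bool = False
    included_ptt_roc: bool = False  # PTT threshold analysis excludes "abnormal other"


def apply_exclusions(
    record: StudyRecord,
    *,
    min_oximetry_hours: float = 4.0,
    min_ptt_hours: float = 3.0,
) -> StudyRecord:
    """Set inclusion flags and the study category.

    A study needs >= 4 artifact-free oximetry hours to be reportable at all;
    the PTT analysis additionally needs >= 3 artifact-free PTT hours; the
    PTT threshold (ROC) analysis further drops "abnormal other" children,
    whose findings stem from causes unrelated to obstruction.
    """
    record.included_oximetry = (
        record.oximetry.artifact_free_hours >= min_oximetry_hours and record.oximetry.sufficient_data
    )
    if record.included_oximetry:
        record.study_category = classify_study(record.oximetry.category, record.video)
    else:
        record.study_category = None
    record.included_ptt = (
        record.included_oximetry
        and record.ptt is not None
        and record.ptt.artifact_free_hours >= min_ptt_hours
    )
    record.included_ptt_roc = (
        record.included_ptt and record.study_category != StudyCategory.ABNORMAL_OTHER
    )
    return record


def write_annotations_json(video: VideoAnnotations, path) -> None:
    payload = {
        "snoring": bool(video.snoring_present),
        "episodes": [
            {"start_s": e.start_s, "end_s": e.end_s, "arousal_linked": bool(a)}
            for e, a in zip(video.obstructive_episodes, video.arousal_linked)
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_annotations_json(path) -> VideoAnnotations:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    episodes = [Event(ep["start_s"], ep["end_s"], "obstructive") for ep in payload["episodes"]]
    flags = [bool(ep["arousal_linked"]) for ep in payload["episodes"]]
    return VideoAnnotations(bool(payload["snoring"]), episodes, flags)
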