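"""End-to-end orchestration: simulate -> featurize -> classify -> evaluate.

Every rule constant of the protocol is a named ``PipelineConfig`` field with
the published default, so sensitivity analyses can move one dial at a time;
the run manifest embeds the seed, the config and its hash so any report can
be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import StudyCategory, StudyRecord, apply_exclusions
from .diagnostics import (
    LabeledValues,
    bootstrap_ci,
    evaluate_threshold,
    roc_curve,
    select_thresholds,
    split_train_test,
)
from .oximetry import oximetry_features_for_record
from .ptt_features import ptt_features_for_record
from .synthetic import CohortConfig, ConfigError, generate_cohort

logger = logging.getLogger("pttsleep")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "records_to_frame"]


@dataclass
class PipelineConfig:
    """All protocol constants, with published defaults, plus run settings."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    n_boot: int = 2000
    # PTT rules
    resample_hz: float = 5.0
    smooth_window: int = 17
    arousal_drop_ms: float = 15.0
    arousal_window_s: tuple[float, float] = (5.0, 45.0)
    valid_range_ms: tuple[float, float] = (150.0, 500.0)
    spike_ms: float = 50.0
    artifact_pad_s: float = 2.0
    # oximetry rules
    dip_drop_pct: float = 4.0
    dip_duration_s: tuple[float, float] = (5.0, 180.0)
    # exclusion rules
    min_oximetry_hours: float = 4.0
    min_ptt_hours: float = 3.0
    # threshold targets
    target_rate: float = 0.90
    output_dir: str | None = None


_KNOWN_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(config: PipelineConfig | dict) -> PipelineConfig:
    """Range-check a config, collecting every violation into one error."""
    if isinstance(config, dict):
        unknown = set(config) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cohort = config.pop("cohort", None)
        config = PipelineConfig(**config)
        if isinstance(cohort, dict):
            config.cohort = CohortConfig(**cohort)
        elif cohort is not None:
            config.cohort = cohort
    problems = []
    try:
        config.cohort.validate()
    except ConfigError as exc:
        problems.append(str(exc))
    if config.n_boot < 100:
        problems.append("n_boot must be >= 100")
    if config.arousal_drop_ms <= 0:
        problems.append("arousal_drop_ms must be positive")
    if not config.arousal_window_s[0] < config.arousal_window_s[1]:
        problems.append("arousal_window_s must be (low, high) with low < high")
    if not config.valid_range_ms[0] < config.valid_range_ms[1]:
        problems.append("valid_range_ms must be (low, high) with low < high")
    if config.dip_drop_pct <= 0:
        problems.append("dip_drop_pct must be positive")
    if not config.dip_duration_s[0] < config.dip_duration_s[1]:
        problems.append("dip_duration_s must be (low, high) with low < high")
    if config.spike_ms <= 0:
        problems.append("spike_ms must be positive")
    if config.smooth_window < 3 or config.smooth_window % 2 == 0:
        problems.append("smooth_window must be an odd integer >= 3")
    if not 0 < config.target_rate <= 1:
        problems.append("target_rate must be in (0, 1]")
    if min(config.min_oximetry_hours, config.min_ptt_hours) < 0:
        problems.append("exclusion hour thresholds must be >= 0")
    if problems:
        raise ConfigError("; ".join(problems))
    return config


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohort"]["category_params"] = {
        k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        for k, v in d["cohort"]["category_params"].items()
    }
    return d


def records_to_frame(records: list[StudyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "child_id": r.child_id,
                "study_category": r.study_category.value if r.study_category else None,
                "oximetry_category": r.oximetry.category.value,
                "mean_spo2_pct": r.oximetry.mean_spo2_pct,
                "min_spo2_pct": r.oximetry.min_spo2_pct,
                "baseline_spo2_pct": r.oximetry.baseline_spo2_pct,
                "dip_index_per_hour": r.oximetry.dip_index_per_hour,
                "oximetry_hours": r.oximetry.artifact_free_hours,
                "ptt_arousal_index": r.ptt.ptt_arousal_index if r.ptt else None,
                "respiratory_swing_ms": r.ptt.respiratory_swing_ms if r.ptt else None,
                "ptt_hours": r.ptt.artifact_free_hours if r.ptt else None,
                "included_oximetry": r.included_oximetry,
                "included_ptt": r.included_ptt,
                "included_ptt_roc": r.included_ptt_roc,
            }
        )
    return pd.DataFrame(rows)


def _evaluate_index(records: list[StudyRecord], attr: str, config: PipelineConfig) -> dict:
    """Train/test ROC analysis of one PTT index over the ROC-eligible records."""
    eligible = [r for r in records if r.included_ptt_roc]
    train, test = split_train_test(eligible, seed=config.seed)

    def labeled(rs: list[StudyRecord]) -> LabeledValues:
        values = np.array([getattr(r.ptt, attr) for r in rs])
        labels = np.array([r.study_category in (StudyCategory.UARS, StudyCategory.OSA) for r in rs])
        return LabeledValues(values, labels)

    roc = roc_curve(labeled(train))
    roc.selected = select_thresholds(roc)
    thr = roc.selected.max_sum_threshold
    train_table, train_sens, train_spec = evaluate_threshold(labeled(train), thr)
    test_table, test_sens, test_spec = evaluate_threshold(labeled(test), thr)
    ci = bootstrap_ci(labeled(test), thr, n_boot=config.n_boot, seed=config.seed + 1)
    return {
        "index": attr,
        "n_train": len(train),
        "n_test": len(test),
        "auc_train": roc.auc,
        "thresholds": {
            "max_sum": thr,
            "sens90": roc.selected.sens90_threshold,
            "spec90": roc.selected.spec90_threshold,
        },
        "train": {"sensitivity": train_sens, "specificity": train_spec,
                  "table": dataclasses.asdict(train_table)},
        "test": {"sensitivity": test_sens, "specificity": test_spec,
                 "table": dataclasses.asdict(test_table)},
        "test_bootstrap_ci": ci,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate a cohort, compute all features, classify, and evaluate thresholds.

    Returns a report dict with the per-child record table, the two ROC
    evaluations (respiratory swing and arousal index) and a manifest; writes
    CSV/JSON to ``config.output_dir`` when set.  Idempotent per seed.
    """
    config = validate_config(config)
    config.cohort.seed = config.seed
    cohort = generate_cohort(config.cohort)
    records: list[StudyRecord] = []
    for child in cohort:
        if child.spo2 is None or child.annotations is None or child.beats is None:
            raise ValueError(f"record {child.child_id}: pipeline needs ptt, spo2 and annotation channels")
        oxi = oximetry_features_for_record(child.spo2, min_hours=config.min_oximetry_hours)
        ptt = ptt_features_for_record(
            child.beats,
            resample_hz=config.resample_hz,
            smooth_window=config.smooth_window,
            drop_ms=config.arousal_drop_ms,
            arousal_window_s=config.arousal_window_s,
            valid_range_ms=config.valid_range_ms,
            spike_ms=config.spike_ms,
            artifact_pad_s=config.artifact_pad_s,
        )
        record = StudyRecord(child_id=child.child_id, oximetry=oxi, video=child.annotations, ptt=ptt)
        record = apply_exclusions(
            record,
            min_oximetry_hours=config.min_oximetry_hours,
            min_ptt_hours=config.min_ptt_hours,
        )
        if not record.included_oximetry:
            logger.warning("%s excluded: <%.0f h artifact-free oximetry", child.child_id,
                           config.min_oximetry_hours)
        elif not record.included_ptt:
            logger.warning("%s excluded from PTT analysis: <%.0f h artifact-free PTT",
                           child.child_id, config.min_ptt_hours)
        records.append(record)

    frame = records_to_frame(records)
    diagnostics = {
        "respiratory_swing_ms": _evaluate_index(records, "respiratory_swing_ms", config),
        "ptt_arousal_index": _evaluate_index(records, "ptt_arousal_index", config),
    }
    cfg_dict = _config_dict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    report = {
        "manifest": {
            "seed": config.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "n_children": len(records),
        },
        "records": frame,
        "diagnostics": diagnostics,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "study_records.csv", index=False)
        with open(out / "diagnostics.json", "w", encoding="utf-8") as fh:
            json.dump({k: v for k, v in report.items() if k != "records"}, fh, indent=1, default=str)
    return report
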