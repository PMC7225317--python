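"""Printed summary counts of the reference clinical cohort.

These are the published cross-tabulations from the 521-child secondary-care
cohort whose protocol this package implements (oximetry + video/sound
multi-channel studies; 368 children with analyzable PTT).  They are inputs:
every derived rate below is recomputed at run time by the diagnostics
operations, never stored.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import (
    ContingencyTable2x2,
    LabeledValues,
    chi_square_2x2,
    contingency_accuracy,
    evaluate_threshold,
)

__all__ = [
    "OXIMETRY_BY_VIDEO_COUNTS",
    "SWING_THRESHOLD_COUNTS",
    "UARS_SUBGROUP_COUNTS",
    "SWING_THRESHOLD_MS",
    "oximetry_screening_accuracy",
    "swing_threshold_performance",
    "uars_subgroup_chi2",
    "labeled_values_from_counts",
]

# rows: (normal, inconclusive, abnormal) oximetry category
# cols: (normal or primary snoring, UARS or OSA) video/multi-channel finding
OXIMETRY_BY_VIDEO_COUNTS = np.array(
    [
        [153, 43],
        [180, 69],
        [6, 70],
    ]
)

# children above/below the 17.92 ms respiratory-swing threshold
SWING_THRESHOLD_MS = 17.92
SWING_THRESHOLD_COUNTS = {
    "training": {"above_pos": 57, "below_pos": 14, "above_neg": 24, "below_neg": 95},
    "test": {"above_pos": 44, "below_pos": 15, "above_neg": 33, "below_neg": 86},
}

# normal/inconclusive-oximetry subgroup: swing above/below threshold
# rows: (UARS, normal or primary snoring); cols: (above, below)
UARS_SUBGROUP_COUNTS = np.array(
    [
        [43, 13],
        [25, 96],
    ]
)


def oximetry_screening_accuracy() -> dict[str, float]:
    """Sensitivity/specificity of abnormal oximetry for UARS/OSA, plus totals."""
    sens, spec = contingency_accuracy(OXIMETRY_BY_VIDEO_COUNTS)
    total = int(OXIMETRY_BY_VIDEO_COUNTS.sum())
    inconclusive = int(OXIMETRY_BY_VIDEO_COUNTS[1].sum())
    return {
        "sensitivity": round(sens, 2),
        "specificity": round(spec, 2),
        "n_children": total,
        "n_uars_osa": int(OXIMETRY_BY_VIDEO_COUNTS[:, 1].sum()),
        "inconclusive_pct": round(100.0 * inconclusive / total),
    }


def labeled_values_from_counts(counts: dict[str, int], threshold: float) -> LabeledValues:
    """Reconstruct a LabeledValues sample consistent with above/below counts."""
    values = np.concatenate(
        [
            np.full(counts["above_pos"], threshold + 1.0),
            np.full(counts["below_pos"], threshold - 1.0),
            np.full(counts["above_neg"], threshold + 1.0),
            np.full(counts["below_neg"], threshold - 1.0),
        ]
    )
    labels = np.concatenate(
        [
            np.ones(counts["above_pos"] + counts["below_pos"], dtype=bool),
            np.zeros(counts["above_neg"] + counts["below_neg"], dtype=bool),
        ]
    )
    return LabeledValues(values, labels)


def swing_threshold_performance() -> dict[str, dict]:
    """Train/test sensitivity-specificity at the published swing threshold."""
    out: dict[str, dict] = {}
    grand_total = 0
    for split, counts in SWING_THRESHOLD_COUNTS.items():
        data = labeled_values_from_counts(counts, SWING_THRESHOLD_MS)
        table, sens, spec = evaluate_threshold(data, SWING_THRESHOLD_MS)
        out[split] = {
            "sensitivity": round(sens, 2),
            "specificity": round(spec, 2),
            "n": table.total,
        }
        grand_total += table.total
    out["overall_total"] = grand_total
    return out


def uars_subgroup_chi2() -> tuple[float, float]:
    """Chi-square for swing-above-threshold vs UARS in the inconclusive-oximetry subgroup."""
    t = ContingencyTable2x2(
        tp=int(UARS_SUBGROUP_COUNTS[0, 0]),
        fn=int(UARS_SUBGROUP_COUNTS[0, 1]),
        fp=int(UARS_SUBGROUP_COUNTS[1, 0]),
        tn=int(UARS_SUBGROUP_COUNTS[1, 1]),
    )
    return chi_square_2x2(t)
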