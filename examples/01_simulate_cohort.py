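"""Generate a small synthetic sleep-study cohort and look at its ground truth.

Each child carries a per-beat PTT series, a 1 Hz SpO2 trace and video/sound
annotations, all consistent with its diagnostic category (normal, primary
snoring, UARS, OSA).
"""

from collections import Counter

from pttsleep import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_children=12, seed=1, study_hours=6.0))

print("category mix:", dict(Counter(ch.truth.category for ch in cohort)))
for ch in list(cohort)[:4]:
    t = ch.truth
    print(
        f"{ch.child_id}: {t.category:16s} {t.study_hours:.1f} h, "
        f"{len(t.arousal_times_s)} planted arousals, "
        f"{len(t.desat_intervals)} desaturations, "
        f"target swing {t.true_swing_ms:.1f} ms, "
        f"{t.n_obstructive} obstructive episodes"
    )
# UARS/OSA children carry larger swings and more arousals than normal/snoring
# children; OSA children additionally desaturate below 90%.
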