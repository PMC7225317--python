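"""PTT2 smoothing, artifact spans, arousal rule, and respiratory swing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pttsleep import (
    arousal_index,
    detect_arousals,
    detect_ptt_artifact,
    ptt_features_for_record,
    respiratory_swing,
    smooth_ptt2,
)
from pttsleep.core import BeatPttSeries, Event, UniformSeries, events_to_mask
from pttsleep.ptt_features import NoSwingError


def uniform(values, step=0.2, mask=None, start=0.0):
    return UniformSeries(start_time_s=start, step_s=step, values=np.asarray(values, float),
                         artifact_mask=mask)


class TestSmoothPtt2:
    def test_constant_stays_constant(self):
        out = smooth_ptt2(uniform(np.full(100, 250.0)))
        good = ~out.artifact_mask
        assert good.sum() == 100 - 16
        assert np.allclose(out.values[good], 250.0)

    def test_single_impulse_spreads_as_mean(self):
        v = np.zeros(51)
        v[25] = 170.0
        out = smooth_ptt2(uniform(v))
        assert out.values[25] == pytest.approx(10.0)  # 170 / 17

    def test_edges_are_masked(self):
        out = smooth_ptt2(uniform(np.full(40, 300.0)))
        assert out.artifact_mask[:8].all() and out.artifact_mask[-8:].all()

    def test_mostly_masked_windows_propagate_mask(self):
        v = np.full(60, 300.0)
        mask = np.zeros(60, bool)
        mask[20:40] = True
        out = smooth_ptt2(uniform(v, mask=mask))
        # centre of the masked block has no usable window
        assert out.artifact_mask[25:35].all()

    def test_matches_brute_force_windowed_mean(self, rng):
        """Cumulative-sum smoothing equals the O(n*w) definition everywhere."""
        for _ in range(100):
            n = int(rng.integers(17, 60))
            v = rng.uniform(150, 500, n)
            mask = rng.uniform(size=n) < 0.2
            out = smooth_ptt2(uniform(v, mask=mask.copy()))
            for i in range(8, n - 8):
                w_v = v[i - 8 : i + 9]
                w_m = mask[i - 8 : i + 9]
                if (~w_m).sum() >= 9:
                    assert not out.artifact_mask[i]
                    assert out.values[i] == pytest.approx(w_v[~w_m].mean())
                else:
                    assert out.artifact_mask[i]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_ptt2(uniform(np.full(10, 300.0)))


class TestDetectPttArtifact:
    def test_clean_constant_has_no_spans(self):
        assert detect_ptt_artifact(uniform(np.full(100, 300.0))) == []

    def test_single_spike_padded_span(self):
        v = np.full(100, 300.0)
        v[50] = 420.0
        spans = detect_ptt_artifact(uniform(v))
        assert len(spans) == 1
        assert spans[0].start_s <= 50 * 0.2 - 2.0 + 0.21
        assert spans[0].end_s >= 50 * 0.2 + 2.0 - 0.21

    def test_out_of_range_value_flagged(self):
        v = np.full(100, 300.0)
        v[40:50] = 600.0  # 2 s outside the 150-500 ms valid range
        spans = detect_ptt_artifact(uniform(v))
        assert len(spans) == 1
        assert spans[0].start_s < 40 * 0.2 < 50 * 0.2 < spans[0].end_s

    def test_spans_merge_when_overlapping(self):
        v = np.full(100, 300.0)
        v[30] = 420.0
        v[35] = 420.0
        spans = detect_ptt_artifact(uniform(v))
        assert len(spans) == 1


def _drop_series(drop, fall, n=3000, base=300.0, step=0.2, at=300.0, hold=10.0):
    t = np.arange(n) * step
    v = np.full(n, base)
    rel = t - at
    falling = (rel >= 0) & (rel < fall)
    v[falling] -= drop * rel[falling] / fall
    v[(rel >= fall) & (rel < fall + hold)] -= drop
    rec = (rel >= fall + hold) & (rel < fall + hold + 20.0)
    v[rec] -= drop * (1 - (rel[rec] - fall - hold) / 20.0)
    return smooth_ptt2(uniform(v, step=step))


class TestDetectArousals:
    def test_constant_series_has_no_events(self):
        out = smooth_ptt2(uniform(np.full(300, 300.0)))
        assert detect_arousals(out) == []

    def test_single_qualifying_drop(self):
        events = detect_arousals(_drop_series(20.0, 10.0))
        assert len(events) == 1
        assert events[0].value >= 15.0

    def test_subthreshold_drop_ignored(self):
        assert detect_arousals(_drop_series(10.0, 10.0)) == []

    def test_too_fast_and_too_slow_drops_ignored(self):
        assert detect_arousals(_drop_series(20.0, 2.0)) == []
        assert detect_arousals(_drop_series(20.0, 50.0)) == []

    def test_drop_outside_valid_range_ignored(self):
        # baseline 140 ms sits below the 150 ms validity floor
        assert detect_arousals(_drop_series(20.0, 10.0, base=140.0)) == []

    def test_event_interval_is_half_open_fall(self):
        (e,) = detect_arousals(_drop_series(20.0, 10.0, at=300.0))
        assert 280.0 < e.start_s < 302.0
        assert e.end_s > e.start_s

    def test_zero_hours_rejected(self):
        with pytest.raises(ValueError):
            arousal_index([], 0.0)
        assert arousal_index([], 2.0) == 0.0
        assert arousal_index([Event(0, 1)] * 8, 4.0) == pytest.approx(2.0)

    @given(st.integers(0, 29))
    def test_masking_never_increases_event_count(self, seed):
        """Adding artifact spans can only remove arousals, never create them."""
        rng = np.random.default_rng(seed)
        t = np.arange(4000) * 0.2
        v = 300 + 8 * np.sin(2 * np.pi * t / 40.0) + rng.normal(0, 3, len(t))
        for at in (120.0, 400.0, 650.0):
            rel = t - at
            f = (rel >= 0) & (rel < 12)
            v[f] -= 22 * rel[f] / 12
            v[(rel >= 12) & (rel < 16)] -= 22
            r = (rel >= 16) & (rel < 28)
            v[r] -= 22 * (1 - (rel[r] - 16) / 12)
        base = smooth_ptt2(uniform(v))
        n_base = len(detect_arousals(base))
        a, b = sorted(rng.uniform(0, 780, 2))
        spans = [Event(float(a), float(b), "artifact")]
        masked = base.with_mask(base.artifact_mask | events_to_mask(base, spans))
        assert len(detect_arousals(masked)) <= n_base


class TestRespiratorySwing:
    def test_constant_channel_raises(self):
        t = np.arange(1.0, 1200.0, 0.7)
        with pytest.raises(NoSwingError):
            respiratory_swing(BeatPttSeries(t, np.full(len(t), 300.0)))

    def test_sinusoid_matches_closed_form_attenuation(self):
        """At 1 Hz beats and period 4 s the 3-sample mean gain is exactly 1/3.

        Beat samples of A*sin(pi*t/2) cycle through 0, A, 0, -A, so the
        smoothed channel oscillates between -A/3 and A/3: swing = 2A/3.
        """
        t = np.arange(1.0, 1200.0)  # beats exactly on the 1 Hz grid
        A = 9.0
        v = 300.0 + A * np.sin(2 * np.pi * t / 4.0)
        swing = respiratory_swing(BeatPttSeries(t, v))
        assert swing == pytest.approx(2 * A / 3, rel=0.01)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.uniform(0.6, 0.75, 4000))
        base = 20 * np.sin(2 * np.pi * t / 3.5)
        k = 2.7
        s1 = respiratory_swing(BeatPttSeries(t, 300 + base))
        s2 = respiratory_swing(BeatPttSeries(t, 300 + k * base))
        assert s2 / s1 == pytest.approx(k, rel=0.01)

    def test_pairs_inside_artifact_spans_excluded(self):
        rng = np.random.default_rng(4)
        t = np.cumsum(rng.uniform(0.6, 0.75, 4000))
        v = 300 + 10 * np.sin(2 * np.pi * t / 3.5)
        # corrupt one stretch with a huge excursion and mark it as artifact
        bad = (t > 800) & (t < 900)
        v[bad] += 150.0
        spans = [Event(795.0, 905.0, "artifact")]
        clean = respiratory_swing(BeatPttSeries(t, v), spans)
        reference = respiratory_swing(BeatPttSeries(t[~bad], v[~bad]))
        assert clean == pytest.approx(reference, rel=0.05)

    def test_group_separation_matches_construction(self, clean_cohort):
        """UARS/OSA children show larger swings than normal/snoring children."""
        swings = {"pos": [], "neg": []}
        for ch in clean_cohort:
            s = respiratory_swing(ch.beats)
            swings["pos" if ch.truth.category in ("uars", "osa") else "neg"].append(s)
        assert np.mean(swings["pos"]) > np.mean(swings["neg"])


class TestRecordComposition:
    def test_constant_baseline_child_is_quiet(self):
        t = np.arange(1.0, 4 * 3600.0, 0.7)
        feats = ptt_features_for_record(BeatPttSeries(t, np.full(len(t), 300.0)))
        assert feats.ptt_arousal_count == 0
        assert feats.ptt_arousal_index == 0.0
        assert feats.respiratory_swing_ms == 0.0
        assert feats.artifact_free_hours == pytest.approx(4.0, abs=0.02)

    def test_planted_counts_recovered(self, clean_cohort):
        hits = 0
        for ch in clean_cohort:
            feats = ptt_features_for_record(ch.beats)
            hits += feats.ptt_arousal_count == len(ch.truth.arousal_times_s)
        assert hits >= 0.95 * len(clean_cohort)

    def test_artifact_spans_reduce_artifact_free_hours(self, small_cohort):
        child = next(ch for ch in small_cohort if ch.truth.artifact_spans)
        feats = ptt_features_for_record(child.beats)
        assert len(feats.artifact_spans) > 0
        assert feats.artifact_free_hours < child.truth.study_hours
        assert feats.ptt_arousal_index == pytest.approx(
            feats.ptt_arousal_count / feats.artifact_free_hours
        )
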