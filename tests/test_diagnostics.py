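"""ROC construction, threshold selection, bootstrap CIs, contingency statistics."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency, norm

from pttsleep import (
    ContingencyTable2x2,
    LabeledValues,
    bootstrap_ci,
    chi_square_2x2,
    contingency_accuracy,
    evaluate_threshold,
    roc_curve,
    select_thresholds,
    split_train_test,
)
from pttsleep.diagnostics import OneClassError


class TestSplit:
    def test_even_split(self):
        tr, te = split_train_test(list(range(10)), seed=0)
        assert len(tr) == len(te) == 5
        assert sorted(tr + te) == list(range(10))

    def test_odd_split_favours_training(self):
        tr, te = split_train_test(list(range(11)), seed=0)
        assert len(tr) == 6 and len(te) == 5

    def test_full_cohort_split_is_exact_half(self):
        tr, te = split_train_test(list(range(368)), seed=3)
        assert len(tr) == len(te) == 184

    def test_seeded_and_reproducible(self):
        a = split_train_test(list(range(20)), seed=5)
        b = split_train_test(list(range(20)), seed=5)
        c = split_train_test(list(range(20)), seed=6)
        assert a == b
        assert a != c

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            split_train_test([1, 2, 3], seed=0)


class TestRocCurve:
    def test_perfect_separation(self):
        data = LabeledValues([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        roc = roc_curve(data)
        assert roc.auc == pytest.approx(1.0)
        best = np.max(roc.sensitivity + roc.specificity)
        assert best == pytest.approx(2.0)

    def test_one_class_rejected(self):
        with pytest.raises(OneClassError):
            roc_curve(LabeledValues([1, 2, 3], [True, True, True]))

    def test_permuted_labels_give_chance_auc(self, rng):
        values = rng.normal(size=2000)
        labels = rng.permutation([True] * 1000 + [False] * 1000)
        roc = roc_curve(LabeledValues(values, labels))
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_sens_spec_match_brute_force_counts(self, rng):
        """Every ROC point equals direct counting of >=-threshold calls."""
        for _ in range(100):
            n = int(rng.integers(4, 50))
            values = rng.normal(size=n).round(1)  # force ties
            labels = rng.uniform(size=n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_curve(LabeledValues(values, labels))
            for t, se, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity):
                call = values >= t
                tp = np.sum(call & labels)
                tn = np.sum(~call & ~labels)
                assert se == pytest.approx(tp / labels.sum())
                assert sp == pytest.approx(tn / (~labels).sum())

    def test_sensitivity_non_increasing_in_threshold(self, rng):
        values = rng.normal(size=200)
        labels = rng.uniform(size=200) < 0.4
        roc = roc_curve(LabeledValues(values, labels))
        order = np.argsort(roc.thresholds)
        assert np.all(np.diff(roc.sensitivity[order]) <= 1e-12)


class TestSelectThresholds:
    def test_separable_data_thresholds_coincide(self):
        data = LabeledValues([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        sel = select_thresholds(roc_curve(data))
        assert sel.sens90_threshold == sel.spec90_threshold == sel.max_sum_threshold

    def test_max_sum_matches_exhaustive_search(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            values = rng.normal(size=n).round(1)
            labels = rng.uniform(size=n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_curve(LabeledValues(values, labels))
            sel = select_thresholds(roc)
            finite = np.isfinite(roc.thresholds)
            total = roc.sensitivity[finite] + roc.specificity[finite]
            _, se, sp = evaluate_threshold(LabeledValues(values, labels), sel.max_sum_threshold)
            assert se + sp == pytest.approx(np.max(total))

    def test_unreachable_target_reported_absent(self):
        # fully overlapping classes reach 90% sens/spec only at the infinities
        data = LabeledValues([1, 1, 2, 2], [True, False, True, False])
        sel = select_thresholds(roc_curve(data))
        assert sel.sens90_threshold is None and "sens90" in sel.diagnostics
        assert sel.spec90_threshold is None and "spec90" in sel.diagnostics


class TestEvaluateThreshold:
    def test_all_above_threshold(self):
        data = LabeledValues([5, 6, 7, 8], [True, True, False, False])
        table, se, sp = evaluate_threshold(data, 0.0)
        assert (se, sp) == (1.0, 0.0)
        assert table.total == 4

    def test_counts_and_rates(self):
        data = LabeledValues([20, 20, 10, 20, 10, 10], [True, True, True, False, False, False])
        table, se, sp = evaluate_threshold(data, 15.0)
        assert (table.tp, table.fn, table.fp, table.tn) == (2, 1, 1, 2)
        assert se == pytest.approx(2 / 3)


class TestBootstrap:
    def test_degenerate_data_collapses_to_point(self):
        data = LabeledValues([20] * 6 + [10] * 6, [True] * 6 + [False] * 6)
        ci = bootstrap_ci(data, 15.0, n_boot=200, seed=0)
        for metric in ("sensitivity", "specificity"):
            assert ci[metric]["2.5%"] == ci[metric]["50%"] == ci[metric]["97.5%"] == 1.0

    def test_median_tracks_point_estimate(self, rng):
        values = np.concatenate([rng.normal(18, 4, 150), rng.normal(10, 4, 150)])
        labels = np.array([True] * 150 + [False] * 150)
        data = LabeledValues(values, labels)
        _, se, sp = evaluate_threshold(data, 14.0)
        ci = bootstrap_ci(data, 14.0, n_boot=2000, seed=1)
        assert ci["sensitivity"]["50%"] == pytest.approx(se, abs=0.03)
        assert ci["specificity"]["50%"] == pytest.approx(sp, abs=0.03)
        assert ci["sensitivity"]["2.5%"] < se < ci["sensitivity"]["97.5%"]

    def test_small_n_boot_rejected(self):
        data = LabeledValues([1, 2], [True, False])
        with pytest.raises(ValueError):
            bootstrap_ci(data, 1.5, n_boot=10)


class TestContingencyAccuracy:
    def test_identity_table_is_perfect(self):
        table = np.array([[50, 0], [30, 0], [0, 40]])
        se, sp = contingency_accuracy(table)
        assert (se, sp) == (1.0, 1.0)

    def test_matches_definition_on_random_tables(self, rng):
        for _ in range(100):
            t = rng.integers(0, 50, size=(3, 2))
            if t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
                continue
            se, sp = contingency_accuracy(t)
            assert se == pytest.approx(t[2, 1] / t[:, 1].sum())
            assert sp == pytest.approx((t[0, 0] + t[1, 0]) / t[:, 0].sum())

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            contingency_accuracy(np.array([[0, 5], [0, 5], [0, 5]]))


class TestChiSquare:
    def test_independent_proportions_give_zero(self):
        stat, p = chi_square_2x2(np.array([[50, 50], [50, 50]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_formula_and_scipy(self, rng):
        for _ in range(100):
            t = rng.integers(1, 80, size=(2, 2)).astype(float)
            stat, p = chi_square_2x2(t)
            # independent formula: sum (O-E)^2/E
            rows, cols = t.sum(1), t.sum(0)
            e = np.outer(rows, cols) / t.sum()
            assert stat == pytest.approx((((t - e) ** 2) / e).sum())
            ref = chi2_contingency(t, correction=False)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))


def test_bootstrap_coverage_of_true_sensitivity(rng):
    """Nominal 95% percentile intervals cover truth in >=90% of replicates."""
    mu_pos, mu_neg, sd, thr, n = 18.0, 10.0, 4.0, 14.0, 120
    true_sens = 1.0 - norm.cdf(thr, mu_pos, sd)
    covered = 0
    reps = 300
    for r in range(reps):
        values = np.concatenate([rng.normal(mu_pos, sd, n // 2), rng.normal(mu_neg, sd, n // 2)])
        labels = np.array([True] * (n // 2) + [False] * (n // 2))
        ci = bootstrap_ci(LabeledValues(values, labels), thr, n_boot=400, seed=r)
        covered += ci["sensitivity"]["2.5%"] <= true_sens <= ci["sensitivity"]["97.5%"]
    assert covered / reps >= 0.90
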