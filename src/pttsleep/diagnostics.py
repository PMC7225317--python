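"""Train/test ROC analysis, threshold selection, bootstrap CIs, chi-square.

Convention throughout: a positive call is ``value >= threshold`` (both PTT
indices rise with disease), sensitivity = TP/(TP+FN) against the
UARS-or-OSA label, specificity = TN/(TN+FP) against normal-or-primary-
snoring.  Candidate thresholds are midpoints between consecutive sorted
unique values plus the two infinities, so a value exactly at a threshold
cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledValues",
    "RocResult",
    "SelectedThresholds",
    "ContingencyTable2x2",
    "split_train_test",
    "roc_curve",
    "select_thresholds",
    "evaluate_threshold",
    "bootstrap_ci",
    "contingency_accuracy",
    "chi_square_2x2",
    "OneClassError",
]


class OneClassError(ValueError):
    """ROC analysis needs both a positive and a negative class."""


@dataclass
class LabeledValues:
    """An index per child (swing ms or arousals/h) with the disease label."""

    values: np.ndarray
    labels: np.ndarray  # True = UARS/OSA, False = normal/primary snoring

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ContingencyTable2x2:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass
class SelectedThresholds:
    sens90_threshold: float | None
    spec90_threshold: float | None
    max_sum_threshold: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    selected: SelectedThresholds | None = None


def split_train_test(records: list, seed: int) -> tuple[list, list]:
    """Seeded uniform 50/50 split without replacement; odd n favours training."""
    n = len(records)
    if n < 4:
        raise ValueError("need at least 4 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = (n + 1) // 2
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


def roc_curve(data: LabeledValues) -> RocResult:
    """ROC over all midpoint thresholds with trapezoid AUC."""
    pos = data.labels
    if pos.all() or (~pos).all():
        raise OneClassError("both classes must be present for ROC analysis")
    uniq = np.unique(data.values)
    if len(uniq) > 1:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        mids = np.array([])
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    calls = data.values[None, :] >= thresholds[:, None]
    n_pos = int(pos.sum())
    n_neg = len(data) - n_pos
    tp = (calls & pos[None, :]).sum(axis=1)
    fp = (calls & ~pos[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ties in FPR traversed bottom-up
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def select_thresholds(roc: RocResult) -> SelectedThresholds:
    """The three operating points: sens>=0.90, spec>=0.90, max(sens+spec).

    sens90 is the largest threshold still reaching 90% sensitivity; spec90
    the smallest reaching 90% specificity; ties on the arithmetic sum go to
    the higher specificity, then the higher threshold.  Unreachable targets
    come back as None with a diagnostic.
    """
    diagnostics: dict = {}
    finite = np.isfinite(roc.thresholds)
    thr = roc.thresholds[finite]
    sens = roc.sensitivity[finite]
    spec = roc.specificity[finite]
    if len(thr) == 0:
        raise ValueError("ROC has no finite thresholds")
    ok = sens >= 0.90
    sens90 = float(np.max(thr[ok])) if ok.any() else None
    if sens90 is None:
        diagnostics["sens90"] = "no threshold attains 90% sensitivity"
    ok = spec >= 0.90
    spec90 = float(np.min(thr[ok])) if ok.any() else None
    if spec90 is None:
        diagnostics["spec90"] = "no threshold attains 90% specificity"
    total = sens + spec
    best = total == np.max(total)
    cand = np.flatnonzero(best)
    cand = cand[spec[cand] == np.max(spec[cand])]
    max_sum = float(np.max(thr[cand]))
    return SelectedThresholds(sens90, spec90, max_sum, diagnostics)


def evaluate_threshold(
    data: LabeledValues, threshold: float
) -> tuple[ContingencyTable2x2, float, float]:
    """Contingency counts and sensitivity/specificity at a fixed threshold."""
    call = data.values >= threshold
    pos = data.labels
    table = ContingencyTable2x2(
        tp=int((call & pos).sum()),
        fn=int((~call & pos).sum()),
        fp=int((call & ~pos).sum()),
        tn=int((~call & ~pos).sum()),
    )
    return table, table.sensitivity, table.specificity


def bootstrap_ci(
    data: LabeledValues,
    threshold: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Percentile bootstrap CIs for sensitivity and specificity.

    Whole-sample case resampling with replacement; resamples that lose a
    class entirely are redrawn so both rates stay defined.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    n = len(data)
    call = data.values >= threshold
    pos = data.labels
    sens = np.empty(n_boot)
    spec = np.empty(n_boot)
    idx = rng.integers(0, n, size=(n_boot, n))
    todo = np.arange(n_boot)
    while len(todo):
        p = pos[idx[todo]]
        npos = p.sum(axis=1)
        bad = (npos == 0) | (npos == n)
        redo = todo[bad]
        keep = todo[~bad]
        if len(keep):
            c = call[idx[keep]]
            pk = pos[idx[keep]]
            sens[keep] = (c & pk).sum(axis=1) / pk.sum(axis=1)
            spec[keep] = (~c & ~pk).sum(axis=1) / (~pk).sum(axis=1)
        if len(redo):
            idx[redo] = rng.integers(0, n, size=(len(redo), n))
        todo = redo
    out = {}
    for name, arr in (("sensitivity", sens), ("specificity", spec)):
        lo, med, hi = np.percentile(arr, [2.5, 50.0, 97.5])
        out[name] = {"2.5%": float(lo), "50%": float(med), "97.5%": float(hi)}
    return out


def contingency_accuracy(table: np.ndarray) -> tuple[float, float]:
    """Sensitivity/specificity of abnormal oximetry for UARS/OSA.

    ``table`` is 3x2: rows (normal, inconclusive, abnormal) oximetry, columns
    (normal-or-primary-snoring, UARS-or-OSA) video findings.  Only the
    abnormal row counts as a positive oximetry call.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 3x2 oximetry-by-video table")
    cond_pos = t[:, 1].sum()
    cond_neg = t[:, 0].sum()
    if cond_pos == 0 or cond_neg == 0:
        raise ValueError("both video columns must have children")
    tp = t[2, 1]
    tn = t[0, 0] + t[1, 0]
    return float(tp / cond_pos), float(tn / cond_neg)


def chi_square_2x2(table: ContingencyTable2x2 | np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, 1 df."""
    from scipy.stats import chi2

    if isinstance(table, ContingencyTable2x2):
        obs = np.array([[table.tp, table.fn], [table.fp, table.tn]], dtype=float)
    else:
        obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("all margins must be positive")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))
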