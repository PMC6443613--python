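"""Diagnostic evaluation harness.

Reference-standard labelling (any FFR <= 0.80 or any invasive-angiography
stenosis >= 90% marks a patient functionally significant), confusion-matrix
metrics with exact Clopper-Pearson 95% CIs, tie-aware empirical ROC / AUC,
repeated stratified cross-validation of the intermediate-stenosis
classifier with grade-rule extremes injected, and the packaged ordinal
contingency table of stenosis grade against outcome used for the
degree-of-stenosis-only baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

from .classifier import StenosisSVC
from .triage import combined_probability

__all__ = [
    "ConfusionCounts",
    "MetricWithCI",
    "DiagnosticMetrics",
    "CVPlan",
    "OrdinalContingencyTable",
    "RepeatedCVResult",
    "reference_label",
    "confusion_counts",
    "diagnostic_metrics",
    "roc_points",
    "roc_auc",
    "build_ordinal_fixture",
    "run_repeated_cv",
    "subgroup_filter",
]


def reference_label(record) -> bool:
    """Patient-level reference standard.

    True iff any vessel has FFR <= 0.80 (boundary inclusive) or any
    vessel has high-grade stenosis (>= 90% DS) on invasive angiography.
    """
    ffr = [v for v in record.ffr_values if v is not None]
    ica = [v for v in record.ica_ds_percent if v is not None]
    if not ffr and not ica:
        raise ValueError(
            f"patient {getattr(record, 'patient_id', '?')}: no FFR or ICA data"
        )
    return any(v <= 0.80 for v in ffr) or any(v >= 90.0 for v in ica)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self):
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted, labels) -> ConfusionCounts:
    predicted = np.asarray(predicted, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if predicted.shape != labels.shape:
        raise ValueError("predicted and labels must have equal length")
    return ConfusionCounts(
        tp=int(np.sum(predicted & labels)),
        fp=int(np.sum(predicted & ~labels)),
        tn=int(np.sum(~predicted & ~labels)),
        fn=int(np.sum(~predicted & labels)),
    )


@dataclass(frozen=True)
class MetricWithCI:
    """Proportion with its exact (Clopper-Pearson) 95% CI, as fractions."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    def percent(self, ndigits=1):
        return round(100.0 * self.value, ndigits)


def _proportion(num, den) -> MetricWithCI | None:
    if den == 0:
        return None  # metric undefined, reported absent rather than 0
    lo, hi = proportion_confint(num, den, alpha=0.05, method="beta")
    return MetricWithCI(num / den, float(lo), float(hi), num, den)


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricWithCI | None
    specificity: MetricWithCI | None
    ppv: MetricWithCI | None
    npv: MetricWithCI | None
    accuracy: MetricWithCI | None
    auc: float | None = None

    def as_percent_dict(self, ndigits=1):
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m = getattr(self, name)
            out[name] = None if m is None else m.percent(ndigits)
        if self.auc is not None:
            out["auc"] = round(self.auc, 2)
        return out


def diagnostic_metrics(counts: ConfusionCounts, auc=None) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs."""
    return DiagnosticMetrics(
        sensitivity=_proportion(counts.tp, counts.tp + counts.fn),
        specificity=_proportion(counts.tn, counts.tn + counts.fp),
        ppv=_proportion(counts.tp, counts.tp + counts.fp),
        npv=_proportion(counts.tn, counts.tn + counts.fn),
        accuracy=_proportion(counts.tp + counts.tn, counts.n),
        auc=auc,
    )


def roc_points(scores, labels):
    """Empirical ROC curve: (threshold, fpr, tpr) rows.

    One point per distinct score value (predict positive when score >=
    threshold), preceded by the (inf, 0, 0) endpoint; ties share a
    point, which makes the trapezoidal integral tie-aware.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    cum_tp = np.cumsum(y)[distinct]
    cum_fp = np.cumsum(~y)[distinct]
    rows = [(np.inf, 0.0, 0.0)]
    rows += [
        (s[i], fp / n_neg, tp / n_pos) for i, fp, tp in zip(distinct, cum_fp, cum_tp)
    ]
    return np.array(rows)


def roc_auc(scores, labels):
    """(ROC points, AUC) with AUC as the trapezoidal integral of the curve.

    On tied scores this equals the pairwise-concordance (Mann-Whitney)
    statistic (concordant + 0.5 * tied) / (n_pos * n_neg).
    """
    pts = roc_points(scores, labels)
    auc = float(np.trapezoid(pts[:, 2], pts[:, 1]))
    return pts, auc


@dataclass(frozen=True)
class OrdinalContingencyTable:
    """Patients cross-tabulated by ordinal stenosis grade and outcome."""

    positives: tuple  # per grade G0..G4
    negatives: tuple

    def __post_init__(self):
        if len(self.positives) != 5 or len(self.negatives) != 5:
            raise ValueError("five ordered grade categories are required")
        if min(self.positives) < 0 or min(self.negatives) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_positive(self):
        return sum(self.positives)

    @property
    def n_negative(self):
        return sum(self.negatives)

    @property
    def grade_totals(self):
        return tuple(p + n for p, n in zip(self.positives, self.negatives))

    def scores_labels(self):
        """Expand to per-patient ordinal scores (0..4) and labels."""
        scores, labels = [], []
        for g in range(5):
            scores += [g] * (self.positives[g] + self.negatives[g])
            labels += [True] * self.positives[g] + [False] * self.negatives[g]
        return np.array(scores, dtype=float), np.array(labels)

    def confusion_at(self, min_positive_grade: int) -> ConfusionCounts:
        """Counts when grades >= min_positive_grade are called positive."""
        scores, labels = self.scores_labels()
        return confusion_counts(scores >= min_positive_grade, labels)


def build_ordinal_fixture() -> OrdinalContingencyTable:
    """The packaged grade-by-outcome table of the 126-patient cohort.

    Per-grade (positive, negative) counts: G0 (0,2), G1 (0,8), G2 (6,4),
    G3 (61,30), G4 (14,1); marginals 81 positives / 45 negatives and
    grade totals 2/8/10/91/15.
    """
    return OrdinalContingencyTable(
        positives=(0, 0, 6, 61, 14), negatives=(2, 8, 4, 30, 1)
    )


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified k-fold plan for the intermediate-stenosis set."""

    k: int = 10
    repetitions: int = 50
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k < 2 or self.repetitions < 1:
            raise ValueError("need k >= 2 and at least one repetition")


@dataclass
class RepeatedCVResult:
    plan: CVPlan
    per_repetition: list  # DiagnosticMetrics per repetition
    aucs: np.ndarray  # (repetitions,)
    probabilities: np.ndarray  # (repetitions, n) combined probabilities
    fold_assignments: np.ndarray  # (repetitions, n_intermediate) fold ids
    intermediate_indices: np.ndarray

    @property
    def mean_auc(self):
        return float(self.aucs.mean())

    @property
    def sd_auc(self):
        return float(self.aucs.std(ddof=0))

    def mean_sd(self, metric):
        vals = np.array(
            [getattr(m, metric).value for m in self.per_repetition], dtype=float
        )
        return float(vals.mean()), float(vals.std(ddof=0))


def run_repeated_cv(
    features,
    labels,
    groups,
    plan: CVPlan,
    threshold=0.5,
    classifier_config=None,
):
    """Repeated stratified k-fold CV of the combined triage method.

    ``groups`` holds each patient's triage group; only intermediates are
    cross-validated (the classifier is trained on the training folds and
    each intermediate patient receives exactly one out-of-fold
    probability per repetition), while grade-rule extremes contribute
    fixed probabilities 0 / 1.  Per repetition the combined probability
    vector over all patients yields an AUC and, at ``threshold``, binary
    diagnostic metrics; the aggregate is mean +/- SD over repetitions.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    groups = list(groups)
    if not (len(X) == len(y) == len(groups)):
        raise ValueError("features, labels and groups must align")
    inter = np.array([i for i, g in enumerate(groups) if g == "intermediate"])
    if len(inter) == 0:
        raise ValueError("no intermediate patients to cross-validate")
    y_int = y[inter].astype(int)
    class_counts = np.bincount(y_int, minlength=2)
    if class_counts.min() < plan.k:
        raise ValueError(
            f"stratified {plan.k}-fold split impossible: minority class has "
            f"only {class_counts.min()} intermediate patients"
        )
    config = dict(classifier_config or {})

    base_probs = np.zeros(len(y))
    for i, g in enumerate(groups):
        if g != "intermediate":
            base_probs[i] = combined_probability(g)

    per_rep, aucs, probs_all, folds_all = [], [], [], []
    for rep in range(plan.repetitions):
        rep_seed = int(
            np.random.SeedSequence(plan.seed, spawn_key=(rep,)).generate_state(1)[0]
            % (2**31 - 1)
        )
        skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=rep_seed)
        probs = base_probs.copy()
        fold_of = np.full(len(inter), -1)
        for fold, (tr, va) in enumerate(skf.split(np.zeros(len(inter)), y_int)):
            clf = StenosisSVC(random_state=rep_seed, **config)
            clf.fit(X[inter[tr]], y_int[tr])
            pos = list(clf.classes_).index(1)
            probs[inter[va]] = clf.predict_proba(X[inter[va]])[:, pos]
            fold_of[va] = fold
        _, auc = roc_auc(probs, y)
        per_rep.append(
            diagnostic_metrics(confusion_counts(probs >= threshold, y), auc=auc)
        )
        aucs.append(auc)
        probs_all.append(probs)
        folds_all.append(fold_of)
    return RepeatedCVResult(
        plan=plan,
        per_repetition=per_rep,
        aucs=np.array(aucs),
        probabilities=np.array(probs_all),
        fold_assignments=np.array(folds_all),
        intermediate_indices=inter,
    )


def subgroup_filter(records, exclude_prior_events: bool):
    """Drop patients with prior MI / PCI / CABG when the flag is set."""
    records = list(records)
    if not exclude_prior_events:
        return records
    return [r for r in records if not r.prior_event]
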