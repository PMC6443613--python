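"""Reference rule, diagnostic metrics, ROC/AUC, repeated CV."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from myotriage import (
    CVPlan,
    build_ordinal_fixture,
    confusion_counts,
    diagnostic_metrics,
    reference_label,
    roc_auc,
    roc_points,
    run_repeated_cv,
    subgroup_filter,
)
from myotriage.phantom import PatientRecord
from myotriage.triage import StenosisGrade


def _record(ffr=(), ica=(), label=False, prior=False, pid="P0"):
    n = max(len(ffr), len(ica), 1)
    ffr = tuple(ffr) + (None,) * (n - len(ffr))
    ica = tuple(ica) + (None,) * (n - len(ica))
    return PatientRecord(
        patient_id=pid,
        vessel_grades=(StenosisGrade.G3,) * n,
        ffr_values=ffr,
        ica_ds_percent=ica,
        prior_event=prior,
        true_label=label,
    )


def _concordance_auc(scores, labels):
    """Brute-force pairwise concordance oracle."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    conc = tied = 0
    for p in pos:
        for q in neg:
            if p > q:
                conc += 1
            elif p == q:
                tied += 1
    return (conc + 0.5 * tied) / (len(pos) * len(neg))


class TestReferenceLabel:
    def test_ffr_above_cutoff_without_high_grade_is_negative(self):
        assert not reference_label(_record(ffr=(0.82,), ica=(80.0,)))

    def test_high_grade_ica_alone_is_positive(self):
        assert reference_label(_record(ffr=(0.85, 0.9), ica=(50.0, 92.0), label=True))

    def test_ffr_boundary_inclusive(self):
        assert reference_label(_record(ffr=(0.80,), label=True))

    def test_no_physiology_rejected(self):
        rec = _record(ffr=(0.9,))
        object.__setattr__(rec, "ffr_values", (None,))
        with pytest.raises(ValueError, match="no FFR or ICA"):
            reference_label(rec)


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion_counts([1, 1, 1, 0, 0], [1, 1, 1, 0, 0])
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 0, 2, 0)

    def test_all_positive_predictions(self):
        c = confusion_counts([1] * 5, [1, 1, 1, 0, 0])
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 2, 0, 0)

    def test_fixture_thresholded_at_50_percent(self):
        c = build_ordinal_fixture().confusion_at(3)
        assert (c.tp, c.fn, c.tn, c.fp) == (75, 6, 14, 31)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [1])


class TestOrdinalFixture:
    def test_marginals(self):
        t = build_ordinal_fixture()
        assert t.n_positive == 81
        assert t.n_negative == 45
        assert t.grade_totals == (2, 8, 10, 91, 15)

    def test_no_positives_in_lowest_grades(self):
        t = build_ordinal_fixture()
        assert t.positives[0] == t.positives[1] == 0


class TestDiagnosticMetrics:
    def test_printed_percentages_at_50_threshold(self):
        m = diagnostic_metrics(build_ordinal_fixture().confusion_at(3))
        pct = m.as_percent_dict()
        assert pct["sensitivity"] == 92.6
        assert pct["specificity"] == 31.1

    def test_ppv_at_70_threshold(self):
        m = diagnostic_metrics(build_ordinal_fixture().confusion_at(4))
        assert m.ppv.percent() == 93.3

    def test_all_metrics_absent_for_empty_counts(self):
        m = diagnostic_metrics(confusion_counts([], []))
        assert all(
            getattr(m, k) is None
            for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
        )

    def test_point_estimates_inside_exact_ci(self):
        m = diagnostic_metrics(build_ordinal_fixture().confusion_at(3))
        for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            metric = getattr(m, k)
            assert metric.ci_low <= metric.value <= metric.ci_high

    def test_ci_matches_printed_interval(self):
        # sensitivity 75/81 -> 84.6-97.2 at the printed precision
        m = diagnostic_metrics(build_ordinal_fixture().confusion_at(3))
        assert round(100 * m.sensitivity.ci_low, 1) == 84.6
        assert round(100 * m.sensitivity.ci_high, 1) == 97.2


class TestRocAuc:
    def test_perfectly_separated_scores(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_fixture_auc_is_068(self):
        scores, labels = build_ordinal_fixture().scores_labels()
        _, auc = roc_auc(scores, labels)
        assert round(auc, 2) == 0.68
        assert auc == pytest.approx(_concordance_auc(scores, labels), abs=1e-12)

    def test_trapezoid_equals_concordance_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(_concordance_auc(scores, labels), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_permutation_null_centers_at_half(self, rng):
        scores = rng.normal(size=60)
        labels = np.array([True] * 30 + [False] * 30)
        aucs = []
        for _ in range(1000):
            _, a = roc_auc(scores, rng.permutation(labels))
            aucs.append(a)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_roc_points_span_unit_square(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        pts = roc_points(scores, labels)
        assert tuple(pts[0][1:]) == (0.0, 0.0)
        assert tuple(pts[-1][1:]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 1]) >= 0) and np.all(np.diff(pts[:, 2]) >= 0)


class TestRepeatedCV:
    @pytest.fixture(scope="class")
    def cv_setup(self):
        rng = np.random.default_rng(5)
        groups = (
            ["non_significant"] * 10 + ["intermediate"] * 101 + ["significant"] * 15
        )
        y = np.array(
            [False] * 10 + [True] * 67 + [False] * 34 + [True] * 14 + [False]
        )
        X = rng.normal(size=(126, 6)) + y[:, None] * 1.5
        return X, y, groups

    def test_one_auc_per_repetition_and_determinism(self, cv_setup):
        X, y, groups = cv_setup
        plan = CVPlan(k=10, repetitions=50, seed=4)
        res = run_repeated_cv(X, y, groups, plan)
        assert len(res.aucs) == 50
        small = CVPlan(k=10, repetitions=2, seed=4)
        a = run_repeated_cv(X, y, groups, small)
        b = run_repeated_cv(X, y, groups, small)
        assert np.array_equal(a.aucs, b.aucs)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert np.array_equal(a.aucs, res.aucs[:2])

    def test_folds_partition_intermediates(self, cv_setup):
        X, y, groups = cv_setup
        res = run_repeated_cv(X, y, groups, CVPlan(k=10, repetitions=3, seed=1))
        for rep in res.fold_assignments:
            assert np.all(rep >= 0)
            counts = np.bincount(rep, minlength=10)
            assert counts.sum() == 101
            assert counts.max() - counts.min() <= 1

    def test_extremes_pinned_to_zero_and_one(self, cv_setup):
        X, y, groups = cv_setup
        res = run_repeated_cv(X, y, groups, CVPlan(k=10, repetitions=2, seed=2))
        assert np.all(res.probabilities[:, :10] == 0.0)
        assert np.all(res.probabilities[:, -15:] == 1.0)

    def test_stratification_impossible_rejected(self):
        groups = ["intermediate"] * 12
        y = np.array([True] * 9 + [False] * 3)
        with pytest.raises(ValueError, match="impossible"):
            run_repeated_cv(np.zeros((12, 2)), y, groups, CVPlan(k=10, repetitions=1))

    def test_mean_sd_aggregation(self, cv_setup):
        X, y, groups = cv_setup
        res = run_repeated_cv(X, y, groups, CVPlan(k=10, repetitions=3, seed=9))
        m, s = res.mean_sd("sensitivity")
        vals = [r.sensitivity.value for r in res.per_repetition]
        assert m == pytest.approx(np.mean(vals))
        assert s == pytest.approx(np.std(vals))


class TestSubgroupFilter:
    def test_prior_event_exclusion_counts(self):
        records = [
            _record(ffr=(0.9,), prior=i < 23, pid=f"P{i}") for i in range(126)
        ]
        assert len(subgroup_filter(records, True)) == 103

    def test_flag_false_is_identity(self):
        records = [_record(ffr=(0.9,), prior=True)]
        assert subgroup_filter(records, False) == records

    def test_empty_input(self):
        assert subgroup_filter([], True) == []
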