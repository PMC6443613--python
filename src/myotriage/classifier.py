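"""Patient classification: SVM over myocardium feature vectors.

An RBF-kernel support vector machine maps the per-patient feature
vector to a calibrated probability of functionally significant coronary
stenosis.  Features are standardized with training statistics only, the
regularization constant is chosen by an inner grid search on the
training folds, class imbalance is countered with inverse-prevalence
weights, and probabilities come from a Platt-style sigmoid fit on
cross-validated decision values.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y, check_array

__all__ = ["StenosisSVC", "train_classifier", "predict_probability"]


class StenosisSVC(BaseEstimator, ClassifierMixin):
    """Calibrated RBF-SVM for functionally-significant-stenosis prediction."""

    def __init__(
        self,
        C_grid=(0.1, 1.0, 10.0, 100.0),
        gamma="scale",
        inner_folds=3,
        random_state=0,
    ):
        self.C_grid = C_grid
        self.gamma = gamma
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=int))
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                "training set contains a single class; both outcomes are required"
            )
        folds = int(min(self.inner_folds, *np.bincount(y)[classes]))
        if folds < 2:
            raise ValueError(
                "need at least two patients per class to calibrate probabilities"
            )
        # Platt-style sigmoid on cross-validated decision values
        base = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    CalibratedClassifierCV(
                        SVC(
                            kernel="rbf",
                            gamma=self.gamma,
                            class_weight="balanced",
                        ),
                        method="sigmoid",
                        cv=folds,
                        ensemble=False,
                    ),
                ),
            ]
        )
        grid = sorted(self.C_grid)
        search = GridSearchCV(
            base,
            {"svm__estimator__C": grid},
            cv=StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=self.random_state
            ),
            scoring="roc_auc",
            refit=False,
        )
        search.fit(X, y)
        # degenerate inner folds (single-class validation) score NaN:
        # treat as chance so they fall through to abstention
        mean = np.nan_to_num(search.cv_results_["mean_test_score"], nan=0.5)
        se = np.nan_to_num(
            search.cv_results_["std_test_score"] / np.sqrt(folds), nan=0.0
        )
        best = int(np.argmax(mean))
        self.inner_scores_ = dict(zip(grid, mean.tolist()))
        self.classes_ = np.array(sorted(classes))
        self.n_features_in_ = X.shape[1]
        # no-signal abstention: when the inner CV cannot distinguish the
        # classes better than chance, rankings would be overfitting noise
        # (typically anti-predictive out of fold), so the classifier
        # falls back to the uninformative probability 0.5; a fixed
        # constant keeps abstaining folds exactly tied, avoiding the
        # cross-validation prevalence artifact
        if mean[best] <= 0.5 + 2.0 * se[best]:
            self.abstained_ = True
            self.constant_probability_ = 0.5
            self.model_ = None
            self.best_C_ = None
            return self
        self.abstained_ = False
        # one-standard-error rule: smallest C within one SE of the best
        chosen = next(
            i for i in range(len(grid)) if mean[i] >= mean[best] - se[best]
        )
        base.set_params(svm__estimator__C=grid[chosen])
        self.model_ = base.fit(X, y)
        self.best_C_ = float(grid[chosen])
        self.classes_ = self.model_.named_steps["svm"].classes_
        return self

    def _check(self, X):
        if not hasattr(self, "n_features_in_"):
            raise ValueError("classifier is not fitted")
        X = check_array(np.atleast_2d(X))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} does not match training length "
                f"{self.n_features_in_}"
            )
        return X

    def predict_proba(self, X):
        X = self._check(X)
        if self.abstained_:
            p = np.full(len(X), self.constant_probability_)
            return np.column_stack([1.0 - p, p])
        return self.model_.predict_proba(X)

    def predict(self, X):
        pos = list(self.classes_).index(1)
        return (self.predict_proba(X)[:, pos] >= 0.5).astype(int)

    def decision_function(self, X):
        """Uncalibrated SVM margin (the sigmoid maps it to probability)."""
        X = self._check(X)
        if self.abstained_:
            return np.zeros(len(X))
        scaled = self.model_.named_steps["scale"].transform(X)
        svm = self.model_.named_steps["svm"].calibrated_classifiers_[0].estimator
        return svm.decision_function(scaled)


def train_classifier(features, labels, **config):
    """Train on a feature matrix or a list of PatientFeatureVector."""
    X = _as_matrix(features)
    return StenosisSVC(**config).fit(X, labels)


def predict_probability(model: StenosisSVC, features):
    """Probability of functional significance, in [0, 1]."""
    X = _as_matrix(features)
    pos = list(model.classes_).index(1)
    p = model.predict_proba(X)[:, pos]
    return float(p[0]) if len(p) == 1 else p


def _as_matrix(features):
    if hasattr(features, "values") and hasattr(features, "patient_id"):
        return np.atleast_2d(features.values)
    if isinstance(features, (list, tuple)) and features and hasattr(
        features[0], "values"
    ):
        return np.vstack([f.values for f in features])
    return np.atleast_2d(np.asarray(features, dtype=float))
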