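"""Reproducible study-condition experiments.

Each function rebuilds one headline result of the package from scratch —
generating its synthetic inputs, running the pipeline stages involved,
and measuring the outcome.  ``scripts/acceptance.py`` and the test suite
both call these, so the reported numbers and the tested numbers are the
same computation.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .autoencoder import ConvAutoencoder, encode_lvm, sample_training_patches
from .classifier import StenosisSVC
from .evaluation import (
    CVPlan,
    build_ordinal_fixture,
    diagnostic_metrics,
    roc_auc,
    run_repeated_cv,
)
from .phantom import CohortSpec, generate_cohort
from .pipeline import extract_cohort_features
from .segmentation import TriplanarSegmenter, qc_segmentation
from .triage import patient_max_grade, triage_group

# study-like cohort composition: grade counts and prevalence
STUDY_CATEGORY_COUNTS = (2, 8, 10, 91, 15)
STUDY_PREVALENCE = 81.0 / 126.0

# fixture-scale segmenter: small patches, stride-2 inference for cohorts
COHORT_SEG = dict(patch_edge=9, epochs=3, samples_per_volume=1500, stride=2)


def table2_metrics():
    """Diagnostic metrics of degree-of-stenosis thresholds on the packaged
    ordinal table, as printed percentages (one decimal)."""
    table = build_ordinal_fixture()
    out = {}
    for name, threshold in (("ds25", 2), ("ds50", 3), ("ds70", 4)):
        m = diagnostic_metrics(table.confusion_at(threshold))
        out[name] = m.as_percent_dict()
    return out


def ds_only_auc():
    """Tie-aware AUC of the ordinal grades, and a brute-force concordance
    recount over all positive x negative patient pairs."""
    scores, labels = build_ordinal_fixture().scores_labels()
    _, auc = roc_auc(scores, labels)
    pos = scores[labels]
    neg = scores[~labels]
    conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return auc, conc / (len(pos) * len(neg))


def _study_cohort(seed, effect_size):
    spec = CohortSpec(
        n_patients=126,
        prevalence=STUDY_PREVALENCE,
        category_counts=STUDY_CATEGORY_COUNTS,
        effect_size=effect_size,
        seed=seed,
    )
    return generate_cohort(spec)


def combined_vs_ds(seed, effect_size, repetitions=10, n_train_seg=4):
    """The central comparison: combined triage AUC vs grade-only AUC.

    Full pipeline on a synthetic 126-patient cohort with the study's
    grade composition and prevalence: segmenter trained on the first
    patients' reference masks, every scan segmented automatically and
    QC-checked, myocardium encoded and summarized, the classifier
    cross-validated over the intermediates (repeated stratified 10-fold)
    with grade-rule extremes pinned to 0/1.
    """
    cohort = _study_cohort(seed, effect_size)
    y = np.array([r.true_label for r in cohort.records])
    seg = TriplanarSegmenter(random_state=seed + 1, **COHORT_SEG)
    seg.fit(cohort.volumes[:n_train_seg], cohort.masks[:n_train_seg])
    masks = []
    n_qc_fail = 0
    for vol in cohort.volumes:
        mask = seg.predict_mask(vol)
        passed, _ = qc_segmentation(mask, cohort.spec.voxel_spacing)
        n_qc_fail += not passed
        masks.append(mask if mask.any() else None)
    # QC failures are counted; encoding falls back to nothing only if empty
    usable = [i for i, m in enumerate(masks) if m is not None]
    X, _ = extract_cohort_features(
        [cohort.volumes[i] for i in usable],
        [masks[i] for i in usable],
        seed=seed,
        cae_config={"n_patches": 3000},
        encode_stride=2,
    )
    y = y[usable]
    grades = [patient_max_grade(cohort.records[i].vessel_grades) for i in usable]
    groups = [triage_group(g) for g in grades]
    ds_scores = np.array([g.ordinal for g in grades], dtype=float)
    _, ds = roc_auc(ds_scores, y)
    res = run_repeated_cv(
        X, y, groups, CVPlan(k=10, repetitions=repetitions, seed=seed)
    )
    return {
        "combined_auc": res.mean_auc,
        "combined_auc_sd": res.sd_auc,
        "ds_only_auc": ds,
        "gap": res.mean_auc - ds,
        "n_qc_failed": n_qc_fail,
        "n": len(usable),
    }


def segmentation_dice(seed, n_train=4, n_test=2):
    """Parameter recovery: Dice of the tiny segmenter on held-out phantoms
    drawn from the same generator settings as its training set."""
    spec = CohortSpec(n_patients=n_train + n_test, prevalence=0.5, seed=seed)
    cohort = generate_cohort(spec)
    seg = TriplanarSegmenter(
        patch_edge=9, epochs=3, samples_per_volume=1500, stride=1,
        random_state=seed + 1,
    )
    seg.fit(cohort.volumes[:n_train], cohort.masks[:n_train])
    dices = []
    for i in range(n_train, n_train + n_test):
        pred = seg.predict_mask(cohort.volumes[i])
        truth = cohort.masks[i]
        dices.append(2.0 * np.sum((pred > 0) & (truth > 0)) / (pred.sum() + truth.sum()))
    return float(np.mean(dices))


def cae_sanity(seed, n_patients=4, n_patches=500, epochs=5):
    """Reconstruction error of the trained auto-encoder against the
    untrained baseline, plus the encoding-count contract."""
    spec = CohortSpec(n_patients=n_patients, prevalence=0.5, seed=seed)
    cohort = generate_cohort(spec)
    patches = sample_training_patches(
        cohort.volumes, cohort.masks, n_patches, seed + 1, patch_size=4
    )
    cae = ConvAutoencoder(epochs=epochs, random_state=seed).fit(patches)
    baseline = ConvAutoencoder(epochs=epochs, random_state=seed).initialize()
    enc = encode_lvm(cae, cohort.volumes[0], cohort.masks[0], stride=1)
    return {
        "trained_error": cae.reconstruction_error(patches),
        "untrained_error": baseline.reconstruction_error(patches),
        "n_encodings": len(enc),
        "n_masked_voxels": int(cohort.masks[0].sum()),
    }


def classifier_recovery(seed, effect_size, n_patients=60, repeats=3, k=5):
    """Held-out AUC of the full characterization + SVM chain at a given
    lesion effect size (reference masks; repeated stratified k-fold)."""
    spec = CohortSpec(
        n_patients=n_patients, prevalence=0.5, effect_size=effect_size, seed=seed
    )
    cohort = generate_cohort(spec)
    y = np.array([r.true_label for r in cohort.records])
    X, _ = extract_cohort_features(
        cohort.volumes,
        cohort.masks,
        seed=seed,
        cae_config={"n_patches": 3000},
        encode_stride=1,
    )
    aucs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + 97 * rep)
        for tr, te in skf.split(X, y):
            clf = StenosisSVC(random_state=seed).fit(X[tr], y[tr].astype(int))
            pos = list(clf.classes_).index(1)
            _, a = roc_auc(clf.predict_proba(X[te])[:, pos], y[te])
            aucs.append(a)
    return float(np.mean(aucs))
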