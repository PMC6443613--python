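"""End-to-end pipeline: synthesize/load a cohort, segment, QC, encode,
featurize, cross-validate the classifier and evaluate the combined
triage method against the degree-of-stenosis-only baseline.

Every stage draws its seed from the single global seed, so a rerun with
the same configuration is bit-identical; the report embeds the seed and
a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from .autoencoder import ConvAutoencoder, encode_lvm, sample_training_patches
from .evaluation import (
    CVPlan,
    confusion_counts,
    diagnostic_metrics,
    roc_auc,
    run_repeated_cv,
)
from .features import DEFAULT_STATISTICS, EncodingSummarizer
from .io import read_cohort_table, read_volume
from .phantom import CohortSpec, generate_cohort
from .segmentation import TriplanarSegmenter, qc_segmentation
from .triage import StenosisGrade, patient_max_grade, triage_group

logger = logging.getLogger("myotriage")

__all__ = ["default_config", "config_hash", "extract_cohort_features", "run_pipeline"]


def default_config(seed=0, out_dir="myotriage_out"):
    """Baseline pipeline configuration (JSON-serializable dict)."""
    return {
        "seed": seed,
        "out_dir": str(out_dir),
        "synth": None,  # CohortSpec fields, or None to load an existing cohort
        "cohort_csv": None,
        "volume_dir": None,
        "segmentation": {
            "patch_edge": 9,
            "scales": [1.0, 3.0],
            "epochs": 3,
            "samples_per_volume": 1500,
            "stride": 2,
            "train_patients": 4,
        },
        "autoencoder": {
            "patch_size": 4,
            "encoding_dim": 8,
            "epochs": 15,
            "n_patches": 3000,
            "stride": 2,
        },
        "features": {"statistics": list(DEFAULT_STATISTICS)},
        "classifier": {"C_grid": [1.0, 10.0, 100.0]},
        "cv": {"k": 10, "repetitions": 10},
        "threshold": 0.5,
    }


def config_hash(config) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_seed(seed, stage):
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def extract_cohort_features(
    volumes,
    masks,
    seed,
    cae_config=None,
    encode_stride=2,
    statistics=DEFAULT_STATISTICS,
    patient_ids=None,
):
    """Train the auto-encoder on the cohort and featurize every patient.

    Returns (feature matrix, fitted ConvAutoencoder).  The CAE is
    trained unsupervised on patches pooled over all patients' masked
    voxels, then each patient's masked voxels are encoded (on the given
    stride) and summarized per encoding dimension.
    """
    cfg = dict(cae_config or {})
    n_patches = cfg.pop("n_patches", 600)
    cae = ConvAutoencoder(random_state=_stage_seed(seed, "cae"), **cfg)
    patches = sample_training_patches(
        volumes, masks, n_patches, _stage_seed(seed, "cae_sample"), cae.patch_size
    )
    cae.fit(patches)
    summarizer = EncodingSummarizer(statistics)
    sets = []
    for i, (vol, mask) in enumerate(zip(volumes, masks)):
        pid = patient_ids[i] if patient_ids is not None else f"P{i:04d}"
        sets.append(encode_lvm(cae, vol, mask, stride=encode_stride, patient_id=pid))
    return summarizer.transform(sets), cae


def run_pipeline(config):
    """Execute all stages; returns the report dict and writes artifacts.

    QC-failed and all-non-diagnostic patients are excluded and counted
    in the report.  Output files under ``out_dir``: report.json,
    roc_combined.tsv, roc_ds_only.tsv, predictions.csv.
    """
    seed = int(config["seed"])
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- stage: cohort -------------------------------------------------
    if config.get("synth"):
        spec = CohortSpec(seed=_stage_seed(seed, "synth"), **config["synth"])
        logger.info("stage=synth n_patients=%d", spec.n_patients)
        cohort = generate_cohort(spec, out_dir=out_dir / "data")
        records = cohort.records
        volumes = cohort.volumes
        spacing = spec.voxel_spacing
        true_masks = cohort.masks
    else:
        if not config.get("cohort_csv") or not config.get("volume_dir"):
            raise ValueError("either 'synth' or cohort_csv+volume_dir is required")
        records = read_cohort_table(config["cohort_csv"])
        volumes, true_masks = [], []
        spacing = None
        for rec in records:
            vpath = Path(config["volume_dir"]) / f"{rec.patient_id}_ct.nii.gz"
            if not vpath.exists():
                raise FileNotFoundError(
                    f"stage=load patient={rec.patient_id}: missing volume {vpath}"
                )
            ct = read_volume(vpath)
            volumes.append(ct.data)
            spacing = ct.spacing
            mpath = Path(config["volume_dir"]) / f"{rec.patient_id}_mask.nii.gz"
            true_masks.append(read_volume(mpath).data.astype(np.uint8) if mpath.exists() else None)

    # ---- stage: segmentation ------------------------------------------
    seg_cfg = dict(config["segmentation"])
    n_train = seg_cfg.pop("train_patients", 4)
    train_idx = list(range(min(n_train, len(records))))
    trainable = [i for i in train_idx if true_masks[i] is not None]
    if not trainable:
        raise ValueError("stage=segment: no reference masks available for training")
    segmenter = TriplanarSegmenter(
        random_state=_stage_seed(seed, "segment"), **seg_cfg
    )
    segmenter.fit(
        [volumes[i] for i in trainable], [true_masks[i] for i in trainable],
        log_path=out_dir / "segmenter_loss.tsv",
    )
    logger.info("stage=segment trained on %d patients", len(trainable))

    masks, qc_excluded = [], []
    for i, rec in enumerate(records):
        t = time.time()
        mask = segmenter.predict_mask(volumes[i])
        passed, reasons = qc_segmentation(mask, spacing)
        logger.info(
            "stage=qc patient=%s passed=%s duration=%.2fs",
            rec.patient_id, passed, time.time() - t,
        )
        masks.append(mask)
        if not passed:
            qc_excluded.append({"patient_id": rec.patient_id, "reasons": reasons})

    qc_failed_ids = {e["patient_id"] for e in qc_excluded}
    nd_excluded = [
        r.patient_id
        for r in records
        if patient_max_grade(r.vessel_grades) is StenosisGrade.ND
    ]
    keep = [
        i
        for i, r in enumerate(records)
        if r.patient_id not in qc_failed_ids and r.patient_id not in nd_excluded
    ]
    if not keep:
        raise ValueError("stage=qc: every patient was excluded")

    # ---- stage: encode + featurize ------------------------------------
    ae_cfg = dict(config["autoencoder"])
    encode_stride = ae_cfg.pop("stride", 2)
    X, cae = extract_cohort_features(
        [volumes[i] for i in keep],
        [masks[i] for i in keep],
        seed,
        cae_config=ae_cfg,
        encode_stride=encode_stride,
        statistics=tuple(config["features"]["statistics"]),
        patient_ids=[records[i].patient_id for i in keep],
    )

    # ---- stage: triage + evaluation -----------------------------------
    kept = [records[i] for i in keep]
    y = np.array([r.true_label for r in kept])
    grades = [patient_max_grade(r.vessel_grades) for r in kept]
    groups = [triage_group(g) for g in grades]
    plan = CVPlan(seed=_stage_seed(seed, "cv"), **config["cv"])
    result = run_repeated_cv(
        X, y, groups, plan,
        threshold=config.get("threshold", 0.5),
        classifier_config=config.get("classifier"),
    )
    ds_scores = np.array([g.ordinal for g in grades], dtype=float)
    ds_pts, ds_auc = roc_auc(ds_scores, y)
    ds_metrics = diagnostic_metrics(
        confusion_counts(ds_scores >= 3, y), auc=ds_auc
    )
    mean_probs = result.probabilities.mean(axis=0)
    comb_pts, _ = roc_auc(mean_probs, y)

    report = {
        "seed": seed,
        "config_hash": config_hash(config),
        "n_patients": len(records),
        "n_excluded_qc": len(qc_excluded),
        "qc_exclusions": qc_excluded,
        "n_excluded_nondiagnostic": len(nd_excluded),
        "n_evaluated": len(kept),
        "segmenter_final_loss": segmenter.loss_trace_[-1],
        "cae_final_loss": cae.loss_trace_[-1],
        "ds_only": ds_metrics.as_percent_dict(),
        "ds_only_auc": round(ds_auc, 4),
        "combined_auc_mean": round(result.mean_auc, 4),
        "combined_auc_sd": round(result.sd_auc, 4),
        "combined": {
            m: dict(zip(("mean", "sd"), [round(v, 4) for v in result.mean_sd(m)]))
            for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
        },
        "per_repetition_auc": [round(a, 6) for a in result.aucs],
    }

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    for name, pts in (("roc_ds_only.tsv", ds_pts), ("roc_combined.tsv", comb_pts)):
        with open(out_dir / name, "w") as fh:
            fh.write("threshold\tfpr\ttpr\n")
            for thr, fpr, tpr in pts:
                fh.write(f"{thr:.6g}\t{fpr:.6f}\t{tpr:.6f}\n")
    with open(out_dir / "predictions.csv", "w") as fh:
        fh.write("patient_id,probability\n")
        for rec, p in zip(kept, mean_probs):
            fh.write(f"{rec.patient_id},{p:.6f}\n")
    return report
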