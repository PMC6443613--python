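# myotriage

Identifying patients whose coronary artery stenosis is *functionally*
significant — i.e. actually limits blood flow — is a central problem in
cardiac imaging. Coronary CT angiography (CCTA) grades the anatomical
degree of stenosis (DS) with high sensitivity but poor specificity: many
anatomically intermediate lesions (25–69 % DS) do not restrict flow, yet
they send patients on to invasive fractional flow reserve (FFR)
measurement. `myotriage` implements a combined triage strategy for this
problem, aimed at imaging researchers who want a complete, testable
reference pipeline:

1. **Triage by grade.** Patients whose maximum CCTA grade is ≤ 24 % DS
   are called negative (probability 0); ≥ 70 % DS positive
   (probability 1).
2. **Deep analysis of the myocardium for the intermediates.** The left
   ventricular myocardium (LVM) is segmented voxel-by-voxel with a
   two-stream multiscale triplanar patch CNN, characterized in an
   unsupervised manner by a convolutional auto-encoder (CAE), collapsed
   into one feature vector per patient (statistics over the per-voxel
   encodings), and classified with a calibrated RBF-SVM.
3. **Evaluation** against the reference standard — functionally
   significant iff any FFR ≤ 0.80 or any high-grade (≥ 90 % DS) stenosis
   on invasive angiography — with repeated stratified 10-fold
   cross-validation, exact binomial confidence intervals and tie-aware
   empirical ROC/AUC.

The statistic at the core is the patient-level probability

&nbsp;&nbsp;&nbsp;&nbsp;p(patient) = 0, &nbsp;DSmax ≤ 24 %; &nbsp;&nbsp;
p = 1, &nbsp;DSmax ≥ 70 %; &nbsp;&nbsp;
p = SVM(φ(CAE(LVM))), &nbsp;25 % ≤ DSmax ≤ 69 %

where φ computes mean, SD, min, quartiles and max of each encoding
dimension over all myocardial voxels, and the AUC is the Mann–Whitney
concordance (ties counted ½) of p against the reference labels.

Because no clinical data ship with the package, a synthetic cohort
generator produces contrast-CT-like volumes (ellipsoidal myocardial
shell, blood pool, noise), hypo-attenuating sector lesions whose
presence tracks the functional label, and per-vessel FFR / angiography
ground truth consistent with the reference rule — everything the
pipeline and its evaluation harness need, end to end.

## Worked example

Run the whole pipeline on a 24-patient synthetic demo cohort:

```bash
myotriage run --seed 7 --out demo_run
```

prints

```json
{
  "n_evaluated": 24,
  "ds_only_auc": 0.7074,
  "combined_auc_mean": 0.923
}
```

and writes `demo_run/report.json`, ROC curves (TSV) and per-patient
probabilities (CSV). In this run, grading stenosis degree alone
discriminates functionally significant patients with AUC 0.71
(sensitivity 93.3 %, specificity 33.3 % at the ≥ 50 % DS threshold),
while the combined method — grade rule for the extremes, learned
myocardial classifier for the intermediates — reaches AUC
0.923 ± 0.035 over five repetitions of stratified 3-fold
cross-validation, raising specificity (62.2 ± 5.4 %) at a small
sensitivity cost. The improvement is possible because the synthetic
lesions are strong (40 HU peak depression); with the lesion effect set
to zero the combined AUC falls back to the grade-only value.

Stage-wise subcommands (`synth`, `segment`, `featurize`, `triage`)
operate on the same file formats — NIfTI volumes/masks, a per-vessel
cohort CSV with columns
`patient_id, vessel_id, ccta_grade, ffr, ica_ds_percent, prior_event, true_label`
(grade tokens `0%`, `1-24%`, `25-49%`, `50-69%`, `>=70%`, `ND`), and
JSON configs — so any stage can be rerun in isolation.

Library use mirrors scikit-learn:

```python
from myotriage import (CohortSpec, generate_cohort, TriplanarSegmenter,
                       ConvAutoencoder, EncodingSummarizer, StenosisSVC)

cohort = generate_cohort(CohortSpec(n_patients=24, seed=7))
seg = TriplanarSegmenter(patch_edge=9, stride=2).fit(
    cohort.volumes[:4], cohort.masks[:4])
mask = seg.predict_mask(cohort.volumes[5])
```

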