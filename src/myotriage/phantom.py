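"""Synthetic CT cohort generator.

Builds reproducible stand-ins for a clinical coronary-CT cohort: each
patient is an ellipsoidal left-ventricular-myocardium (LVM) shell inside
a contrast-enhanced chest-like volume, together with per-vessel stenosis
grades, invasive FFR values, invasive-angiography (ICA) stenosis
percentages and prior-event flags.  Patients labelled functionally
significant carry a hypo-attenuating angular sector in the shell whose
mean HU depression is ``effect_size``; the clinical ground truth is
generated so that the reference rule (any FFR <= 0.80 or any ICA DS >=
90%) recovers the label exactly.

Everything derives from a single cohort seed through per-patient spawned
streams, so regeneration is bit-identical and independent of order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .triage import StenosisGrade, patient_max_grade

__all__ = [
    "CohortSpec",
    "PhantomParams",
    "PatientRecord",
    "SyntheticCohort",
    "generate_phantom_volume",
    "assign_physiology",
    "generate_cohort",
    "sample_phantom_params",
]

# Study-like cohort structure: grade composition 2/8/10/91/15 over 126
# patients, 81 positives, and per-grade positive rates 0/0, 6/10, 61/91,
# 14/15 (no positives below 25% DS).
DEFAULT_CATEGORY_WEIGHTS = (2, 8, 10, 91, 15)
DEFAULT_POSITIVE_RATES = (0.0, 0.0, 0.6, 61.0 / 91.0, 14.0 / 15.0)
FFR_PATH_PROB = 0.85  # positives realised through FFR <= 0.80 vs ICA >= 90%
PRIOR_EVENT_RATE = 23.0 / 126.0


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation settings.

    effect_size is the peak HU depression of the ischemic lesion sector;
    lesion_fraction the fraction of the shell circumference it spans.
    """

    n_patients: int = 126
    prevalence: float = 81.0 / 126.0
    category_counts: tuple | None = None
    effect_size: float = 40.0
    lesion_fraction: float = 0.3
    noise_sd: float = 20.0
    grid_shape: tuple = (32, 48, 48)  # (z, y, x) voxels
    voxel_spacing: tuple = (1.0, 1.0, 1.0)  # mm
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive reals")
        if self.category_counts is not None:
            counts = tuple(int(c) for c in self.category_counts)
            if len(counts) != 5 or any(c < 0 for c in counts):
                raise ValueError("category_counts must be five non-negative counts")
            if sum(counts) != self.n_patients:
                raise ValueError(
                    f"category_counts sum to {sum(counts)}, not n_patients="
                    f"{self.n_patients}"
                )
            object.__setattr__(self, "category_counts", counts)

    @property
    def n_positive(self) -> int:
        return int(round(self.prevalence * self.n_patients))


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity of one myocardial-shell phantom.

    Lengths in mm, positions in (z, y, x) physical coordinates relative
    to the grid origin; intensities in HU; angles in radians.
    """

    center: tuple
    axes: tuple  # outer ellipsoid semi-axes (z, y, x)
    thickness: float
    myocardium_hu: float = 100.0
    bloodpool_hu: float = 400.0
    background_hu: float = -50.0
    lesion_theta: float = 0.0  # sector start angle in the (y, x) plane
    seed: int = 0

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("shell thickness must be positive")
        if min(self.axes) <= self.thickness:
            raise ValueError("shell thickness must be smaller than every semi-axis")
        if self.bloodpool_hu <= self.myocardium_hu:
            raise ValueError("blood pool must be brighter than myocardium (contrast)")


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient clinical ground truth for one synthetic patient."""

    patient_id: str
    vessel_grades: tuple
    ffr_values: tuple  # per-vessel FFR in (0, 1], or None where not measured
    ica_ds_percent: tuple  # per-vessel ICA DS in [0, 100], or None
    prior_event: bool
    true_label: bool

    def __post_init__(self):
        if len(self.vessel_grades) == 0:
            raise ValueError("patient must have at least one vessel")
        if not (
            len(self.vessel_grades) == len(self.ffr_values) == len(self.ica_ds_percent)
        ):
            raise ValueError("per-vessel lists must have equal length")
        if all(v is None for v in self.ffr_values) and all(
            v is None for v in self.ica_ds_percent
        ):
            raise ValueError("at least one FFR or ICA DS value is required")
        ffr = [v for v in self.ffr_values if v is not None]
        ica = [v for v in self.ica_ds_percent if v is not None]
        derived = any(v <= 0.80 for v in ffr) or any(v >= 90.0 for v in ica)
        if derived != self.true_label:
            raise ValueError(
                "true_label inconsistent with the FFR<=0.80 / ICA>=90% reference rule"
            )

    @property
    def max_grade(self) -> StenosisGrade:
        return patient_max_grade(self.vessel_grades)


@dataclass
class SyntheticCohort:
    """In-memory result of cohort generation."""

    spec: CohortSpec
    records: list
    volumes: list = field(default_factory=list)
    masks: list = field(default_factory=list)
    params: list = field(default_factory=list)


def sample_phantom_params(seed: int, spec: CohortSpec) -> PhantomParams:
    """Phantom parameters for one patient: template anatomy, drawn intensities.

    All patients share one template shell geometry (scaled to the grid);
    between-patient variation is in tissue HU levels, noise realization
    and lesion placement.  Anatomical variability of real hearts is
    deliberately not emulated, so the lesion is the only class-correlated
    image signal.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    extent = np.array(spec.grid_shape) * np.array(spec.voxel_spacing)
    axes = tuple(extent / 2.0 * np.array([0.62, 0.55, 0.55]))
    center = tuple(extent / 2.0)
    return PhantomParams(
        center=center,
        axes=axes,
        thickness=4.0,
        myocardium_hu=float(100.0 + rng.normal(0.0, 5.0)),
        bloodpool_hu=float(400.0 + rng.normal(0.0, 20.0)),
        background_hu=float(-50.0 + rng.normal(0.0, 10.0)),
        lesion_theta=float(rng.uniform(0.0, 2.0 * math.pi)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_phantom_volume(params: PhantomParams, label: bool, spec: CohortSpec):
    """Voxelize one phantom; returns (volume HU float64, mask uint8).

    The mask is exactly the ellipsoidal shell (outer ellipsoid minus the
    blood-pool cavity).  For positive patients a contiguous angular
    sector of the shell is depressed by a raised-cosine profile peaking
    at ``effect_size`` HU; Gaussian noise with sd ``noise_sd`` is added
    everywhere from a label-independent stream, so identical seeds with
    effect_size 0 give bit-identical volumes for both labels.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    center = np.asarray(params.center, dtype=float)
    axes = np.asarray(params.axes, dtype=float)
    extent = np.array(shape) * spacing
    if np.any(center - axes < 0) or np.any(center + axes > extent):
        raise ValueError(
            f"shell (center {tuple(center)}, axes {tuple(axes)}) does not fit "
            f"inside the grid extent {tuple(extent)} mm"
        )

    # physical coordinate of each voxel center, axis order (z, y, x)
    coords = [
        (np.arange(shape[i]) + 0.5) * spacing[i] - center[i] for i in range(3)
    ]
    dz = coords[0][:, None, None]
    dy = coords[1][None, :, None]
    dx = coords[2][None, None, :]

    inner = axes - params.thickness
    r_out = (dz / axes[0]) ** 2 + (dy / axes[1]) ** 2 + (dx / axes[2]) ** 2
    r_in = (dz / inner[0]) ** 2 + (dy / inner[1]) ** 2 + (dx / inner[2]) ** 2
    cavity = r_in <= 1.0
    shell = (r_out <= 1.0) & ~cavity

    volume = np.full(shape, params.background_hu, dtype=float)
    volume[cavity] = params.bloodpool_hu
    volume[shell] = params.myocardium_hu

    if label and spec.effect_size > 0 and spec.lesion_fraction > 0:
        width = 2.0 * math.pi * spec.lesion_fraction
        phi = np.arctan2(dy, dx) - params.lesion_theta
        t = np.mod(phi, 2.0 * math.pi) / width  # position within the sector
        in_sector = t < 1.0
        taper = 0.5 * (1.0 - np.cos(2.0 * math.pi * np.clip(t, 0.0, 1.0)))
        depression = np.where(in_sector & shell, spec.effect_size * taper, 0.0)
        volume -= depression

    if spec.noise_sd > 0:
        noise_rng = np.random.Generator(np.random.Philox(params.seed))
        volume = volume + noise_rng.normal(0.0, spec.noise_sd, size=shape)

    return volume, shell.astype(np.uint8)


def _negative_physiology(rng, n_vessels):
    # clinical measurement precision: FFR to 2 decimals, ICA DS to 1
    ffr = [round(float(rng.uniform(0.82, 0.95)), 2) for _ in range(n_vessels)]
    ica = [round(float(rng.uniform(5.0, 85.0)), 1) for _ in range(n_vessels)]
    return ffr, ica


def assign_physiology(label, grades, seed, ffr_path_prob=FFR_PATH_PROB):
    """Generate per-vessel FFR and ICA DS consistent with the label.

    Positives are realised either through the FFR path (one culprit
    vessel with FFR <= 0.80) or, with probability 1 - ffr_path_prob,
    through the ICA path (all FFR > 0.80 but one vessel with high-grade
    >= 90% DS on angiography, where FFR is then not measured).
    """
    grades = list(grades)
    if not grades:
        raise ValueError("at least one vessel is required")
    rng = np.random.Generator(np.random.Philox(seed))
    n = len(grades)
    ffr, ica = _negative_physiology(rng, n)
    if not label:
        return tuple(ffr), tuple(ica)

    # culprit: the most stenotic diagnostic vessel (ties broken by index)
    diag = [i for i, g in enumerate(grades) if g is not StenosisGrade.ND]
    culprit = max(diag, key=lambda i: grades[i].ordinal) if diag else 0
    if rng.random() < ffr_path_prob:
        ffr[culprit] = round(float(rng.uniform(0.55, 0.80)), 2)
    else:
        ica[culprit] = round(float(rng.uniform(90.0, 99.0)), 1)
        ffr[culprit] = None  # FFR not performed in high-grade vessels
    return tuple(ffr), tuple(ica)


def _largest_remainder(weights, total):
    """Integer allocation of `total` proportional to `weights`."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0 or total == 0:
        return np.zeros(len(weights), dtype=int)
    ideal = weights / weights.sum() * total
    alloc = np.floor(ideal).astype(int)
    order = np.argsort(-(ideal - alloc), kind="stable")
    for i in order[: total - alloc.sum()]:
        alloc[i] += 1
    return alloc

def _allocate_positives(counts, n_pos):
    """Positives per grade category: none below 25% DS, rates rising with grade."""
    counts = np.asarray(counts, dtype=int)
    rates = np.asarray(DEFAULT_POSITIVE_RATES)
    alloc = _largest_remainder(counts * rates, n_pos)
    alloc = np.minimum(alloc, counts)
    alloc[:2] = 0
    # redistribute any shortfall to eligible categories with free capacity
    while alloc.sum() < n_pos:
        free = np.where((counts - alloc > 0) & (rates > 0))[0]
        if len(free) == 0:
            raise ValueError(
                f"cannot place {n_pos} positives with category counts "
                f"{tuple(counts)} and no positives below 25% DS"
            )
        j = free[np.argmax((counts - alloc)[free])]
        alloc[j] += 1
    return alloc


_GRADE_BY_ORDINAL = [
    StenosisGrade.G0,
    StenosisGrade.G1,
    StenosisGrade.G2,
    StenosisGrade.G3,
    StenosisGrade.G4,
]


def _vessel_grades(rng, category):
    """1-3 vessels; the culprit carries the category grade, others at most it."""
    n_vessels = int(rng.integers(1, 4))
    grades = [_GRADE_BY_ORDINAL[category]]
    for _ in range(n_vessels - 1):
        if rng.random() < 0.1:
            grades.append(StenosisGrade.ND)
        else:
            grades.append(_GRADE_BY_ORDINAL[int(rng.integers(0, category + 1))])
    perm = rng.permutation(n_vessels)
    return [grades[i] for i in perm]


def generate_cohort(spec: CohortSpec, out_dir=None, keep_volumes=True):
    """Generate the full synthetic cohort.

    Returns a SyntheticCohort; when ``out_dir`` is given, additionally
    writes one NIfTI volume and mask per patient plus the cohort CSV
    (one row per vessel).  The spec is validated before any file is
    written, and two runs with the same seed produce byte-identical
    outputs.
    """
    if spec.category_counts is not None:
        counts = np.asarray(spec.category_counts, dtype=int)
    else:
        counts = _largest_remainder(DEFAULT_CATEGORY_WEIGHTS, spec.n_patients)
    pos_per_cat = _allocate_positives(counts, spec.n_positive)

    # per-patient category and label, fixed before any randomness is used
    categories, labels = [], []
    for cat in range(5):
        categories.extend([cat] * counts[cat])
        labels.extend([True] * pos_per_cat[cat])
        labels.extend([False] * (counts[cat] - pos_per_cat[cat]))

    cohort = SyntheticCohort(spec=spec, records=[])
    for i in range(spec.n_patients):
        child = np.random.SeedSequence(spec.seed, spawn_key=(i,))
        s_img, s_vessel, s_phys = child.generate_state(3) % (2**31 - 1)
        rng = np.random.Generator(np.random.Philox(int(s_vessel)))
        grades = _vessel_grades(rng, categories[i])
        ffr, ica = assign_physiology(labels[i], grades, int(s_phys))
        record = PatientRecord(
            patient_id=f"P{i:04d}",
            vessel_grades=tuple(grades),
            ffr_values=ffr,
            ica_ds_percent=ica,
            prior_event=bool(rng.random() < PRIOR_EVENT_RATE),
            true_label=bool(labels[i]),
        )
        cohort.records.append(record)
        params = sample_phantom_params(int(s_img), spec)
        cohort.params.append(params)
        if keep_volumes or out_dir is not None:
            volume, mask = generate_phantom_volume(params, labels[i], spec)
            if keep_volumes:
                cohort.volumes.append(volume)
                cohort.masks.append(mask)
            if out_dir is not None:
                from .io import write_volume

                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                write_volume(
                    out / f"{record.patient_id}_ct.nii.gz",
                    volume,
                    spec.voxel_spacing,
                    dtype=np.int16,
                )
                write_volume(
                    out / f"{record.patient_id}_mask.nii.gz",
                    mask,
                    spec.voxel_spacing,
                    dtype=np.uint8,
                )

    if out_dir is not None and spec.n_patients > 0:
        from .io import write_cohort_table

        write_cohort_table(Path(out_dir) / "cohort.csv", cohort.records)
    return cohort
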