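"""File formats: NIfTI volumes/masks and the per-vessel cohort table."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PatientRecord
from .triage import StenosisGrade

__all__ = [
    "CTVolume",
    "read_volume",
    "write_volume",
    "read_cohort_table",
    "write_cohort_table",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "patient_id",
    "vessel_id",
    "ccta_grade",
    "ffr",
    "ica_ds_percent",
    "prior_event",
    "true_label",
]


@dataclass
class CTVolume:
    """3D intensity grid in HU, axis order (z, y, x), spacing in mm."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    @property
    def shape(self):
        return self.data.shape


def write_volume(path, data, spacing=(1.0, 1.0, 1.0), dtype=np.int16):
    """Write a (z, y, x) array as NIfTI with the given voxel spacing.

    HU volumes are stored as signed 16-bit, masks as unsigned 8-bit.
    """
    data = np.asarray(data)
    if dtype is np.int16:
        data = np.clip(np.rint(data), -32768, 32767)
    # NIfTI stores fastest-varying axis first; keep (x, y, z) on disk
    arr = np.ascontiguousarray(data.transpose(2, 1, 0)).astype(dtype)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(float(s) for s in (spacing[2], spacing[1], spacing[0])))
    nib.save(img, str(path))


def read_volume(path) -> CTVolume:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return CTVolume(
        data=arr.transpose(2, 1, 0).astype(float),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
    )


def write_cohort_table(path, records):
    """One CSV row per vessel; empty cells where FFR/ICA were not measured."""
    rows = []
    for rec in records:
        for v, grade in enumerate(rec.vessel_grades):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "vessel_id": v,
                    "ccta_grade": grade.value,
                    "ffr": rec.ffr_values[v],
                    "ica_ds_percent": rec.ica_ds_percent[v],
                    "prior_event": rec.prior_event,
                    "true_label": rec.true_label,
                }
            )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def _parse_bool(value, row):
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"row {row}: cannot parse boolean {value!r}")


def read_cohort_table(path) -> list:
    """Parse the cohort CSV back into PatientRecord objects.

    Vessel rows are grouped by patient_id (vessel order by vessel_id);
    unknown grade tokens and duplicate (patient, vessel) pairs are
    rejected with the offending row number (1-based, excluding header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} is missing columns {missing}")

    seen = set()
    parsed = {}
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        key = (row["patient_id"], int(row["vessel_id"]))
        if key in seen:
            raise ValueError(f"row {rownum}: duplicate patient/vessel pair {key}")
        seen.add(key)
        try:
            grade = StenosisGrade.from_token(row["ccta_grade"])
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from None
        ffr = None if pd.isna(row["ffr"]) else float(row["ffr"])
        ica = None if pd.isna(row["ica_ds_percent"]) else float(row["ica_ds_percent"])
        entry = parsed.setdefault(
            row["patient_id"],
            {"vessels": [], "prior": None, "label": None},
        )
        entry["vessels"].append((int(row["vessel_id"]), grade, ffr, ica))
        prior = _parse_bool(row["prior_event"], rownum)
        label = _parse_bool(row["true_label"], rownum)
        for fieldname, value in (("prior", prior), ("label", label)):
            if entry[fieldname] is None:
                entry[fieldname] = value
            elif entry[fieldname] != value:
                raise ValueError(
                    f"row {rownum}: inconsistent {fieldname} flag for patient "
                    f"{row['patient_id']}"
                )

    records = []
    for pid, entry in parsed.items():
        vessels = sorted(entry["vessels"])
        records.append(
            PatientRecord(
                patient_id=pid,
                vessel_grades=tuple(v[1] for v in vessels),
                ffr_values=tuple(v[2] for v in vessels),
                ica_ds_percent=tuple(v[3] for v in vessels),
                prior_event=entry["prior"],
                true_label=entry["label"],
            )
        )
    return records
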