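"""Examination intake under both data-availability scenarios.

Scenario 2 (PACS era): technical parameters are read from DICOM headers,
series are grouped by series identifier, and the scanned body region is
recognized from the images themselves by threshold segmentation. Scenario
1 (pre-PACS): exams carry only the limited roster fields, and parameters
come from hospital/period/scanner/age/exam-type protocol tables filled in
from questionnaires.

Extraction never invents values: an absent DICOM attribute stays ``None``
and is listed in the validation report; downstream stages decide how to
fill it.
"""
from __future__ import annotations

import datetime as dt
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.errors import InvalidDicomError
from scipy import ndimage

from .errors import ConsistencyError, FormatError, ValidationError
from .records import (ExaminationRecord, PatientRecord, ProtocolEntry,
                      SeriesRecord, SliceFeatures)

__all__ = [
    "extract_series_metadata", "slice_features", "classify_body_region",
    "GroupKey", "assign_group", "lookup_protocol", "validate_minimum_dataset",
    "read_protocol_csv", "DEFAULT_AGE_GROUPS", "age_group_of",
]

#: default age bands, mirroring the phantom age series (years)
DEFAULT_AGE_GROUPS = ("<1", "1-4", "5-9", "10-14", "15-19")

# body-region rule thresholds (config defaults)
THETA_BONE = 0.05
THETA_AIR = 0.05
THETA_LUNG = 0.15

# segmentation thresholds on HU-like pixel values
_BODY_HU = -400.0
_BONE_HU = 300.0
_AIR_HU = -400.0


# ---------------------------------------------------------------------------
# Scenario 2: DICOM extraction
# ---------------------------------------------------------------------------

def _get(ds, name):
    v = getattr(ds, name, None)
    return None if v in (None, "") else v


def _series_from_datasets(datasets: list) -> tuple[SeriesRecord, list[str]]:
    ds = datasets[0]
    rotation = _get(ds, "RevolutionTime")
    if rotation is None:
        exp_time = _get(ds, "ExposureTime")  # ms
        rotation = float(exp_time) / 1000.0 if exp_time is not None else None
    zs = []
    for d in datasets:
        if _get(d, "SliceLocation") is not None:
            zs.append(float(d.SliceLocation))
        elif _get(d, "ImagePositionPatient") is not None:
            zs.append(float(d.ImagePositionPatient[2]))
    start, end = (min(zs), max(zs)) if zs else (None, None)
    if start is not None and start == end and len(datasets) > 1:
        start = end = None  # degenerate position table: treat as absent
    rec = SeriesRecord(
        series_uid=_get(ds, "SeriesInstanceUID"),
        manufacturer=_get(ds, "Manufacturer"),
        model=_get(ds, "ManufacturerModelName"),
        kvp=float(ds.KVP) if _get(ds, "KVP") is not None else None,
        tube_current_ma=(float(ds.XRayTubeCurrent)
                         if _get(ds, "XRayTubeCurrent") is not None else None),
        rotation_time_s=float(rotation) if rotation is not None else None,
        exposure_mas=float(ds.Exposure) if _get(ds, "Exposure") is not None else None,
        pitch=(float(ds.SpiralPitchFactor)
               if _get(ds, "SpiralPitchFactor") is not None else None),
        collimation_mm=(float(ds.TotalCollimationWidth)
                        if _get(ds, "TotalCollimationWidth") is not None else None),
        scan_start_mm=start, scan_end_mm=end,
        ctdi_vol=float(ds.CTDIvol) if _get(ds, "CTDIvol") is not None else None,
    )
    missing = rec.missing_fields()
    return rec, missing


def extract_series_metadata(paths: list[str | Path]
                            ) -> tuple[ExaminationRecord, PatientRecord, dict]:
    """Read a DICOM file set into an examination record.

    Returns (examination, patient, validation report). Series are grouped
    by SeriesInstanceUID; scan start/end come from the min/max slice
    positions. Raises :class:`FormatError` for non-DICOM input and
    :class:`ConsistencyError` when the set mixes patients.
    """
    if not paths:
        raise ValidationError("empty DICOM file set")
    datasets = []
    for p in paths:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except (InvalidDicomError, OSError, struct.error) as exc:
            raise FormatError(f"{p}: not a readable DICOM Part 10 file ({exc})")
    pids = {str(_get(d, "PatientID")) for d in datasets}
    if len(pids) > 1:
        raise ConsistencyError(f"file set mixes patients: {sorted(pids)}")
    by_series: dict[str, list] = {}
    for d in datasets:
        by_series.setdefault(str(_get(d, "SeriesInstanceUID")), []).append(d)
    series, report = [], {"missing": {}, "n_files": len(datasets)}
    for uid, group in sorted(by_series.items()):
        rec, missing = _series_from_datasets(group)
        series.append(rec)
        if missing:
            report["missing"][uid] = missing
    d0 = datasets[0]
    study_date = _get(d0, "StudyDate") or _get(d0, "SeriesDate")
    exam_date = (dt.datetime.strptime(study_date, "%Y%m%d").date()
                 if study_date else None)
    birth = _get(d0, "PatientBirthDate")
    sex_map = {"M": "male", "F": "female"}
    patient = PatientRecord(
        patient_id=str(_get(d0, "PatientID")),
        sex=sex_map.get(_get(d0, "PatientSex"), _get(d0, "PatientSex") or "unknown"),
        birth_date=(dt.datetime.strptime(birth, "%Y%m%d").date() if birth else None),
        hospital_id=_get(d0, "InstitutionName"))
    body_part = _get(d0, "BodyPartExamined")
    exam = ExaminationRecord(
        patient_id=patient.patient_id, exam_date=exam_date,
        body_region=body_part.lower() if body_part else None,
        series=series, scenario="post_pacs", n_scans=len(series))
    return exam, patient, report


# ---------------------------------------------------------------------------
# body-region recognition
# ---------------------------------------------------------------------------

def slice_features(image: np.ndarray, pixel_spacing_mm: float = 1.0) -> SliceFeatures:
    """Threshold-segmentation features of one axial image (HU-like values).

    body mask: pixels above soft-tissue floor; bone: high-intensity pixels
    within the body; internal air: low-intensity pixels inside the filled
    body outline (lung, bowel gas).
    """
    img = np.asarray(image, float)
    body = img > _BODY_HU
    if not body.any():
        return SliceFeatures(0.0, 0.0, 0.0)
    filled = ndimage.binary_fill_holes(body)
    n_body = int(filled.sum())
    bone = (img > _BONE_HU) & filled
    air = (img < _AIR_HU) & filled
    return SliceFeatures(
        body_area_mm2=n_body * pixel_spacing_mm ** 2,
        bone_fraction=bone.sum() / n_body,
        air_fraction=air.sum() / n_body)


def _rule_label(bone: float, air: float, theta_bone: float, theta_air: float,
                theta_lung: float) -> str:
    if bone > theta_bone and air < theta_air:
        return "head"
    if air > theta_lung:
        return "chest"
    return "abdomen"


def classify_body_region(features: list[SliceFeatures], *,
                         theta_bone: float = THETA_BONE,
                         theta_air: float = THETA_AIR,
                         theta_lung: float = THETA_LUNG) -> tuple[str, float]:
    """Recognize the scanned body region from per-slice features.

    The scan-level label applies the rule cascade to the per-scan medians;
    confidence is the fraction of slices whose own rule label agrees.
    """
    if not features:
        raise ValidationError("empty feature sequence")
    bones = np.array([f.bone_fraction for f in features])
    airs = np.array([f.air_fraction for f in features])
    label = _rule_label(float(np.median(bones)), float(np.median(airs)),
                        theta_bone, theta_air, theta_lung)
    per_slice = [_rule_label(b, a, theta_bone, theta_air, theta_lung)
                 for b, a in zip(bones, airs)]
    confidence = sum(l == label for l in per_slice) / len(per_slice)
    return label, confidence


# ---------------------------------------------------------------------------
# Scenario 1: grouping and protocol lookup
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupKey:
    """Patient-grouping key: hospital x period x scanner x exam type x age."""

    hospital_id: str
    period_from: dt.date | None
    scanner_model: str | None
    exam_type: str
    age_group: str
    matched: bool = True

    @staticmethod
    def unmatched() -> "GroupKey":
        return GroupKey("", None, None, "", "", matched=False)


def age_group_of(age: float, bands=DEFAULT_AGE_GROUPS) -> str:
    edges = []
    for band in bands:
        if band.startswith("<"):
            edges.append((0.0, float(band[1:])))
        else:
            lo, hi = band.split("-")
            edges.append((float(lo), float(hi) + 1.0))
    for band, (lo, hi) in zip(bands, edges):
        if lo <= age < hi:
            return band
    return bands[-1] if age >= edges[-1][1] else bands[0]


def assign_group(patient: PatientRecord, exam: ExaminationRecord,
                 protocol_table: list[ProtocolEntry],
                 age_bands=DEFAULT_AGE_GROUPS) -> GroupKey:
    """Total grouping function: every exam maps to one key or to the
    explicit unmatched key (never an error).

    Periods are half-open [from, to): a date on the boundary belongs to
    the later period, i.e. the earlier period excludes its end date.
    """
    if exam.exam_date is None:
        raise ValidationError("exam date required for grouping")
    region = exam.region()
    if patient.hospital_id is None or region is None:
        return GroupKey.unmatched()
    age = patient.age_at(exam.exam_date)
    if age is None:
        return GroupKey.unmatched()
    band = age_group_of(age, age_bands)
    model = next((s.model for s in exam.series if s.model is not None), None)
    candidates = [
        e for e in protocol_table
        if e.hospital_id == patient.hospital_id
        and e.period[0] <= exam.exam_date < e.period[1]
        and e.exam_type == region and e.age_group == band
        and (model is None or e.scanner_model is None or e.scanner_model == model)
    ]
    if not candidates:
        return GroupKey.unmatched()
    # prefer a scanner-specific entry over the period default
    chosen = next((e for e in candidates if model is not None
                   and e.scanner_model == model), candidates[0])
    return GroupKey(chosen.hospital_id, chosen.period[0], chosen.scanner_model,
                    chosen.exam_type, chosen.age_group)


def lookup_protocol(key: GroupKey, protocol_table: list[ProtocolEntry]
                    ) -> list[tuple[tuple, float]]:
    """Joint parameter rows (kvp, mas, pitch, scan_length_mm) with
    normalized weights; empty for unmatched keys."""
    if not key.matched:
        return []
    for e in protocol_table:
        if (e.hospital_id, e.period[0], e.scanner_model, e.exam_type,
                e.age_group) == (key.hospital_id, key.period_from,
                                 key.scanner_model, key.exam_type, key.age_group):
            return list(zip([tuple(r) for r in e.rows], e.normalized_weights()))
    return []


MINIMUM_DATASET_ITEMS = (
    "sex, age and department",
    "year and scanner type",
    "body area scanned",
    "date of scan",
    "number of scans",
)


def validate_minimum_dataset(patient: PatientRecord,
                             exam: ExaminationRecord) -> list[str]:
    """Check the five-item minimum data set for crude dose estimation.

    Body area may be inferred from the examination type; scanner type may
    be satisfied by any series-level manufacturer/model or generation.
    """
    missing = []
    if not (patient.sex in ("male", "female") and patient.birth_date is not None
            and patient.hospital_id is not None):
        missing.append(MINIMUM_DATASET_ITEMS[0])
    has_scanner = any(s.model is not None or s.manufacturer is not None
                      for s in exam.series)
    if exam.exam_date is None or not has_scanner:
        missing.append(MINIMUM_DATASET_ITEMS[1])
    if exam.region() is None:
        missing.append(MINIMUM_DATASET_ITEMS[2])
    if exam.exam_date is None:
        missing.append(MINIMUM_DATASET_ITEMS[3])
    if exam.n_scans is None:
        missing.append(MINIMUM_DATASET_ITEMS[4])
    return missing


# ---------------------------------------------------------------------------
# protocol-table CSV interface
# ---------------------------------------------------------------------------

_PROTOCOL_COLUMNS = ["hospital_id", "period_from", "period_to", "scanner_model",
                     "exam_type", "age_group", "kvp", "mas", "pitch",
                     "scan_length_mm", "weight"]


def read_protocol_csv(path: str | Path) -> list[ProtocolEntry]:
    """Read a protocol table from CSV (one parameter row per line; rows
    sharing hospital/period/scanner/exam/age form one entry)."""
    df = pd.read_csv(path)
    missing_cols = set(_PROTOCOL_COLUMNS[:6]) - set(df.columns)
    if missing_cols:
        raise FormatError(f"protocol CSV lacks columns: {sorted(missing_cols)}")
    entries = []
    keys = ["hospital_id", "period_from", "period_to", "scanner_model",
            "exam_type", "age_group"]
    df["scanner_model"] = df["scanner_model"].where(df["scanner_model"].notna(), None)
    for key, grp in df.groupby(keys, dropna=False, sort=True):
        hosp, pfrom, pto, model, etype, band = key
        entries.append(ProtocolEntry(
            hospital_id=str(hosp),
            period=(dt.date.fromisoformat(str(pfrom)), dt.date.fromisoformat(str(pto))),
            scanner_model=None if pd.isna(model) else str(model),
            exam_type=str(etype), age_group=str(band),
            rows=[(r.kvp, r.mas, r.pitch, r.scan_length_mm)
                  for r in grp.itertuples()],
            weights=(list(grp["weight"]) if "weight" in grp
                     and grp["weight"].notna().all() else None)))
    return entries


def write_protocol_csv(entries: list[ProtocolEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        for (kvp, mas, pitch, length), w in zip(e.rows, e.normalized_weights()):
            rows.append({"hospital_id": e.hospital_id,
                         "period_from": e.period[0].isoformat(),
                         "period_to": e.period[1].isoformat(),
                         "scanner_model": e.scanner_model, "exam_type": e.exam_type,
                         "age_group": e.age_group, "kvp": kvp, "mas": mas,
                         "pitch": pitch, "scan_length_mm": length, "weight": w})
    pd.DataFrame(rows, columns=_PROTOCOL_COLUMNS).to_csv(path, index=False)
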