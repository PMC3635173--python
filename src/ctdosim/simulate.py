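"""Synthetic cohorts with known ground truth.

Generates every input the dose-reconstruction pipeline consumes —
patient rosters, examinations with true technical parameters, protocol
tables, DICOM file sets, axial image stacks, and outcome tables drawn
under a known excess relative risk — so recovery can be tested end to
end. Ground-truth doses are always computed by the same dose engine used
in reconstruction (there is no second dose model): reconstruction from
fully observed parameters must therefore reproduce the truth to machine
precision.

The two data-availability scenarios are produced by masking alone:
pre-PACS examinations keep only the limited roster fields (department,
date, body part, number of scans, sex, birth date) while per-series
technical parameters are removed; post-PACS examinations keep technical
parameters subject to configurable per-field dropout. Masking never
alters a retained value.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .coefficients import synthetic_coefficient_table
from .errors import ConfigurationError
from .phantoms import AGE_CLASSES, build_reference_phantom
from .records import ExaminationRecord, PatientRecord, ProtocolEntry, SeriesRecord
from .registry import load_era_registry
from .uncertainty import CohortDoseModel, stable_seed

__all__ = ["SynthConfig", "GroundTruth", "generate_cohort", "mask_for_scenario",
           "write_dicom_fixtures", "generate_axial_images",
           "generate_protocol_table", "default_dose_model", "generate_outcomes"]

REGIONS = ("head", "chest", "abdomen")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 500
    n_hospitals: int = 3
    span: tuple[dt.date, dt.date] = (dt.date(1990, 1, 1), dt.date(2010, 12, 31))
    #: PACS transition date per hospital (hospital index -> date); hospitals
    #: not listed transition on 2000-01-01
    pacs_transition: dict[int, dt.date] = field(default_factory=dict)
    mean_extra_exams: float = 0.5  # exams per patient = 1 + Poisson(this)
    region_probs: tuple[float, float, float] = (0.5, 0.2, 0.3)  # head/chest/abdomen
    #: per-field dropout probability for post-PACS series (Scenario 2 noise)
    post_pacs_dropout: dict[str, float] = field(default_factory=dict)
    true_err_per_gy: float = 2.0
    baseline_rate: float = 2e-3  # cases per person-year in unexposed
    person_years_band: tuple[float, float] = (5.0, 15.0)
    target_organ: str = "red_bone_marrow"
    organs: tuple[str, ...] = ("red_bone_marrow", "brain", "colon")
    master_seed: int = 0

    def __post_init__(self):
        if self.span[0] >= self.span[1]:
            raise ConfigurationError("calendar span must be non-empty")
        if not np.isclose(sum(self.region_probs), 1.0):
            raise ConfigurationError("region probabilities must sum to 1")
        for p in self.post_pacs_dropout.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("dropout probabilities must be in [0,1]")

    def transition_of(self, hospital: int) -> dt.date:
        return self.pacs_transition.get(hospital, dt.date(2000, 1, 1))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    exams_true: dict[str, list[ExaminationRecord]]  # fully observed
    doses_mgy: pd.DataFrame  # index patient_id, columns organs
    expected_rate: pd.Series  # cases per person-year, per patient
    outcomes: pd.DataFrame  # patient_id, person_years, cases, stratum


def default_dose_model(organs=("red_bone_marrow", "brain", "colon")
                       ) -> CohortDoseModel:
    """Dose model over synthetic coefficient tables for the whole family."""
    tables = {(ac, sex): synthetic_coefficient_table(build_reference_phantom(ac, sex))
              for ac in AGE_CLASSES for sex in ("male", "female")}
    return CohortDoseModel(tables, organs=organs)


def generate_protocol_table(config: SynthConfig) -> list[ProtocolEntry]:
    """Questionnaire-style protocol table consistent with the era registry.

    One entry per hospital x era x exam type x age group, with two joint
    parameter rows (weights 2:1) drawn from the era-default distributions.
    These rows are also the pool the generator draws true pre-PACS
    parameters from, so Scenario-1 lookup is well specified.
    """
    reg = load_era_registry()
    bands = ("<1", "1-4", "5-9", "10-14", "15-19")
    entries = []
    for h in range(config.n_hospitals):
        trans = config.transition_of(h)
        periods = [(config.span[0], trans, "ScannerA"),
                   (trans, config.span[1] + dt.timedelta(days=1), "ScannerB")]
        for pfrom, pto, model in periods:
            if pfrom >= pto:
                continue
            mid = pfrom + (pto - pfrom) / 2
            for region in REGIONS:
                for band in bands:
                    rng = np.random.Generator(np.random.Philox(key=np.uint64(
                        stable_seed(config.master_seed, "protocol", h, pfrom,
                                    region, band))))
                    rows = []
                    for _ in range(2):
                        kvp = reg.pdf(mid, region, "kvp").sample(rng)["kvp"]
                        mas = reg.pdf(mid, region, "mas").sample(rng)
                        pitch = reg.pdf(mid, region, "pitch").sample(rng)
                        length = reg.pdf(mid, region, "scan_length_mm").sample(rng)
                        # mAs as an integer and coarse rounding elsewhere:
                        # protocol questionnaires record round numbers, and
                        # the DICOM Exposure attribute is an integer string
                        rows.append((float(kvp), float(round(float(mas))),
                                     round(float(pitch), 2), round(float(length), 0)))
                    entries.append(ProtocolEntry(
                        hospital_id=f"H{h}", period=(pfrom, pto),
                        scanner_model=model, exam_type=region, age_group=band,
                        rows=rows, weights=[2.0, 1.0]))
    return entries


def _band_of(age: float) -> str:
    for band, (lo, hi) in zip(("<1", "1-4", "5-9", "10-14", "15-19"),
                              ((0, 1), (1, 5), (5, 10), (10, 15), (15, 20))):
        if lo <= age < hi:
            return band
    return "15-19"


def generate_cohort(config: SynthConfig,
                    dose_model: CohortDoseModel | None = None,
                    protocol_table: list[ProtocolEntry] | None = None
                    ) -> tuple[dict, dict, GroundTruth]:
    """Draw a cohort with fully observed examinations and known doses.

    Returns (patients, exams_by_patient, ground truth); the exams carry
    their true technical parameters (Scenario masking is a separate,
    subsequent step). Identical seeds give identical cohorts.
    """
    dose_model = dose_model or default_dose_model(config.organs)
    protocol_table = protocol_table or generate_protocol_table(config)
    proto_index = {}
    for e in protocol_table:
        proto_index.setdefault(
            (e.hospital_id, e.period[0], e.exam_type, e.age_group), e)
    rng = np.random.Generator(np.random.Philox(key=np.uint64(
        stable_seed(config.master_seed, "cohort"))))
    span_days = (config.span[1] - config.span[0]).days
    patients, exams_by_patient = {}, {}
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        sex = "male" if rng.random() < 0.5 else "female"
        hospital = int(rng.integers(config.n_hospitals))
        first = config.span[0] + dt.timedelta(days=int(rng.integers(span_days)))
        age0 = float(rng.uniform(0.0, 19.5))
        birth = first - dt.timedelta(days=int(age0 * 365.25))
        patients[pid] = PatientRecord(pid, sex, birth_date=birth,
                                      hospital_id=f"H{hospital}")
        n_exams = 1 + rng.poisson(config.mean_extra_exams)
        date = first
        exams = []
        for _ in range(n_exams):
            # exam ages stay inside the paediatric range [0, 20)
            if date > config.span[1] or patients[pid].age_at(date) >= 20.0:
                break
            region = str(rng.choice(REGIONS, p=config.region_probs))
            trans = config.transition_of(hospital)
            scenario = "pre_pacs" if date < trans else "post_pacs"
            age = patients[pid].age_at(date)
            period_from = config.span[0] if scenario == "pre_pacs" else trans
            entry = proto_index.get((f"H{hospital}", period_from, region,
                                     _band_of(age)))
            ridx = rng.choice(len(entry.rows), p=np.asarray(
                entry.normalized_weights()))
            kvp, mas, pitch, length = entry.rows[ridx]
            # per-patient anatomical jitter of the scan length, at the
            # 0.1 mm table-position resolution DICOM slice locations use
            length = round(float(length) * float(rng.uniform(0.9, 1.1)), 1)
            series = SeriesRecord(
                series_uid=f"{pid}.{len(exams)}.1",
                manufacturer="SynthMed", model=entry.scanner_model,
                kvp=float(kvp), exposure_mas=float(mas),
                tube_current_ma=float(mas), rotation_time_s=1.0,
                pitch=float(pitch), collimation_mm=10.0,
                scan_start_mm=0.0, scan_end_mm=length)
            exams.append(ExaminationRecord(
                patient_id=pid, exam_date=date, body_region=region,
                series=[series], scenario=scenario, n_scans=1))
            date = date + dt.timedelta(days=int(rng.uniform(180, 1100)))
        exams_by_patient[pid] = exams

    dose_rows = {}
    for pid, exams in exams_by_patient.items():
        total = dict.fromkeys(config.organs, 0.0)
        for exam in exams:
            d = dose_model.exam_dose(patients[pid], exam)
            for o in config.organs:
                total[o] += d[o]
        dose_rows[pid] = total
    doses = pd.DataFrame.from_dict(dose_rows, orient="index").sort_index()
    outcomes, rates = generate_outcomes(config, patients, doses)
    gt = GroundTruth(exams_true={p: list(e) for p, e in exams_by_patient.items()},
                     doses_mgy=doses, expected_rate=rates, outcomes=outcomes)
    return patients, exams_by_patient, gt


def generate_outcomes(config: SynthConfig, patients: dict,
                      doses_mgy: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Poisson outcomes under rate = baseline * (1 + ERR * D_Gy)."""
    rng = np.random.Generator(np.random.Philox(key=np.uint64(
        stable_seed(config.master_seed, "outcomes"))))
    rows = []
    rates = {}
    for pid in doses_mgy.index:
        d_gy = doses_mgy.loc[pid, config.target_organ] / 1000.0
        rate = config.baseline_rate * (1.0 + config.true_err_per_gy * d_gy)
        py = float(rng.uniform(*config.person_years_band))
        cases = int(rng.poisson(rate * py))
        rows.append({"patient_id": pid, "person_years": py, "cases": cases,
                     "stratum": patients[pid].sex})
        rates[pid] = rate
    return pd.DataFrame(rows), pd.Series(rates, name="expected_rate")


# ---------------------------------------------------------------------------
# scenario masking
# ---------------------------------------------------------------------------

_PRE_PACS_STRIPPED = ("manufacturer", "model", "kvp", "tube_current_ma",
                      "rotation_time_s", "exposure_mas", "pitch",
                      "collimation_mm", "scan_start_mm", "scan_end_mm",
                      "ctdi_w", "ctdi_vol", "modulation_profile")
_DROPPABLE = ("kvp", "exposure_mas", "tube_current_ma", "rotation_time_s",
              "pitch", "collimation_mm", "scan_start_mm", "scan_end_mm")


def mask_for_scenario(exams_by_patient: dict, config: SynthConfig) -> dict:
    """Apply the two-scenario availability masking.

    Pre-PACS: series keep only their identifier; all technical parameters
    are absent (the roster-level fields on the examination remain).
    Post-PACS: each droppable field is removed independently with its
    configured probability. Retained values are never altered.
    """
    out = {}
    for pid, exams in exams_by_patient.items():
        masked_exams = []
        for iex, exam in enumerate(exams):
            new_series = []
            for isr, s in enumerate(exam.series):
                if exam.scenario == "pre_pacs":
                    kw = {f: None for f in _PRE_PACS_STRIPPED}
                    new_series.append(dataclasses.replace(s, **kw))
                else:
                    rng = np.random.Generator(np.random.Philox(key=np.uint64(
                        stable_seed(config.master_seed, "mask", pid, iex, isr))))
                    kw = {}
                    for fname in _DROPPABLE:
                        p = config.post_pacs_dropout.get(fname, 0.0)
                        if p > 0 and rng.random() < p:
                            kw[fname] = None
                    if ("scan_start_mm" in kw) != ("scan_end_mm" in kw):
                        kw["scan_start_mm"] = None
                        kw["scan_end_mm"] = None
                    new_series.append(dataclasses.replace(s, **kw) if kw else s)
            masked_exams.append(dataclasses.replace(exam, series=new_series))
        out[pid] = masked_exams
    return out


# ---------------------------------------------------------------------------
# DICOM fixtures
# ---------------------------------------------------------------------------

def write_dicom_fixtures(exams_by_patient: dict, patients: dict,
                         out_dir: str | Path) -> list[dict]:
    """Write post-PACS examinations as DICOM Part 10 CT file sets.

    Two single-frame files per series (first and last slice position).
    Absent optional fields are omitted from the header, never zero-filled,
    so the intake round trip preserves absence. Returns a manifest with
    one entry per series: patient id, series UID and the file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for pid, exams in sorted(exams_by_patient.items()):
        patient = patients[pid]
        for iex, exam in enumerate(exams):
            if exam.scenario != "post_pacs":
                continue
            study_uid = generate_uid(entropy_srcs=[pid, str(iex)])
            for isr, s in enumerate(exam.series):
                series_uid = generate_uid(entropy_srcs=[pid, str(iex), str(isr)])
                positions = [s.scan_start_mm, s.scan_end_mm]
                if positions[0] is None:
                    positions = [None]
                entry = {"patient_id": pid, "series_uid": str(series_uid),
                         "paths": []}
                for k, zpos in enumerate(positions):
                    ds = Dataset()
                    ds.SOPClassUID = CTImageStorage
                    ds.SOPInstanceUID = generate_uid(
                        entropy_srcs=[pid, str(iex), str(isr), str(k)])
                    ds.Modality = "CT"
                    ds.PatientID = pid
                    ds.PatientSex = {"male": "M", "female": "F"}.get(patient.sex, "O")
                    if patient.birth_date is not None:
                        ds.PatientBirthDate = patient.birth_date.strftime("%Y%m%d")
                    if patient.hospital_id is not None:
                        ds.InstitutionName = patient.hospital_id
                    if exam.exam_date is not None:
                        ds.StudyDate = exam.exam_date.strftime("%Y%m%d")
                    if exam.body_region is not None:
                        ds.BodyPartExamined = exam.body_region.upper()
                    ds.StudyInstanceUID = study_uid
                    ds.SeriesInstanceUID = series_uid
                    if s.manufacturer is not None:
                        ds.Manufacturer = s.manufacturer
                    if s.model is not None:
                        ds.ManufacturerModelName = s.model
                    if s.kvp is not None:
                        ds.KVP = s.kvp
                    if s.tube_current_ma is not None:
                        ds.XRayTubeCurrent = int(round(s.tube_current_ma))
                    if s.rotation_time_s is not None:
                        ds.ExposureTime = int(round(s.rotation_time_s * 1000))
                    if s.exposure_mas is not None:
                        ds.Exposure = int(round(s.exposure_mas))
                    if s.pitch is not None:
                        ds.SpiralPitchFactor = s.pitch
                    if s.collimation_mm is not None:
                        ds.TotalCollimationWidth = s.collimation_mm
                    if s.ctdi_vol is not None:
                        ds.CTDIvol = s.ctdi_vol
                    if zpos is not None:
                        ds.SliceLocation = zpos
                    path = out_dir / f"{pid}_e{iex}_s{isr}_{k}.dcm"
                    meta = FileMetaDataset()
                    meta.MediaStorageSOPClassUID = ds.SOPClassUID
                    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
                    meta.TransferSyntaxUID = ExplicitVRLittleEndian
                    ds.file_meta = meta
                    pydicom.dcmwrite(path, ds, enforce_file_format=True)
                    entry["paths"].append(path)
                manifest.append(entry)
    return manifest


# ---------------------------------------------------------------------------
# axial image stacks
# ---------------------------------------------------------------------------

def generate_axial_images(region: str, n_scans: int, seed: int, *,
                          n_slices: int = 8, size: int = 96,
                          noise_hu: float = 20.0,
                          jitter: float = 0.1) -> list[tuple[np.ndarray, str]]:
    """Labelled synthetic axial stacks for the region classifier.

    head: elliptical body with a high-intensity peripheral ring and no
    internal air; chest: body with two internal low-intensity ellipses;
    abdomen: body with neither. Values are HU-like (air -1000).
    """
    if region not in REGIONS:
        raise ConfigurationError(f"unknown region {region!r}")
    rng = np.random.Generator(np.random.Philox(key=np.uint64(seed)))
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = size / 2
    stacks = []
    for _ in range(n_scans):
        scale = 1.0 + float(rng.uniform(-jitter, jitter))
        a, b = 0.42 * size * scale, 0.34 * size * scale
        stack = np.empty((n_slices, size, size))
        for k in range(n_slices):
            img = np.full((size, size), -1000.0)
            r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
            img[r2 <= 1.0] = 40.0
            if region == "head":
                ring = (r2 <= 1.0) & (r2 >= 0.72)
                img[ring] = 800.0
            elif region == "chest":
                for sgn in (-1, 1):
                    lr2 = (((xx - cx - sgn * 0.45 * a) / (0.30 * a)) ** 2
                           + ((yy - cy) / (0.55 * b)) ** 2)
                    img[(lr2 <= 1.0) & (r2 <= 1.0)] = -820.0
            if noise_hu > 0:
                img += rng.normal(0.0, noise_hu, img.shape)
            stack[k] = img
        stacks.append((stack, region))
    return stacks
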