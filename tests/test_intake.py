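import dataclasses
import datetime as dt

import numpy as np
import pytest

from conftest import make_exam, make_patient, make_series
from ctdosim.errors import ConsistencyError, FormatError, ValidationError
from ctdosim.intake import (GroupKey, age_group_of, assign_group,
                            classify_body_region, extract_series_metadata,
                            lookup_protocol, read_protocol_csv, slice_features,
                            validate_minimum_dataset, write_protocol_csv)
from ctdosim.records import ProtocolEntry, SliceFeatures
from ctdosim.simulate import generate_axial_images, write_dicom_fixtures


# ---------------------------------------------------------------------------
# DICOM extraction
# ---------------------------------------------------------------------------

@pytest.fixture()
def dicom_exam(tmp_path):
    patient = make_patient()
    s1 = make_series(series_uid="u1", manufacturer="SynthMed", model="ScannerB",
                     tube_current_ma=100.0, rotation_time_s=1.0,
                     scan_start_mm=0.0, scan_end_mm=150.0)
    s2 = make_series(series_uid="u2", kvp=100.0, exposure_mas=80.0,
                     pitch=None, scan_start_mm=0.0, scan_end_mm=120.0)
    exam = make_exam(series=[s1, s2])
    manifest = write_dicom_fixtures({"P1": [exam]}, {"P1": patient}, tmp_path)
    paths = [p for e in manifest for p in e["paths"]]
    return patient, exam, manifest, paths


def test_two_series_fixture_counts_two_scans(dicom_exam):
    _, _, manifest, paths = dicom_exam
    assert len(manifest) == 2  # one manifest entry per series
    got, _, _ = extract_series_metadata(paths)
    assert got.n_scans == 2


def test_missing_pitch_reported_absent_never_defaulted(dicom_exam):
    _, _, manifest, paths = dicom_exam
    got, _, report = extract_series_metadata(paths)
    by_missing = {tuple(v) for v in report["missing"].values()}
    no_pitch = [s for s in got.series if s.pitch is None]
    assert len(no_pitch) == 1
    assert any("pitch" in miss for miss in by_missing)


def test_round_trip_field_identity(dicom_exam):
    patient, exam, _, paths = dicom_exam
    got, gpat, _ = extract_series_metadata(paths)
    # extraction orders series by generated UID; align on content instead
    orig = sorted(exam.series, key=lambda s: s.scan_end_mm)
    got_series = sorted(got.series, key=lambda s: s.scan_end_mm)
    fields = ("manufacturer", "model", "kvp", "tube_current_ma",
              "rotation_time_s", "exposure_mas", "pitch", "collimation_mm",
              "scan_start_mm", "scan_end_mm", "ctdi_vol")
    assert len(got_series) == len(orig)
    for o, g in zip(orig, got_series):
        for f in fields:
            assert getattr(g, f) == getattr(o, f), f
    assert gpat.sex == patient.sex and gpat.birth_date == patient.birth_date
    assert got.exam_date == exam.exam_date
    assert got.body_region == exam.body_region


def test_non_dicom_input_is_format_error(tmp_path):
    bad = tmp_path / "not_dicom.dcm"
    bad.write_bytes(b"definitely not dicom")
    with pytest.raises(FormatError):
        extract_series_metadata([bad])


def test_mixed_patients_is_consistency_error(tmp_path):
    exams, patients = {}, {}
    for pid in ("A", "B"):
        patients[pid] = make_patient(pid)
        exams[pid] = [make_exam(patient_id=pid)]
    manifest = write_dicom_fixtures(exams, patients, tmp_path)
    paths = [p for e in manifest for p in e["paths"]]
    with pytest.raises(ConsistencyError):
        extract_series_metadata(paths)


def test_extraction_reports_exactly_removed_fields(tmp_path):
    """No-default contract: remove k fields, report exactly those k."""
    s = make_series(kvp=None, pitch=None, scan_start_mm=0.0, scan_end_mm=99.0,
                    tube_current_ma=None, rotation_time_s=None)
    exam = make_exam(series=[s])
    manifest = write_dicom_fixtures({"P1": [exam]}, {"P1": make_patient()},
                                    tmp_path)
    got, _, report = extract_series_metadata(manifest[0]["paths"])
    (missing,) = report["missing"].values()
    assert set(missing) == {"kvp", "pitch"}


# ---------------------------------------------------------------------------
# body-region recognition
# ---------------------------------------------------------------------------

def _features(region, seed=0, **kw):
    (stack, label), = generate_axial_images(region, 1, seed, **kw)
    return [slice_features(sl) for sl in stack], label


def test_head_slices_classified_head_confidence_one():
    feats, _ = _features("head")
    region, conf = classify_body_region(feats)
    assert region == "head" and conf == 1.0


def test_chest_slices_classified_chest():
    feats, _ = _features("chest")
    assert classify_body_region(feats)[0] == "chest"


def test_abdomen_slices_classified_abdomen():
    feats, _ = _features("abdomen")
    assert classify_body_region(feats)[0] == "abdomen"


def test_mixed_slices_majority_confidence():
    chest, _ = _features("chest")
    abdomen, _ = _features("abdomen")
    mixed = chest[:6] + abdomen[:4]  # 60% chest slices
    region, conf = classify_body_region(mixed)
    assert region == "chest"
    assert conf == pytest.approx(0.6)


def test_empty_feature_sequence_rejected():
    with pytest.raises(ValidationError):
        classify_body_region([])


def test_noise_free_images_have_exact_features():
    feats, _ = _features("head", noise_hu=0.0, jitter=0.0)
    feats2, _ = _features("head", seed=99, noise_hu=0.0, jitter=0.0)
    for a, b in zip(feats, feats2):
        assert a == b  # configured means, no randomness left
    assert all(f.air_fraction == 0.0 for f in feats)
    assert all(f.bone_fraction > 0.05 for f in feats)


def test_slice_feature_fraction_bounds():
    with pytest.raises(ValidationError):
        SliceFeatures(10.0, 1.2, 0.0)


# ---------------------------------------------------------------------------
# grouping and protocol lookup
# ---------------------------------------------------------------------------

@pytest.fixture()
def protocol_table():
    early = ProtocolEntry("H0", (dt.date(1990, 1, 1), dt.date(2000, 1, 1)),
                          "ScannerA", "head", "5-9",
                          rows=[(120.0, 200.0, 1.0, 150.0)])
    late = ProtocolEntry("H0", (dt.date(2000, 1, 1), dt.date(2011, 1, 1)),
                         "ScannerB", "head", "5-9",
                         rows=[(120.0, 150.0, 1.0, 150.0),
                               (100.0, 180.0, 1.2, 140.0)],
                         weights=[2.0, 1.0])
    return [early, late]


def test_assign_group_inside_period(protocol_table):
    patient = make_patient(birth=dt.date(1990, 6, 1))
    exam = make_exam(exam_date=dt.date(1998, 6, 1),
                     series=[make_series(model=None)])
    key = assign_group(patient, exam, protocol_table)
    assert key.matched and key.period_from == dt.date(1990, 1, 1)


def test_assign_group_boundary_date_goes_to_later_period(protocol_table):
    """Half-open [from, to): the shared boundary date belongs to the later
    period — the earlier period excludes its end date."""
    patient = make_patient(birth=dt.date(1992, 6, 1))
    exam = make_exam(exam_date=dt.date(2000, 1, 1),
                     series=[make_series(model=None)])
    key = assign_group(patient, exam, protocol_table)
    assert key.matched and key.period_from == dt.date(2000, 1, 1)


def test_assign_group_unknown_hospital_unmatched(protocol_table):
    patient = make_patient(hospital_id="H9", birth=dt.date(1990, 6, 1))
    exam = make_exam(exam_date=dt.date(1998, 6, 1))
    key = assign_group(patient, exam, protocol_table)
    assert not key.matched


def test_assign_group_partitions_exams(protocol_table):
    patients = [make_patient(f"P{i}", birth=dt.date(1991, 1, 1),
                             hospital_id="H0" if i % 2 else "H9")
                for i in range(10)]
    exams = [make_exam(patient_id=p.patient_id, exam_date=dt.date(1997, 5, 1),
                       series=[make_series(model=None)]) for p in patients]
    keys = [assign_group(p, e, protocol_table) for p, e in zip(patients, exams)]
    assert len(keys) == len(exams)  # total function, one key per exam
    assert sum(k.matched for k in keys) == 5
    assert sum(not k.matched for k in keys) == 5


def test_lookup_protocol(protocol_table):
    one = lookup_protocol(GroupKey("H0", dt.date(1990, 1, 1), "ScannerA",
                                   "head", "5-9"), protocol_table)
    assert one == [((120.0, 200.0, 1.0, 150.0), 1.0)]
    two = lookup_protocol(GroupKey("H0", dt.date(2000, 1, 1), "ScannerB",
                                   "head", "5-9"), protocol_table)
    assert [w for _, w in two] == pytest.approx([2 / 3, 1 / 3])
    assert lookup_protocol(GroupKey.unmatched(), protocol_table) == []


def test_age_group_edges():
    assert age_group_of(0.5) == "<1"
    assert age_group_of(1.0) == "1-4"
    assert age_group_of(4.9) == "1-4"
    assert age_group_of(15.0) == "15-19"


def test_protocol_csv_round_trip(tmp_path, protocol_table):
    path = tmp_path / "protocols.csv"
    write_protocol_csv(protocol_table, path)
    back = read_protocol_csv(path)
    assert len(back) == len(protocol_table)
    for a, b in zip(sorted(back, key=lambda e: e.period[0]), protocol_table):
        assert a.hospital_id == b.hospital_id
        assert a.period == b.period
        assert a.rows == [tuple(r) for r in b.rows]
        assert a.normalized_weights() == pytest.approx(b.normalized_weights())


# ---------------------------------------------------------------------------
# minimum data set
# ---------------------------------------------------------------------------

def _exam_with_scanner(**kw):
    return make_exam(series=[make_series(model="ScannerB")], **kw)


def test_minimum_dataset_complete():
    assert validate_minimum_dataset(make_patient(), _exam_with_scanner()) == []


def test_minimum_dataset_missing_body_area():
    exam = _exam_with_scanner(region=None)
    exam = dataclasses.replace(exam, exam_type=None)
    missing = validate_minimum_dataset(make_patient(), exam)
    assert missing == ["body area scanned"]


def test_minimum_dataset_region_inferred_from_exam_type():
    exam = dataclasses.replace(_exam_with_scanner(region=None),
                               exam_type="head CT")
    assert validate_minimum_dataset(make_patient(), exam) == []
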