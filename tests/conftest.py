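import datetime as dt

import pytest

from ctdosim.coefficients import synthetic_coefficient_table
from ctdosim.materials import load_material_library
from ctdosim.phantoms import build_reference_phantom
from ctdosim.records import ExaminationRecord, PatientRecord, SeriesRecord
from ctdosim.simulate import SynthConfig, default_dose_model, generate_cohort, \
    generate_protocol_table


@pytest.fixture(scope="session")
def materials():
    return load_material_library()


@pytest.fixture(scope="session")
def phantom_10y():
    return build_reference_phantom("10y", "male")


@pytest.fixture(scope="session")
def phantom_1y():
    return build_reference_phantom("1y", "female")


@pytest.fixture(scope="session")
def table_10y(phantom_10y):
    return synthetic_coefficient_table(phantom_10y)


@pytest.fixture(scope="session")
def dose_model():
    return default_dose_model()


@pytest.fixture(scope="session")
def small_cohort(dose_model):
    """60 patients with default study conditions and known ground truth."""
    config = SynthConfig(
        n_patients=60, master_seed=11,
        post_pacs_dropout={"kvp": 0.1, "exposure_mas": 0.1, "pitch": 0.1,
                           "scan_start_mm": 0.1, "scan_end_mm": 0.1})
    protocols = generate_protocol_table(config)
    patients, exams, truth = generate_cohort(config, dose_model=dose_model,
                                             protocol_table=protocols)
    return config, protocols, patients, exams, truth


def make_series(**kw):
    defaults = dict(series_uid="s1", kvp=120.0, exposure_mas=100.0,
                    pitch=1.0, collimation_mm=10.0)
    defaults.update(kw)
    return SeriesRecord(**defaults)


def make_exam(patient_id="P1", region="head", series=None, **kw):
    return ExaminationRecord(
        patient_id=patient_id, exam_date=kw.pop("exam_date", dt.date(2005, 6, 1)),
        body_region=region, series=series if series is not None else [make_series()],
        scenario=kw.pop("scenario", "post_pacs"), **kw)


def make_patient(pid="P1", sex="male", birth=dt.date(1995, 6, 1), **kw):
    return PatientRecord(pid, sex, birth_date=birth,
                         hospital_id=kw.pop("hospital_id", "H0"), **kw)
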