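import dataclasses

import numpy as np
import pytest

from conftest import make_exam, make_series
from ctdosim.engine import (accumulate_patient_dose, compute_exam_dose,
                            compute_series_dose, ctdi_vol, dlp, map_scan_range)
from ctdosim.errors import (ConsistencyError, ExtrapolationError,
                            ReconstructionError, ValidationError)


def test_ctdi_vol():
    assert ctdi_vol(10.0, 1.0) == 10.0
    assert ctdi_vol(10.0, 2.0) == 5.0
    with pytest.raises(ValidationError):
        ctdi_vol(10.0, 0.0)


def test_dlp():
    assert dlp(5.0, 200.0) == 100.0
    assert dlp(5.0, 0.0) == 0.0
    assert dlp(0.0, 200.0) == 0.0
    with pytest.raises(ValidationError):
        dlp(5.0, -1.0)


def test_ctdi_identity_restored(phantom_10y, table_10y):
    """CTDIvol * pitch == CTDIw for any positive pitch, exactly."""
    for pitch in (0.5, 1.0, 1.375, 2.0):
        s = make_series(pitch=pitch)
        _, prov = compute_series_dose(s, phantom_10y, table_10y, region="head")
        ctdiw = table_10y.ctdiw_at(s.kvp, 0.5 * sum(prov["z_interval"]))
        assert prov["ctdi_vol_mgy"] * pitch == ctdiw * s.exposure_mas / 100.0


def test_map_scan_range(phantom_10y):
    head = phantom_10y.landmarks["head"]
    # no positions -> exactly the landmark
    s = make_series(scan_start_mm=None, scan_end_mm=None)
    assert map_scan_range(s, phantom_10y, "head") == head
    # recorded length preserved, centred on the landmark
    chest = phantom_10y.landmarks["chest"]
    length = 1.2 * (chest[1] - chest[0])
    s = make_series(scan_start_mm=0.0, scan_end_mm=length)
    z0, z1 = map_scan_range(s, phantom_10y, "chest")
    assert z1 - z0 == pytest.approx(length)
    assert 0.5 * (z0 + z1) == pytest.approx(0.5 * sum(chest))
    # reversed endpoints give the same interval
    s_rev = make_series(scan_start_mm=length, scan_end_mm=0.0)
    assert map_scan_range(s_rev, phantom_10y, "chest") == (z0, z1)
    # neither region nor positions -> reconstruction error
    with pytest.raises(ReconstructionError):
        map_scan_range(make_series(scan_start_mm=None, scan_end_mm=None),
                       phantom_10y, None)


def test_exact_mas_linearity(phantom_10y, table_10y):
    d1, _ = compute_series_dose(make_series(exposure_mas=100.0), phantom_10y,
                                table_10y, region="head")
    d2, _ = compute_series_dose(make_series(exposure_mas=200.0), phantom_10y,
                                table_10y, region="head")
    for organ in d1:
        assert d2[organ] == 2.0 * d1[organ]  # exact, not approximate


def test_exact_ctdiw_linearity(phantom_10y, table_10y):
    d1, _ = compute_series_dose(make_series(ctdi_w=10.0), phantom_10y,
                                table_10y, region="head")
    d2, _ = compute_series_dose(make_series(ctdi_w=20.0), phantom_10y,
                                table_10y, region="head")
    d3, _ = compute_series_dose(make_series(ctdi_w=30.0), phantom_10y,
                                table_10y, region="head")
    for organ in d1:
        assert d2[organ] == 2.0 * d1[organ]  # power-of-two factor: bitwise
        assert d3[organ] == pytest.approx(3.0 * d1[organ], rel=1e-14)


def test_exact_additivity_over_series(phantom_10y, table_10y):
    a = make_series(series_uid="a", exposure_mas=80.0)
    b = make_series(series_uid="b", exposure_mas=150.0, kvp=100.0)
    da, _ = compute_series_dose(a, phantom_10y, table_10y, region="head")
    db, _ = compute_series_dose(b, phantom_10y, table_10y, region="head")
    exam = make_exam(series=[a, b])
    both = compute_exam_dose(exam, phantom_10y, table_10y)
    for organ in da:
        assert both.organ_dose_mgy[organ] == da[organ] + db[organ]


def test_head_scan_brain_dose_exceeds_abdomen_scan(dose_model):
    """Geometry oracle at equal CTDIvol, on every reference phantom."""
    from ctdosim.phantoms import AGE_CLASSES, build_reference_phantom
    from ctdosim.coefficients import synthetic_coefficient_table
    for age_class in AGE_CLASSES:
        ph = build_reference_phantom(age_class, "female")
        table = synthetic_coefficient_table(ph)
        doses = {}
        for region in ("head", "abdomen"):
            s = make_series(ctdi_w=15.0)  # same recorded CTDIw and pitch
            d, prov = compute_series_dose(s, ph, table, region=region)
            doses[region] = d["brain"]
        assert doses["head"] > doses["abdomen"], age_class


def test_flat_modulation_profile_is_identity(phantom_10y, table_10y):
    base = make_series(exposure_mas=120.0)
    flat = make_series(exposure_mas=None, tube_current_ma=120.0,
                       rotation_time_s=1.0,
                       modulation_profile=[120.0, 120.0, 120.0])
    d0, _ = compute_series_dose(base, phantom_10y, table_10y, region="chest")
    d1, _ = compute_series_dose(flat, phantom_10y, table_10y, region="chest")
    for organ in d0:
        assert d1[organ] == pytest.approx(d0[organ], rel=1e-12)


def test_missing_parameter_raises(phantom_10y, table_10y):
    with pytest.raises(ReconstructionError):
        compute_series_dose(make_series(kvp=None), phantom_10y, table_10y,
                            region="head")


def test_kvp_outside_grid_is_extrapolation_error(phantom_10y, table_10y):
    with pytest.raises(ExtrapolationError):
        compute_series_dose(make_series(kvp=150.0), phantom_10y, table_10y,
                            region="head")


def test_scanner_class_tier(phantom_10y, table_10y):
    s = make_series()
    _, p_rec = compute_series_dose(
        dataclasses.replace(s, ctdi_w=12.0), phantom_10y, table_10y,
        region="head")
    _, p_cls = compute_series_dose(s, phantom_10y, table_10y, region="head",
                                   scanner_class="multi_slice")
    _, p_ref = compute_series_dose(s, phantom_10y, table_10y, region="head")
    assert p_rec["ctdiw_tier"] == "recorded"
    assert p_cls["ctdiw_tier"] == "class_default"
    assert p_ref["ctdiw_tier"] == "table_reference"


def test_out_of_field_bounded_by_scatter_tail(phantom_10y, table_10y):
    """A head scan gives colon (fully out of field) at most the table's
    maximum out-of-region colon coefficient times the delivered mAs-CTDIw."""
    s = make_series(scan_start_mm=None, scan_end_mm=None)
    d, prov = compute_series_dose(s, phantom_10y, table_10y, region="head")
    z0, z1 = prov["z_interval"]
    oi = table_10y.organs.index("colon")
    out_mask = (table_10y.z_grid >= z0) & (table_10y.z_grid <= z1)
    tail_max = table_10y.values[:, out_mask, oi].max()
    ctdiw = table_10y.ctdiw_at(s.kvp, 0.5 * (z0 + z1))
    step = s.collimation_mm * s.pitch
    n_rot = (z1 - z0) / step
    assert d["colon"] <= tail_max * ctdiw * s.exposure_mas / 100.0 * n_rot + 1e-9


def test_accumulate_patient_dose(phantom_10y, table_10y):
    e1 = compute_exam_dose(make_exam(region="head"), phantom_10y, table_10y)
    e2 = compute_exam_dose(make_exam(region="abdomen"), phantom_10y, table_10y)
    total = accumulate_patient_dose([e1, e2])
    perm = accumulate_patient_dose([e2, e1])
    for organ in e1.organ_dose_mgy:
        assert total.organ_dose_mgy[organ] == \
            e1.organ_dose_mgy[organ] + e2.organ_dose_mgy[organ]
        assert perm.organ_dose_mgy[organ] == total.organ_dose_mgy[organ]
    assert total.n_exams == 2
    # identity and empty cases
    one = accumulate_patient_dose([e1])
    assert one.organ_dose_mgy == e1.organ_dose_mgy
    empty = accumulate_patient_dose([])
    assert empty.organ_dose_mgy == {} and empty.n_exams == 0
    # mixed patients rejected
    e3 = compute_exam_dose(make_exam(patient_id="P2"), phantom_10y, table_10y)
    with pytest.raises(ConsistencyError):
        accumulate_patient_dose([e1, e3])


def test_partial_last_rotation_weighted_fractionally(phantom_10y, table_10y):
    """Doubling scan length over a flat coefficient plateau doubles dose."""
    head = phantom_10y.landmarks["head"]
    s1 = make_series(scan_start_mm=0.0, scan_end_mm=37.0)
    s2 = make_series(scan_start_mm=0.0, scan_end_mm=74.0)
    # use a constant-coefficient organ region: remainder spans everything,
    # so compare total delivered rotation weight instead via ctdi: DLP scales
    _, p1 = compute_series_dose(s1, phantom_10y, table_10y, region="head")
    _, p2 = compute_series_dose(s2, phantom_10y, table_10y, region="head")
    assert p2["dlp_mgy_cm"] == pytest.approx(2.0 * p1["dlp_mgy_cm"], rel=1e-12)
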