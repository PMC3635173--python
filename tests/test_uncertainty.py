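import numpy as np
import pytest
from scipy import stats

from conftest import make_exam, make_patient, make_series
from ctdosim.errors import (ElicitationError, ReconstructionError,
                            ValidationError)
from ctdosim.uncertainty import (ParameterPdf, RealizationSet, elicit_pdf,
                                 generate_realizations, sample_parameters,
                                 stable_seed, summarize_realizations)


def rng_of(seed):
    return np.random.Generator(np.random.Philox(key=np.uint64(seed)))


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def test_stable_seed_deterministic_and_bounded():
    a = stable_seed(7, "group:G0", "mas", 3, "")
    assert a == stable_seed(7, "group:G0", "mas", 3, "")
    assert 0 <= a < 2 ** 31
    assert a != stable_seed(7, "group:G0", "mas", 4, "")
    assert a != stable_seed(7, "group:G1", "mas", 3, "")


# ---------------------------------------------------------------------------
# PDF objects and elicitation
# ---------------------------------------------------------------------------

def test_pdf_validation():
    with pytest.raises(ValidationError):
        ParameterPdf("x", "beta")
    with pytest.raises(ValidationError):
        ParameterPdf("x", "point", {"value": 1.0}, scope="site")
    with pytest.raises(ValidationError):
        ParameterPdf("x", "lognormal", {"median": 1.0, "gsd": 0.8})
    with pytest.raises(ValidationError):
        ParameterPdf("x", "uniform", {"lo": 0, "hi": 1}, truncation=(2.0, 1.0))
    with pytest.raises(ValidationError):
        ParameterPdf("x", "discrete_joint", {"rows": [(1,)], "weights": [-1.0]})


def test_pdf_sampling_respects_truncation():
    pdf = ParameterPdf("mas", "lognormal", {"median": 100.0, "gsd": 2.0},
                       truncation=(80.0, 130.0))
    rng = rng_of(1)
    draws = [pdf.sample(rng) for _ in range(500)]
    assert all(80.0 <= x <= 130.0 for x in draws)
    assert len(set(draws)) > 100  # genuinely random, not clipped to a bound


def test_pdf_joint_sample_returns_named_row():
    pdf = ParameterPdf("proto", "discrete_joint",
                       {"rows": [(120.0, 200.0), (100.0, 150.0)]},
                       columns=("kvp", "mas"))
    draw = pdf.sample(rng_of(2))
    assert set(draw) == {"kvp", "mas"}
    assert (draw["kvp"], draw["mas"]) in {(120.0, 200.0), (100.0, 150.0)}


def test_elicit_identical_observations_point_mass():
    pdf = elicit_pdf("mas", [100.0, 100.0, 100.0])
    assert pdf.family == "point"
    assert pdf.params["value"] == pytest.approx(100.0)


def test_elicit_three_spread_observations_lognormal():
    pdf = elicit_pdf("mas", [50.0, 100.0, 200.0])
    assert pdf.family == "lognormal"
    assert pdf.params["median"] == pytest.approx(100.0)  # geometric mean
    assert pdf.params["gsd"] > 1.0


def test_elicit_sparse_observations_triangular():
    pdf = elicit_pdf("mas", [90.0, 110.0])
    assert pdf.family == "triangular" and pdf.tier == "sparse"
    assert pdf.params["mode"] == pytest.approx(100.0)


def test_elicit_no_observations_uses_era_default():
    era = ParameterPdf("mas", "lognormal", {"median": 150.0, "gsd": 1.5},
                       truncation=(40.0, 500.0), tier="era_default")
    pdf = elicit_pdf("mas", [], era_default=era)
    assert pdf.tier == "era_default"
    assert pdf.params == era.params
    with pytest.raises(ElicitationError):
        elicit_pdf("mas", [])
    with pytest.raises(ValidationError):
        elicit_pdf("mas", [0.0, 100.0])


# ---------------------------------------------------------------------------
# sampling contracts
# ---------------------------------------------------------------------------

def _group_pdf(scope="group", **kw):
    return ParameterPdf("mas", "lognormal", {"median": 100.0, "gsd": 1.5},
                        scope=scope, **kw)


def test_recorded_values_pass_through_untouched():
    out = sample_parameters("G0", "P1", {"mas": _group_pdf()}, 0, 7,
                            recorded={"mas": 123.0})
    assert out["mas"] == 123.0


def test_group_scope_shared_within_group_and_realization():
    pdfs = {"mas": _group_pdf()}
    a = sample_parameters("G0", "P1", pdfs, 0, 7)
    b = sample_parameters("G0", "P2", pdfs, 0, 7)
    c = sample_parameters("G1", "P3", pdfs, 0, 7)
    d = sample_parameters("G0", "P1", pdfs, 1, 7)
    assert a["mas"] == b["mas"]       # same group, same realization
    assert a["mas"] != c["mas"]       # other group draws independently
    assert a["mas"] != d["mas"]       # draws vary across realizations


def test_patient_scope_independent_between_patients():
    pdfs = {"mas": _group_pdf(scope="patient")}
    a = sample_parameters("G0", "P1", pdfs, 0, 7)
    b = sample_parameters("G0", "P2", pdfs, 0, 7)
    assert a["mas"] != b["mas"]


def test_patient_tag_perturbs_only_patient_scope():
    pdfs = {"mas": _group_pdf(scope="patient"),
            "kvp": ParameterPdf("kvp", "discrete_joint",
                                {"rows": [(100.0,), (120.0,), (130.0,),
                                          (135.0,), (140.0,)]},
                                columns=("kvp",), scope="group")}
    base = sample_parameters("G0", "P1", pdfs, 0, 7, patient_tag="")
    rep = sample_parameters("G0", "P1", pdfs, 0, 7, patient_tag="rep")
    assert rep["kvp"] == base["kvp"]
    assert rep["mas"] != base["mas"]


def test_linked_parameters_come_from_one_joint_row():
    rows = [(120.0, 200.0), (100.0, 150.0), (140.0, 300.0)]
    pdfs = {
        "kvp": ParameterPdf("kvp", "discrete_joint", {"rows": rows},
                            columns=("kvp", "mas"), linkage_id="proto"),
        "mas": ParameterPdf("mas", "discrete_joint", {"rows": rows},
                            columns=("kvp", "mas"), linkage_id="proto"),
    }
    for iv in range(20):
        out = sample_parameters("G0", "P1", pdfs, iv, 7)
        assert (out["kvp"], out["mas"]) in set(rows)  # never a mixed pair


def test_linkage_row_missing_parameter_rejected():
    pdfs = {"pitch": ParameterPdf("pitch", "discrete_joint",
                                  {"rows": [(120.0,)]}, columns=("kvp",),
                                  linkage_id="proto")}
    with pytest.raises(ReconstructionError):
        sample_parameters("G0", "P1", pdfs, 0, 7)


# ---------------------------------------------------------------------------
# cohort realizations
# ---------------------------------------------------------------------------

def _two_patient_setup(missing="mas"):
    patients, exams = {}, {}
    for pid in ("P1", "P2"):
        patients[pid] = make_patient(pid)
        kw = dict(scan_start_mm=0.0, scan_end_mm=150.0)
        if missing == "mas":
            kw["exposure_mas"] = None
        exams[pid] = [make_exam(patient_id=pid,
                                series=[make_series(**kw)])]
    return patients, exams


def _resolver_for(pdf):
    def resolver(gkey, exam, parameter):
        if parameter == pdf.name:
            return pdf
        return None  # no nCTDIw / modulation priors in this toy study
    return resolver


def test_v1_point_masses_reproduce_deterministic_doses(dose_model):
    patients, exams = _two_patient_setup()
    pdf = ParameterPdf("mas", "point", {"value": 100.0}, scope="group")
    rs = generate_realizations(patients, exams, _resolver_for(pdf), 1, 7,
                               dose_model, lambda p, e: "G0", replicate=False)
    for ip, pid in enumerate(rs.patient_ids):
        # mas recorded at the point value, everything else as generated
        filled = make_exam(patient_id=pid,
                           series=[make_series(scan_start_mm=0.0,
                                               scan_end_mm=150.0)])
        expected = dose_model.exam_dose(patients[pid], filled)
        for io, organ in enumerate(rs.organs):
            assert rs.doses[0, ip, io] == pytest.approx(expected[organ],
                                                        rel=1e-12)


def test_group_scope_draws_give_constant_dose_ratio(dose_model):
    patients, exams = _two_patient_setup()
    rs = generate_realizations(patients, exams, _resolver_for(_group_pdf()),
                               20, 7, dose_model, lambda p, e: "G0",
                               replicate=False)
    io = rs.organ_index("brain")
    ratio = rs.doses[:, 0, io] / rs.doses[:, 1, io]
    assert np.ptp(ratio) == 0.0  # identical shared draw -> exact ratio
    rho = stats.spearmanr(rs.doses[:, 0, io], rs.doses[:, 1, io]).statistic
    assert rho == pytest.approx(1.0)


def test_patient_scope_draws_decorrelate_patients(dose_model):
    patients, exams = _two_patient_setup()
    rs = generate_realizations(patients, exams,
                               _resolver_for(_group_pdf(scope="patient")),
                               30, 7, dose_model, lambda p, e: "G0",
                               replicate=False)
    io = rs.organ_index("brain")
    assert np.ptp(rs.doses[:, 0, io] / rs.doses[:, 1, io]) > 0.0


def test_missing_parameter_without_pdf_raises(dose_model):
    patients, exams = _two_patient_setup()
    def resolver(gkey, exam, parameter):
        return None
    with pytest.raises(ReconstructionError):
        generate_realizations(patients, exams, resolver, 1, 7, dose_model,
                              lambda p, e: "G0")


def test_realizations_invariant_to_insertion_order(dose_model):
    patients, exams = _two_patient_setup()
    rev_patients = dict(reversed(list(patients.items())))
    rev_exams = dict(reversed(list(exams.items())))
    kw = dict(pdf_resolver=_resolver_for(_group_pdf(scope="patient")),
              v=5, master_seed=7, dose_model=dose_model,
              group_of=lambda p, e: "G0", replicate=False)
    a = generate_realizations(patients, exams, **kw)
    b = generate_realizations(rev_patients, rev_exams, **kw)
    assert a.patient_ids == b.patient_ids
    np.testing.assert_array_equal(a.doses, b.doses)


def test_fully_recorded_series_yield_identical_realizations(dose_model):
    patients = {"P1": make_patient()}
    exams = {"P1": [make_exam(series=[make_series(scan_start_mm=0.0,
                                                  scan_end_mm=150.0)])]}
    rs = generate_realizations(patients, exams, _resolver_for(_group_pdf()),
                               5, 7, dose_model, lambda p, e: "G0",
                               replicate=False)
    assert np.ptp(rs.doses, axis=0).max() == 0.0


# ---------------------------------------------------------------------------
# summaries and the shared/unshared decomposition
# ---------------------------------------------------------------------------

def test_summary_requires_v_ge_2():
    rs = RealizationSet(["P1"], ("brain",), np.ones((1, 1, 1)), 0)
    with pytest.raises(ValidationError):
        summarize_realizations(rs)


def test_summary_decomposition_on_constructed_set():
    """D = S * U with shared S and patient-scope U; D' reuses S with a
    fresh U'. The unshared estimate E[(D-D')^2]/2 must converge to the
    conditional variance E[S^2] Var(U), and shared+unshared==total."""
    rng = rng_of(9)
    v = 20_000
    s = rng.lognormal(0.0, 0.3, size=v)
    u = rng.normal(10.0, 1.0, size=v)
    u2 = rng.normal(10.0, 1.0, size=v)
    d = (s * u).reshape(v, 1, 1)
    d2 = (s * u2).reshape(v, 1, 1)
    rs = RealizationSet(["P1"], ("brain",), d, 0, doses_replicate=d2)
    out = summarize_realizations(rs).iloc[0]
    expected_unshared = np.mean(s ** 2) * 1.0  # Var(U) = 1
    assert out["var_unshared"] == pytest.approx(expected_unshared, rel=0.05)
    assert out["var_shared"] + out["var_unshared"] == \
        pytest.approx(out["var_total"], abs=1e-12)
    assert out["var_total"] == pytest.approx(d[:, 0, 0].var(), rel=1e-12)


def test_summary_shared_only_has_zero_unshared(dose_model):
    patients, exams = _two_patient_setup()
    rs = generate_realizations(patients, exams, _resolver_for(_group_pdf()),
                               40, 7, dose_model, lambda p, e: "G0")
    out = summarize_realizations(rs)
    brain = out[out.organ == "brain"]
    assert (brain["var_unshared"] == 0.0).all()  # replicate reuses shared draw
    assert (brain["var_shared"] > 0.0).all()


def test_summary_point_pdf_zero_variance(dose_model):
    patients, exams = _two_patient_setup()
    pdf = ParameterPdf("mas", "point", {"value": 100.0}, scope="group")
    rs = generate_realizations(patients, exams, _resolver_for(pdf), 5, 7,
                               dose_model, lambda p, e: "G0")
    out = summarize_realizations(rs)
    assert (out["var_total"] == 0.0).all()
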