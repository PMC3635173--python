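"""Missing-parameter uncertainty as correlated cohort dose realizations.

Every technical parameter that is absent from a patient's records is
represented by a probability density function with a *sharing scope*:
``group`` parameters (e.g. the mAs a hospital's protocol used in a
period) are drawn once per (group, realization) and shared by all the
group's patients, ``patient`` parameters independently per patient, and
``cohort`` parameters once per realization for everyone. Parameters
elicited jointly (a protocol row chooses kVp, mAs, pitch and scan length
together) share a linkage id and are drawn as one row of a discrete joint
table, never as independent marginals.

A realization of the cohort is one internally consistent alternative set
of doses for every patient: within a realization, patients sharing a
group see the same shared draws (their dose-model errors are correlated,
which single imputation would destroy); across realizations the shared
draws vary, carrying the uncertainty. Recorded values always pass
through untouched.

Seeds: master seed -> per-draw seed by stable hashing of
(scope key | parameter-or-linkage | realization), so results are
reproducible and independent of patient insertion order.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import compute_exam_dose
from .errors import (ElicitationError, ReconstructionError, ValidationError)

__all__ = ["ParameterPdf", "RealizationSet", "elicit_pdf", "sample_parameters",
           "generate_realizations", "summarize_realizations", "CohortDoseModel",
           "stable_seed"]

PDF_FAMILIES = ("point", "uniform", "triangular", "lognormal", "discrete_joint")
SCOPES = ("cohort", "group", "patient")
#: parameters the sampler knows how to feed into the dose engine
SAMPLEABLE = ("kvp", "mas", "pitch", "scan_length_mm", "modulation_factor",
              "nctdiw_factor", "stature_deviation")


def stable_seed(*parts) -> int:
    """Order-stable 31-bit seed from arbitrary string-able parts."""
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "little") >> 1


@dataclass(frozen=True)
class ParameterPdf:
    """Distribution of one missing parameter (or a joint parameter row)."""

    name: str  # parameter name, or linkage id for discrete_joint
    family: str
    params: dict = field(default_factory=dict)
    truncation: tuple[float, float] | None = None
    scope: str = "group"
    linkage_id: str | None = None
    columns: tuple[str, ...] | None = None  # for discrete_joint rows
    tier: str = "elicited"  # elicited | sparse | era_default

    def __post_init__(self):
        if self.family not in PDF_FAMILIES:
            raise ValidationError(f"unknown PDF family {self.family!r}")
        if self.scope not in SCOPES:
            raise ValidationError(f"unknown sharing scope {self.scope!r}")
        if self.truncation is not None and not self.truncation[0] <= self.truncation[1]:
            raise ValidationError("truncation bounds must be ordered")
        if self.family == "lognormal" and self.params.get("gsd", 1.0) < 1.0:
            raise ValidationError("lognormal GSD must be >= 1")
        if self.family == "discrete_joint":
            w = np.asarray(self.params.get("weights",
                                           [1.0] * len(self.params["rows"])), float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValidationError("joint-row weights must be non-negative")

    def sample(self, rng: np.random.Generator):
        """One draw; a scalar, or a dict of column values for joint rows."""
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "discrete_joint":
            w = np.asarray(p.get("weights", [1.0] * len(p["rows"])), float)
            i = rng.choice(len(p["rows"]), p=w / w.sum())
            row = p["rows"][i]
            cols = self.columns or tuple(f"c{j}" for j in range(len(row)))
            return dict(zip(cols, row))
        for _ in range(10_000):
            if self.family == "uniform":
                x = rng.uniform(p["lo"], p["hi"])
            elif self.family == "triangular":
                x = rng.triangular(p["lo"], p["mode"], p["hi"])
            else:  # lognormal
                x = p["median"] * math.exp(math.log(p["gsd"]) * rng.standard_normal())
            if self.truncation is None or self.truncation[0] <= x <= self.truncation[1]:
                return float(x)
        raise ValidationError(f"{self.name}: truncation bounds reject all draws")


def elicit_pdf(parameter: str, observations, *, scope: str = "group",
               era_default: ParameterPdf | None = None) -> ParameterPdf:
    """Derive a parameter PDF from protocol observations of similar groups.

    Three or more observations give a lognormal through the geometric
    median and geometric SD (collapsing to a point mass when all agree),
    truncated to the era range when one is registered; one or two give a
    triangular with mode at their mean and era-default bounds; none fall
    back to the era default at the lowest confidence tier.
    """
    obs = [float(v) for v in observations]
    if any(v <= 0 for v in obs):
        raise ValidationError("observations must be positive")
    if not obs:
        if era_default is None:
            raise ElicitationError(f"{parameter}: no observations and no era default")
        return ParameterPdf(parameter, era_default.family, era_default.params,
                            era_default.truncation, scope,
                            columns=era_default.columns, tier="era_default")
    if len(obs) >= 3:
        logs = np.log(obs)
        gsd = float(np.exp(logs.std(ddof=0)))
        median = float(np.exp(logs.mean()))
        if gsd <= 1.0 + 1e-12:
            return ParameterPdf(parameter, "point", {"value": median}, scope=scope)
        trunc = era_default.truncation if era_default is not None else \
            (min(obs), max(obs))
        return ParameterPdf(parameter, "lognormal", {"median": median, "gsd": gsd},
                            trunc, scope)
    mode = float(np.mean(obs))
    if era_default is not None and era_default.truncation is not None:
        lo, hi = era_default.truncation
    else:
        lo, hi = 0.5 * mode, 1.5 * mode
    lo, hi = min(lo, mode), max(hi, mode)
    return ParameterPdf(parameter, "triangular", {"lo": lo, "mode": mode, "hi": hi},
                        scope=scope, tier="sparse")


def _scope_key(pdf: ParameterPdf, group_key, patient_id) -> str:
    if pdf.scope == "cohort":
        return "cohort"
    if pdf.scope == "group":
        return f"group:{group_key}"
    return f"patient:{patient_id}"


def sample_parameters(group_key, patient_id, pdfs: dict[str, ParameterPdf],
                      realization: int, master_seed: int,
                      recorded: dict | None = None,
                      patient_tag: str = "") -> dict:
    """Sample one realization's parameter values for one patient/exam.

    ``pdfs`` maps parameter name -> PDF; parameters sharing a linkage id
    are drawn once as a joint row. ``recorded`` values pass through
    untouched and suppress sampling. ``patient_tag`` perturbs only
    patient-scope draws (used for the paired replicate that feeds the
    shared/unshared variance decomposition).
    """
    recorded = dict(recorded or {})
    out = dict(recorded)
    drawn_linkages: dict[str, dict] = {}
    for name, pdf in sorted(pdfs.items()):
        if name in recorded:
            continue
        unit = pdf.linkage_id or name
        skey = _scope_key(pdf, group_key, patient_id)
        tag = patient_tag if pdf.scope == "patient" else ""
        if unit in drawn_linkages:
            joint = drawn_linkages[unit]
            if name not in joint:
                raise ReconstructionError(
                    f"linkage {unit!r} draw lacks parameter {name!r}")
            out[name] = joint[name]
            continue
        rng = np.random.Generator(np.random.Philox(
            key=np.uint64(stable_seed(master_seed, skey, unit, realization, tag))))
        value = pdf.sample(rng)
        if isinstance(value, dict):
            drawn_linkages[unit] = value
            if name not in value:
                raise ReconstructionError(
                    f"joint draw for {unit!r} lacks parameter {name!r}")
            out[name] = value[name]
        else:
            out[name] = value
    return out


class CohortDoseModel:
    """Binds phantoms, coefficient tables and the dose engine for a cohort.

    ``tables`` maps (age_class, sex) -> CoefficientTable; exams are routed
    to the phantom selected from the patient's age (and stature when
    recorded) at the exam date.
    """

    def __init__(self, tables: dict, organs=("red_bone_marrow", "brain", "colon"),
                 scanner_class: str | None = None):
        self.tables = tables
        self.organs = tuple(organs)
        self.scanner_class = scanner_class

    def table_for(self, patient, exam):
        from .phantoms import build_reference_phantom, select_phantom
        age = patient.age_at(exam.exam_date) if exam.exam_date else None
        age_class = select_phantom(age if age is not None else 10.0, patient.sex,
                                   height=patient.height_cm, weight=patient.weight_kg)
        key = (age_class, patient.sex)
        if key not in self.tables:
            raise ReconstructionError(f"no coefficient table for {key}")
        return build_reference_phantom(age_class, patient.sex), self.tables[key]

    def exam_dose(self, patient, exam) -> dict[str, float]:
        phantom, table = self.table_for(patient, exam)
        res = compute_exam_dose(exam, phantom, table,
                                scanner_class=self.scanner_class)
        return {o: res.organ_dose_mgy[o] for o in self.organs}


@dataclass
class RealizationSet:
    """V alternative, internally consistent cohort dose sets (mGy)."""

    patient_ids: list[str]
    organs: tuple[str, ...]
    doses: np.ndarray  # (V, n_patients, n_organs)
    master_seed: int
    group_map: dict[str, str] = field(default_factory=dict)
    registry_version: str = ""
    doses_replicate: np.ndarray | None = None  # fresh patient-scope draws

    def __post_init__(self):
        if np.any(self.doses < 0):
            raise ValidationError("doses must be non-negative")
        v, n, o = self.doses.shape
        if n != len(self.patient_ids) or o != len(self.organs):
            raise ValidationError("dose array shape inconsistent with cohort")

    @property
    def v(self) -> int:
        return self.doses.shape[0]

    def organ_index(self, organ: str) -> int:
        return self.organs.index(organ)

    def mean_dose(self, organ: str) -> np.ndarray:
        return self.doses[:, :, self.organ_index(organ)].mean(axis=0)


def _fill_series(series, sampled: dict):
    kw = {}
    if series.kvp is None and "kvp" in sampled:
        kw["kvp"] = sampled["kvp"]
    if series.mas()[0] is None and "mas" in sampled:
        kw["exposure_mas"] = sampled["mas"]
    if series.pitch is None and "pitch" in sampled:
        kw["pitch"] = sampled["pitch"]
    if series.collimation_mm is None:
        kw["collimation_mm"] = sampled.get("collimation_mm", 10.0)
    if (series.scan_start_mm is None or series.scan_end_mm is None) \
            and "scan_length_mm" in sampled:
        kw["scan_start_mm"] = 0.0
        kw["scan_end_mm"] = float(sampled["scan_length_mm"])
    return series.with_values(**kw) if kw else series


def _recorded_values(series) -> dict:
    rec = {}
    if series.kvp is not None:
        rec["kvp"] = series.kvp
    mas, _, _ = series.mas()
    if mas is not None:
        rec["mas"] = mas
    if series.pitch is not None:
        rec["pitch"] = series.pitch
    if series.scan_start_mm is not None and series.scan_end_mm is not None:
        rec["scan_length_mm"] = abs(series.scan_end_mm - series.scan_start_mm)
    return rec


def generate_realizations(patients: dict, exams_by_patient: dict,
                          pdf_resolver, v: int, master_seed: int,
                          dose_model: CohortDoseModel, group_of,
                          *, replicate: bool = True) -> RealizationSet:
    """Draw V correlated cohort dose realizations.

    ``pdf_resolver(group_key, exam, parameter_name) -> ParameterPdf`` maps
    each missing parameter to its registered PDF (raising
    :class:`ReconstructionError` when none exists); ``group_of(patient,
    exam) -> key`` supplies the sharing group. With ``replicate=True`` a
    second dose array with identical group-scope draws but fresh
    patient-scope draws is stored for the shared/unshared variance
    decomposition.
    """
    if v < 1:
        raise ValidationError("V must be >= 1")
    pids = sorted(patients)
    organs = dose_model.organs
    tags = ("",) + (("rep",) if replicate else ())
    arrays = {t: np.zeros((v, len(pids), len(organs))) for t in tags}
    group_map = {}
    for ip, pid in enumerate(pids):
        patient = patients[pid]
        for exam in exams_by_patient.get(pid, []):
            gkey = group_of(patient, exam)
            group_map[pid] = str(gkey)
            for series in exam.series:
                recorded = _recorded_values(series)
                missing = [p for p in ("kvp", "mas", "pitch", "scan_length_mm")
                           if p not in recorded]
                # a recorded mAs already reflects any tube-current
                # modulation; the dose-reducing modulation factor applies
                # only when mAs is imputed from a nominal protocol value
                extras = ["nctdiw_factor"]
                if "mas" in missing:
                    extras.append("modulation_factor")
                pdfs = {}
                for p in missing + extras:
                    pdf = pdf_resolver(gkey, exam, p)
                    if pdf is None:
                        if p in ("modulation_factor", "nctdiw_factor"):
                            continue
                        raise ReconstructionError(
                            f"no PDF registered for missing parameter {p!r} "
                            f"(patient {pid})")
                    pdfs[p] = pdf
                for iv in range(v):
                    for tag in tags:
                        try:
                            sampled = sample_parameters(
                                gkey, pid, pdfs, iv, master_seed,
                                recorded=recorded, patient_tag=tag)
                            filled = _fill_series(series, sampled)
                            one = ExamShim(exam, [filled])
                            dose = dose_model.exam_dose(patient, one)
                        except ReconstructionError as exc:
                            raise ReconstructionError(
                                f"realization {iv}, patient {pid}: {exc}") from exc
                        factor = (sampled.get("modulation_factor", 1.0)
                                  * sampled.get("nctdiw_factor", 1.0))
                        for io, organ in enumerate(organs):
                            arrays[tag][iv, ip, io] += dose[organ] * factor
    return RealizationSet(
        patient_ids=pids, organs=organs, doses=arrays[""],
        master_seed=master_seed, group_map=group_map,
        doses_replicate=arrays.get("rep"))


class ExamShim:
    """One-series view of an exam (keeps per-series sampling independent)."""

    def __init__(self, exam, series):
        self._exam = exam
        self.series = series
        self.patient_id = exam.patient_id
        self.exam_date = exam.exam_date

    def region(self):
        return self._exam.region()


def summarize_realizations(rs: RealizationSet) -> pd.DataFrame:
    """Per-patient, per-organ summary across realizations.

    Columns: mean, median, p2.5, p97.5, variance and its shared/unshared
    split. The unshared (within-group, patient-scope) component is
    estimated from the paired replicate as E[(D - D')^2]/2 — the Monte
    Carlo form of the conditional variance given the group-level draws —
    and the shared component is the complement, so the two sum to the
    total exactly.
    """
    if rs.v < 2:
        raise ValidationError("dispersion summaries require V >= 2")
    d = rs.doses
    rows = []
    for io, organ in enumerate(rs.organs):
        x = d[:, :, io]
        var_total = x.var(axis=0)
        if rs.doses_replicate is not None:
            xr = rs.doses_replicate[:, :, io]
            var_unshared = 0.5 * np.mean((x - xr) ** 2, axis=0)
            var_unshared = np.minimum(var_unshared, var_total)
        else:
            var_unshared = np.full(x.shape[1], np.nan)
        for ip, pid in enumerate(rs.patient_ids):
            rows.append({
                "patient_id": pid, "organ": organ,
                "mean": x[:, ip].mean(), "median": np.median(x[:, ip]),
                "p2.5": np.percentile(x[:, ip], 2.5),
                "p97.5": np.percentile(x[:, ip], 97.5),
                "var_total": var_total[ip],
                "var_unshared": var_unshared[ip],
                "var_shared": var_total[ip] - var_unshared[ip],
            })
    return pd.DataFrame(rows)
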