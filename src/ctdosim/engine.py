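"""Deterministic organ-dose computation.

Per series: the recorded (or protocol/PDF-filled) technical parameters are
turned into a train of axial rotations stepped by collimation x pitch
across the scan range mapped into the phantom frame; each rotation
contributes coefficient(organ, z, kVp) x CTDIw-per-rotation, so the result
is exactly linear in mAs and in CTDIw and exactly additive over series.
Helical scans are approximated by this contiguous-rotation train, with the
partial last rotation weighted by its fractional coverage.

CTDIw per rotation comes from the first available tier:
recorded CTDIw -> scanner-class n_CTDIw lookup -> the coefficient table's
own simulated reference CTDIw. The tier used is recorded in provenance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .coefficients import CoefficientTable
from .errors import ConsistencyError, ReconstructionError, ValidationError
from .phantoms import StylizedPhantom, locate_region
from .records import SeriesRecord

__all__ = ["ctdi_vol", "dlp", "map_scan_range", "compute_series_dose",
           "compute_exam_dose", "accumulate_patient_dose", "OrganDoseResult",
           "load_nctdiw_registry"]


def ctdi_vol(ctdi_w: float, pitch: float) -> float:
    """Volume CT dose index: CTDIw / pitch, mGy."""
    if pitch <= 0:
        raise ValidationError("pitch must be positive")
    return ctdi_w / pitch


def dlp(ctdi_vol_mgy: float, scan_length_mm: float) -> float:
    """Dose-length product, mGy*cm."""
    if scan_length_mm < 0:
        raise ValidationError("scan length must be non-negative")
    return ctdi_vol_mgy * scan_length_mm / 10.0


@lru_cache(maxsize=1)
def load_nctdiw_registry() -> dict:
    text = resources.files("ctdosim.data").joinpath("nctdiw.yaml").read_text()
    return yaml.safe_load(text)


def _nctdiw(kvp: float, scanner_class: str, kind: str) -> float:
    reg = load_nctdiw_registry()
    if scanner_class not in reg or scanner_class == "version":
        raise ReconstructionError(f"unknown scanner class {scanner_class!r}")
    table = reg[scanner_class][kind]
    kvps = np.array(sorted(table))
    if not kvps[0] <= kvp <= kvps[-1]:
        raise ReconstructionError(f"kVp {kvp} outside n_CTDIw registry range")
    vals = np.array([table[int(k)] for k in kvps])
    return float(np.exp(np.interp(np.log(kvp), np.log(kvps), np.log(vals))))


def map_scan_range(series: SeriesRecord, phantom: StylizedPhantom,
                   region: str | None) -> tuple[float, float]:
    """Map the recorded scan interval into the phantom frame, mm.

    With no recorded positions the scan covers the region landmark
    exactly; with recorded positions the recorded length is preserved,
    centred on the landmark (the phantom has no per-patient localizer, so
    the landmark centre is the anchor). Output is orientation-normalized
    (z0 < z1).
    """
    has_pos = series.scan_start_mm is not None and series.scan_end_mm is not None
    if region is None:
        raise ReconstructionError(
            "cannot map scan range: body region unknown"
            + ("" if has_pos else " and no recorded positions"))
    lz0, lz1 = locate_region(phantom, region)
    if not has_pos:
        return lz0, lz1
    length = abs(series.scan_end_mm - series.scan_start_mm)
    mid = (lz0 + lz1) / 2
    return mid - length / 2, mid + length / 2


@dataclass
class OrganDoseResult:
    """Per-organ doses with provenance, for an exam or a patient total."""

    patient_id: str
    organ_dose_mgy: dict[str, float]
    series_components: list[dict[str, float]] = field(default_factory=list)
    ctdi_vol_mgy: float | None = None
    dlp_mgy_cm: float | None = None
    provenance: dict = field(default_factory=dict)
    n_exams: int = 1

    def total(self, organ: str) -> float:
        return self.organ_dose_mgy[organ]


def _rotation_train(z0: float, z1: float, step_mm: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rotation centre positions and fractional weights covering [z0, z1]."""
    length = z1 - z0
    n_full = int(np.floor(length / step_mm + 1e-12))
    centers = z0 + step_mm * (np.arange(n_full) + 0.5)
    weights = np.ones(n_full)
    rem = length - n_full * step_mm
    if rem > 1e-9:
        centers = np.append(centers, z0 + n_full * step_mm + rem / 2)
        weights = np.append(weights, rem / step_mm)
    return centers, weights


def compute_series_dose(series: SeriesRecord, phantom: StylizedPhantom,
                        table: CoefficientTable, *, region: str | None = None,
                        scanner_class: str | None = None
                        ) -> tuple[dict[str, float], dict]:
    """Organ doses (mGy) for one series, plus provenance.

    Requires kVp, per-rotation mAs (or a modulation profile), pitch,
    collimation and a mappable scan range; anything absent is a
    reconstruction error — filling absent values is the caller's job
    (protocol lookup or PDF sampling), never the engine's.
    """
    missing = series.missing_fields()
    if missing and not (missing == ["scan_length_mm"] and region is not None):
        raise ReconstructionError(f"missing parameters: {missing}")
    z0, z1 = map_scan_range(series, phantom, region)
    step = series.collimation_mm * series.pitch
    centers, weights = _rotation_train(z0, z1, step)
    mas, _source, _flag = series.mas()
    if series.modulation_profile is not None:
        prof = np.asarray(series.modulation_profile, float)
        if series.rotation_time_s is None:
            raise ReconstructionError("modulation profile requires rotation time")
        x_old = np.linspace(0, 1, len(prof)) if len(prof) > 1 else np.array([0.5])
        x_new = np.linspace(0, 1, len(centers)) if len(centers) > 1 else np.array([0.5])
        mas_rot = np.interp(x_new, x_old, prof) * series.rotation_time_s
    else:
        mas_rot = np.full(len(centers), mas)

    if series.ctdi_w is not None:
        ctdiw_100 = series.ctdi_w
        tier = "recorded"
    elif scanner_class is not None:
        kind = "head" if region == "head" else "body"
        ctdiw_100 = _nctdiw(series.kvp, scanner_class, kind) * 100.0
        tier = "class_default"
    else:
        ctdiw_100 = table.ctdiw_at(series.kvp, (z0 + z1) / 2)
        tier = "table_reference"

    doses = {}
    for organ in table.organs:
        coeff = np.atleast_1d(table.coefficient(organ, centers, series.kvp))
        doses[organ] = float(np.sum(weights * coeff * ctdiw_100 * mas_rot / 100.0))
    mean_mas = float(np.sum(weights * mas_rot) / weights.sum())
    cvol = ctdi_vol(ctdiw_100 * mean_mas / 100.0, series.pitch)
    prov = {"ctdiw_tier": tier, "table": f"{table.age_class}/{table.sex}",
            "table_kind": table.kind, "z_interval": (z0, z1),
            "ctdi_vol_mgy": cvol, "dlp_mgy_cm": dlp(cvol, z1 - z0)}
    return doses, prov


def compute_exam_dose(exam, phantom: StylizedPhantom, table: CoefficientTable,
                      *, scanner_class: str | None = None) -> OrganDoseResult:
    """Sum of series doses for one examination."""
    organ_dose = {o: 0.0 for o in table.organs}
    components, provs = [], []
    for s in exam.series:
        d, p = compute_series_dose(s, phantom, table, region=exam.region(),
                                   scanner_class=scanner_class)
        components.append(d)
        provs.append(p)
        for o, v in d.items():
            organ_dose[o] += v
    return OrganDoseResult(
        patient_id=exam.patient_id, organ_dose_mgy=organ_dose,
        series_components=components,
        ctdi_vol_mgy=sum(p["ctdi_vol_mgy"] for p in provs) if provs else None,
        dlp_mgy_cm=sum(p["dlp_mgy_cm"] for p in provs) if provs else None,
        provenance={"series": provs})


def accumulate_patient_dose(results: list[OrganDoseResult]) -> OrganDoseResult:
    """Cumulative organ doses over a patient's examinations."""
    if not results:
        return OrganDoseResult(patient_id="", organ_dose_mgy={}, n_exams=0)
    pid = results[0].patient_id
    if any(r.patient_id != pid for r in results):
        raise ConsistencyError("cannot accumulate doses across patients")
    organs = set()
    for r in results:
        organs.update(r.organ_dose_mgy)
    total = {o: sum(r.organ_dose_mgy.get(o, 0.0) for r in results) for o in organs}
    return OrganDoseResult(patient_id=pid, organ_dose_mgy=total,
                           n_exams=len(results),
                           provenance={"n_exams": len(results)})
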