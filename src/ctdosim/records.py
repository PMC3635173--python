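"""Patient, series, examination and protocol record types.

Optional fields use ``None`` for "not recorded": extraction and masking
never substitute defaults, so absence is always distinguishable from a
value. The dose engine and the uncertainty sampler decide how absent
fields are filled (protocol lookup or PDF draw), and record which.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

from .errors import ValidationError

__all__ = ["PatientRecord", "SeriesRecord", "ExaminationRecord",
           "ProtocolEntry", "SliceFeatures"]


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    birth_date: dt.date | None = None
    hospital_id: str | None = None
    height_cm: float | None = None
    weight_kg: float | None = None

    def age_at(self, date: dt.date) -> float | None:
        if self.birth_date is None:
            return None
        age = (date - self.birth_date).days / 365.25
        if age < 0:
            raise ValidationError(f"{self.patient_id}: exam predates birth")
        return age


@dataclass
class SeriesRecord:
    """Technical parameters of one CT series (one scan)."""

    series_uid: str | None = None
    manufacturer: str | None = None
    model: str | None = None
    kvp: float | None = None
    tube_current_ma: float | None = None
    rotation_time_s: float | None = None
    exposure_mas: float | None = None  # per-rotation tube current-time product
    pitch: float | None = None
    collimation_mm: float | None = None
    scan_start_mm: float | None = None
    scan_end_mm: float | None = None
    ctdi_w: float | None = None  # reported, mGy per 100 mAs
    ctdi_vol: float | None = None  # reported, mGy
    modulation_profile: list[float] | None = None  # per-rotation mA

    def __post_init__(self):
        if self.kvp is not None and self.kvp <= 0:
            raise ValidationError("kVp must be positive when present")
        if self.pitch is not None and self.pitch <= 0:
            raise ValidationError("pitch must be positive when present")
        if (self.scan_start_mm is not None and self.scan_end_mm is not None
                and self.scan_start_mm == self.scan_end_mm):
            raise ValidationError("scan start and end must differ")

    def mas(self) -> tuple[float | None, str, bool]:
        """Per-rotation mAs: (value, source, discrepancy_flag).

        The recorded exposure attribute takes precedence over
        current x rotation time; a >10% disagreement between the two
        raises the flag.
        """
        prod = (self.tube_current_ma * self.rotation_time_s
                if self.tube_current_ma is not None and self.rotation_time_s is not None
                else None)
        if self.exposure_mas is not None:
            flag = (prod is not None and prod > 0
                    and abs(self.exposure_mas - prod) / prod > 0.10)
            return self.exposure_mas, "exposure", flag
        if prod is not None:
            return prod, "current_x_time", False
        return None, "absent", False

    def missing_fields(self) -> list[str]:
        out = []
        if self.kvp is None:
            out.append("kvp")
        if self.mas()[0] is None:
            out.append("mas")
        if self.pitch is None:
            out.append("pitch")
        if self.collimation_mm is None:
            out.append("collimation_mm")
        if self.scan_start_mm is None or self.scan_end_mm is None:
            out.append("scan_length_mm")
        return out

    def with_values(self, **kw) -> "SeriesRecord":
        return replace(self, **kw)


@dataclass
class ExaminationRecord:
    patient_id: str
    exam_date: dt.date | None = None
    exam_type: str | None = None  # e.g. "head CT"
    body_region: str | None = None  # head | chest | abdomen
    series: list[SeriesRecord] = field(default_factory=list)
    scenario: str | None = None  # pre_pacs | post_pacs
    n_scans: int | None = None

    def __post_init__(self):
        if self.series and self.n_scans is not None and self.n_scans != len(self.series):
            raise ValidationError("n_scans must equal the number of series present")
        if self.series and self.n_scans is None:
            self.n_scans = len(self.series)

    def region(self) -> str | None:
        """Body region, falling back to the examination-type text."""
        if self.body_region is not None:
            return self.body_region
        if self.exam_type is not None:
            low = self.exam_type.lower()
            for region in ("head", "chest", "abdomen"):
                if region in low:
                    return region
        return None


@dataclass
class ProtocolEntry:
    """One questionnaire row: the joint technical-parameter table used at a
    hospital for a scanner/period/exam-type/age-group combination."""

    hospital_id: str
    period: tuple[dt.date, dt.date]
    scanner_model: str | None
    exam_type: str
    age_group: str
    rows: list[tuple]  # (kvp, mas, pitch, scan_length_mm)
    weights: list[float] | None = None
    completeness: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if not self.period[0] < self.period[1]:
            raise ValidationError("protocol period must have from < to")
        if self.weights is not None:
            if len(self.weights) != len(self.rows) or any(w < 0 for w in self.weights):
                raise ValidationError("weights must be non-negative, one per row")

    def normalized_weights(self) -> list[float]:
        w = self.weights if self.weights is not None else [1.0] * len(self.rows)
        total = sum(w)
        return [wi / total for wi in w]


@dataclass
class SliceFeatures:
    """Segmentation features of one axial slice."""

    body_area_mm2: float
    bone_fraction: float
    air_fraction: float

    def __post_init__(self):
        for v in (self.bone_fraction, self.air_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValidationError("feature fractions must lie in [0, 1]")
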