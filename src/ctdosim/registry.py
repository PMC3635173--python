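"""Era-default PDF registry.

Maps (calendar era, body region, parameter) to a prior distribution used
when a missing parameter has no protocol observations at all — the lowest
confidence tier. The registry ships as an editable YAML data file; each
entry carries a free-text provenance note. Later eras are checked to be
no wider than earlier eras for the same parameter (documentation improves
over time, so uncertainty must not grow).
"""
from __future__ import annotations

import datetime as dt
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError
from .uncertainty import ParameterPdf

__all__ = ["EraRegistry", "load_era_registry", "DEFAULT_SCOPES",
           "make_pdf_resolver", "PROTOCOL_PARAMETERS"]

#: default sharing scope per parameter: protocol-driven settings are shared
#: by the hospital group; anatomy- and scan-specific ones vary per patient
DEFAULT_SCOPES = {
    "kvp": "group", "mas": "group", "pitch": "group",
    "scan_length_mm": "patient", "modulation_factor": "patient",
    "nctdiw_factor": "group", "stature_deviation": "patient",
}


def _entry_to_pdf(name: str, entry: dict, scope: str) -> ParameterPdf:
    fam = entry["family"]
    if fam == "point":
        return ParameterPdf(name, "point", {"value": entry["value"]}, scope=scope,
                            tier="era_default")
    if fam == "triangular":
        return ParameterPdf(name, "triangular",
                            {"lo": entry["lo"], "mode": entry["mode"], "hi": entry["hi"]},
                            truncation=(entry["lo"], entry["hi"]), scope=scope,
                            tier="era_default")
    if fam == "lognormal":
        return ParameterPdf(name, "lognormal",
                            {"median": entry["median"], "gsd": entry["gsd"]},
                            truncation=(entry["lo"], entry["hi"]), scope=scope,
                            tier="era_default")
    if fam == "discrete_joint":
        return ParameterPdf(name, "discrete_joint",
                            {"rows": [tuple(r) for r in entry["rows"]],
                             "weights": entry.get("weights")},
                            columns=tuple(entry["columns"]), scope=scope,
                            tier="era_default")
    raise ConfigurationError(f"unknown PDF family {fam!r} in era registry")


def _width(pdf: ParameterPdf) -> float:
    """Crude dispersion measure used for the narrowing-over-time check."""
    p = pdf.params
    if pdf.family == "point":
        return 0.0
    if pdf.family == "triangular":
        return p["hi"] - p["lo"]
    if pdf.family == "lognormal":
        return float(np.log(p["gsd"]))
    if pdf.family == "discrete_joint":
        vals = [r[0] for r in p["rows"]]
        return float(max(vals) - min(vals)) if len(vals) > 1 else 0.0
    return np.inf


class EraRegistry:
    def __init__(self, spec: dict):
        self.eras = spec["eras"]
        self.version = str(spec.get("version", "0"))
        self._check_narrowing()

    def _check_narrowing(self):
        for earlier, later in zip(self.eras, self.eras[1:]):
            for param, regions in later["parameters"].items():
                if param == "modulation_factor":
                    # tube-current modulation only exists in the later era;
                    # the narrowing-over-time rule applies to parameters
                    # whose documentation improves, not to new technology
                    continue
                for region, entry in regions.items():
                    prev = earlier["parameters"].get(param, {}).get(region)
                    if prev is None:
                        continue
                    w_new = _width(_entry_to_pdf(param, entry, "group"))
                    w_old = _width(_entry_to_pdf(param, prev, "group"))
                    if w_new > w_old + 1e-12:
                        raise ConfigurationError(
                            f"era {later['name']}: PDF for {param}/{region} is "
                            f"wider than in {earlier['name']}")

    def era_of(self, date: dt.date) -> dict:
        for era in self.eras:
            until = era.get("until")
            if until is not None and date < dt.date.fromisoformat(str(until)):
                return era
            frm = era.get("from")
            if frm is not None and date >= dt.date.fromisoformat(str(frm)):
                return era
        return self.eras[-1]

    def pdf(self, date: dt.date, region: str, parameter: str,
            scope: str | None = None) -> ParameterPdf | None:
        era = self.era_of(date)
        entry = era["parameters"].get(parameter, {}).get(region)
        if entry is None:
            return None
        return _entry_to_pdf(parameter, entry,
                             scope or DEFAULT_SCOPES.get(parameter, "group"))


#: the four technical parameters a protocol row elicits jointly
PROTOCOL_PARAMETERS = ("kvp", "mas", "pitch", "scan_length_mm")


def make_pdf_resolver(protocol_table, registry: "EraRegistry"):
    """Build the tiered ``pdf_resolver`` used for dose realizations.

    For a missing technical parameter, the matched group's protocol rows
    (if any) give a discrete joint PDF over complete rows — the four
    protocol parameters share one linkage id, so a realization draws one
    internally consistent row, never independent marginals. Groups with
    no protocol entry fall back to the era-default registry at the lowest
    confidence tier. Returns ``None`` for parameters with no prior at
    either tier.
    """
    from .intake import lookup_protocol

    def resolver(group_key, exam, parameter):
        if parameter in PROTOCOL_PARAMETERS and getattr(group_key, "matched", False):
            rows = lookup_protocol(group_key, protocol_table)
            if rows:
                return ParameterPdf(
                    parameter, "discrete_joint",
                    {"rows": [tuple(r) for r, _ in rows],
                     "weights": [w for _, w in rows]},
                    columns=PROTOCOL_PARAMETERS, scope="group",
                    linkage_id=f"protocol:{group_key}", tier="elicited")
        return registry.pdf(exam.exam_date, exam.region(), parameter,
                            DEFAULT_SCOPES.get(parameter))

    return resolver


@lru_cache(maxsize=1)
def load_era_registry() -> EraRegistry:
    text = resources.files("ctdosim.data").joinpath("era_defaults.yaml").read_text()
    return EraRegistry(yaml.safe_load(text))
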