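"""CTDIw-normalized organ-dose coefficient tables.

A coefficient table is the Monte Carlo dose database for one phantom:
for each tube voltage and axial rotation position it stores, per organ,
the organ dose from a single rotation divided by the weighted CT dose
index of the matching dosimetry cylinder (16 cm head phantom while the
rotation lies in the head landmark, 32 cm body phantom elsewhere).
Multiplying a coefficient by the examination's per-rotation CTDIw
recovers the organ dose contribution of that rotation.

Lookups interpolate linearly in z and linearly in log-kVp; requests
outside the kVp grid raise instead of extrapolating.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import __version__ as _pkg_version
from .errors import ExtrapolationError, ValidationError
from .phantoms import StylizedPhantom, build_reference_phantom
from .transport import (BeamModel, CtdiPhantomSpec, simulate_axial_rotation,
                        simulate_ctdiw)

__all__ = ["CoefficientTable", "generate_coefficient_table",
           "synthetic_coefficient_table", "save_table", "load_table"]


def _cell_seed(master: int, ik: int, iz: int) -> int:
    # stable per-cell sub-seed, recorded in the table for reproducibility
    return (int(master) * 1_000_003 + ik * 9_176 + iz * 31) % (2 ** 31)


@dataclass
class CoefficientTable:
    """Per-rotation organ dose per unit CTDIw, on a (kVp, z) grid."""

    age_class: str
    sex: str
    kvp_grid: np.ndarray  # ascending
    z_grid: np.ndarray  # mm, ascending, covering the phantom extent
    organs: list[str]
    values: np.ndarray  # (n_kvp, n_z, n_organ), dimensionless, >= 0
    se: np.ndarray  # Monte Carlo standard errors, same shape
    ctdiw_100mas: dict  # kvp -> {"head": mGy, "body": mGy} per 100 mAs
    head_interval: tuple[float, float]  # z-range normalized to the head cylinder
    n_photons: int = 0
    seed: int = 0
    cell_seeds: np.ndarray | None = None  # (n_kvp, n_z)
    software_version: str = _pkg_version
    kind: str = "monte_carlo"  # or "synthetic"

    def __post_init__(self):
        self.kvp_grid = np.asarray(self.kvp_grid, float)
        self.z_grid = np.asarray(self.z_grid, float)
        if np.any(np.diff(self.kvp_grid) <= 0) or np.any(np.diff(self.z_grid) <= 0):
            raise ValidationError("coefficient grids must be strictly increasing")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("coefficients must be finite and non-negative")

    def coefficient(self, organ: str, z, kvp: float) -> np.ndarray:
        """Interpolated coefficient; linear in z, linear in log-kVp."""
        if organ not in self.organs:
            raise ValidationError(f"organ {organ!r} not in table")
        kg = self.kvp_grid
        if not kg[0] <= kvp <= kg[-1]:
            raise ExtrapolationError(
                f"kVp {kvp} outside table grid [{kg[0]}, {kg[-1]}]")
        oi = self.organs.index(organ)
        z = np.asarray(z, float)
        ik = min(np.searchsorted(kg, kvp, side="right"), len(kg) - 1)
        lo = self.values[ik - 1, :, oi] if len(kg) > 1 else self.values[0, :, oi]
        hi = self.values[ik, :, oi] if len(kg) > 1 else self.values[0, :, oi]
        v_lo = np.interp(z, self.z_grid, lo)
        v_hi = np.interp(z, self.z_grid, hi)
        if len(kg) == 1 or kg[ik - 1] == kvp:
            return v_lo if kvp == kg[ik - 1] or len(kg) == 1 else v_hi
        w = (np.log(kvp) - np.log(kg[ik - 1])) / (np.log(kg[ik]) - np.log(kg[ik - 1]))
        return (1 - w) * v_lo + w * v_hi

    def ctdiw_at(self, kvp: float, z: float) -> float:
        """CTDIw (mGy/100 mAs) of the matching cylinder, log-kVp interpolated."""
        kind = "head" if self.head_interval[0] <= z <= self.head_interval[1] else "body"
        kg = self.kvp_grid
        if not kg[0] <= kvp <= kg[-1]:
            raise ExtrapolationError(f"kVp {kvp} outside table grid")
        vals = np.array([self.ctdiw_100mas[float(k)][kind] for k in kg])
        return float(np.exp(np.interp(np.log(kvp), np.log(kg), np.log(vals))))


def generate_coefficient_table(phantom: StylizedPhantom, kvps, z_step_mm: float,
                               n_photons: int, seed: int, *,
                               beam_kwargs: dict | None = None,
                               n_photons_ctdi: int = 50_000) -> CoefficientTable:
    """Build the Monte Carlo dose database for one phantom.

    Each (kVp, z) cell runs an independent axial-rotation simulation with a
    recorded sub-seed, so any cell can be regenerated bit-identically.
    """
    kvps = sorted(float(k) for k in kvps)
    if not kvps:
        raise ValidationError("kVp list must not be empty")
    z0, z1 = phantom.extent
    z_grid = np.arange(z0 + z_step_mm / 2, z1, z_step_mm)
    organs = list(phantom.organs)
    head = phantom.landmarks["head"]
    values = np.zeros((len(kvps), len(z_grid), len(organs)))
    se = np.zeros_like(values)
    seeds = np.zeros((len(kvps), len(z_grid)), dtype=np.int64)
    ctdiw = {}
    bk = dict(beam_kwargs or {})
    for ik, kvp in enumerate(kvps):
        beam = BeamModel(kvp=kvp, **bk)
        ctdiw[kvp] = {
            "head": simulate_ctdiw(beam, CtdiPhantomSpec(diameter_mm=160.0),
                                   n_photons_ctdi, _cell_seed(seed, ik, 10 ** 6)),
            "body": simulate_ctdiw(beam, CtdiPhantomSpec(diameter_mm=320.0),
                                   n_photons_ctdi, _cell_seed(seed, ik, 10 ** 6 + 1)),
        }
        for iz, z in enumerate(z_grid):
            sub = _cell_seed(seed, ik, iz)
            seeds[ik, iz] = sub
            res = simulate_axial_rotation(phantom, beam, float(z), n_photons, sub)
            norm = ctdiw[kvp]["head" if head[0] <= z <= head[1] else "body"]
            # per-photon dose -> per-rotation dose at the calibration output
            scale = beam.photons_per_mas * 100.0 / norm
            for io, organ in enumerate(organs):
                d, d_se = res.organ_dose_per_photon_mgy[organ]
                values[ik, iz, io] = d * scale
                se[ik, iz, io] = d_se * scale
    return CoefficientTable(
        age_class=phantom.age_class, sex=phantom.sex,
        kvp_grid=np.array(kvps), z_grid=z_grid, organs=organs,
        values=values, se=se, ctdiw_100mas=ctdiw, head_interval=head,
        n_photons=n_photons, seed=seed, cell_seeds=seeds)


def synthetic_coefficient_table(phantom: StylizedPhantom,
                                kvps=(80.0, 100.0, 120.0, 140.0),
                                z_step_mm: float = 20.0) -> CoefficientTable:
    """Synthetic (non-Monte-Carlo) coefficient table with the same contract.

    A deterministic, smooth stand-in for the transport-generated database:
    each organ gets an in-field plateau over its axial extent plus
    exponential scatter tails, with a mild power-law kVp dependence. Used
    by the cohort simulator and fast tests where physical fidelity of the
    coefficients is irrelevant but the table contract (shapes, units,
    interpolation, CTDIw normalization) matters.
    """
    kvps = sorted(float(k) for k in kvps)
    z0, z1 = phantom.extent
    z_grid = np.arange(z0 + z_step_mm / 2, z1, z_step_mm)
    organs = list(phantom.organs)
    values = np.zeros((len(kvps), len(z_grid), len(organs)))
    for io, organ in enumerate(organs):
        spans = [(phantom.slabs[si].z0, phantom.slabs[si].z1, frac)
                 for si, _, frac in phantom.organs[organ].extent]
        prof = np.zeros(len(z_grid))
        for s0, s1, frac in spans:
            length = s1 - s0
            # plateau sized so a typical series yields organ doses of a few
            # tens of mGy, matching the scale of the Monte Carlo tables
            peak = frac * min(1.0, 10.0 / length) * 1.3
            inside = (z_grid >= s0) & (z_grid <= s1)
            prof[inside] += peak
            dist = np.where(z_grid < s0, s0 - z_grid, np.maximum(0.0, z_grid - s1))
            prof[~inside] += peak * 0.05 * np.exp(-dist[~inside] / 60.0)
        for ik, kvp in enumerate(kvps):
            values[ik, :, io] = prof * (kvp / 120.0) ** 0.8
    ctdiw = {k: {"head": 0.19 * k / 120.0 * 100, "body": 0.095 * k / 120.0 * 100}
             for k in kvps}
    return CoefficientTable(
        age_class=phantom.age_class, sex=phantom.sex, kvp_grid=np.array(kvps),
        z_grid=z_grid, organs=organs, values=values, se=np.zeros_like(values),
        ctdiw_100mas=ctdiw, head_interval=phantom.landmarks["head"],
        kind="synthetic")


def save_table(table: CoefficientTable, path: str) -> None:
    """Persist a coefficient table to HDF5 with embedded metadata."""
    with h5py.File(path, "w") as f:
        f.attrs.update({
            "age_class": table.age_class, "sex": table.sex,
            "n_photons": table.n_photons, "seed": table.seed,
            "software_version": table.software_version, "kind": table.kind,
            "head_z0": table.head_interval[0], "head_z1": table.head_interval[1],
            "organs": ",".join(table.organs),
        })
        f["kvp_grid"] = table.kvp_grid
        f["z_grid"] = table.z_grid
        f["values"] = table.values
        f["se"] = table.se
        if table.cell_seeds is not None:
            f["cell_seeds"] = table.cell_seeds
        g = f.create_group("ctdiw_100mas")
        for k, v in table.ctdiw_100mas.items():
            g[f"{k}"] = [v["head"], v["body"]]


def load_table(path: str) -> CoefficientTable:
    with h5py.File(path, "r") as f:
        ctdiw = {float(k): {"head": float(v[0]), "body": float(v[1])}
                 for k, v in f["ctdiw_100mas"].items()}
        return CoefficientTable(
            age_class=f.attrs["age_class"], sex=f.attrs["sex"],
            kvp_grid=f["kvp_grid"][:], z_grid=f["z_grid"][:],
            organs=f.attrs["organs"].split(","),
            values=f["values"][:], se=f["se"][:], ctdiw_100mas=ctdiw,
            head_interval=(float(f.attrs["head_z0"]), float(f.attrs["head_z1"])),
            n_photons=int(f.attrs["n_photons"]), seed=int(f.attrs["seed"]),
            cell_seeds=f["cell_seeds"][:] if "cell_seeds" in f else None,
            software_version=str(f.attrs["software_version"]),
            kind=str(f.attrs["kind"]))
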