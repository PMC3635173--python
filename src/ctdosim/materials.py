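"""Phantom materials and photon mass-attenuation data.

Each material carries a tabulated mass-attenuation curve on a common
photon-energy grid (10-200 keV): total, photoelectric and incoherent
(Compton) components in cm^2/g. The bundled table omits coherent
scattering, so total = photoelectric + incoherent exactly and the
interaction sampler partitions the total cross-section without residue.
Lookups between grid points are log-log interpolated.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ValidationError

__all__ = ["Material", "MaterialLibrary", "load_material_library"]


@dataclass(frozen=True)
class Material:
    """A homogeneous tissue substitute with photon attenuation data."""

    name: str
    density: float  # g/cm^3
    energies: np.ndarray = field(repr=False)  # keV, strictly increasing
    mu_total: np.ndarray = field(repr=False)  # cm^2/g
    mu_photoelectric: np.ndarray = field(repr=False)
    mu_incoherent: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValidationError(f"{self.name}: energy grid must be strictly increasing")
        for arr, label in ((self.mu_total, "total"), (self.mu_photoelectric, "photoelectric"),
                           (self.mu_incoherent, "incoherent")):
            if np.any(np.asarray(arr) <= 0):
                raise ValidationError(f"{self.name}: {label} coefficients must be positive")
        if np.any(self.mu_total + 1e-12 < self.mu_photoelectric) or np.any(
                self.mu_total + 1e-12 < self.mu_incoherent):
            raise ValidationError(f"{self.name}: total must dominate each component")

    def _interp(self, table: np.ndarray, energy_kev) -> np.ndarray:
        e = np.asarray(energy_kev, float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise ValidationError(
                f"{self.name}: energy outside attenuation grid "
                f"[{self.energies[0]}, {self.energies[-1]}] keV")
        return np.exp(np.interp(np.log(e), np.log(self.energies), np.log(table)))

    def mass_attenuation(self, energy_kev) -> np.ndarray:
        """Total mass attenuation coefficient, cm^2/g."""
        return self._interp(self.mu_total, energy_kev)

    def linear_attenuation(self, energy_kev) -> np.ndarray:
        """Total linear attenuation coefficient, 1/cm."""
        return self.density * self.mass_attenuation(energy_kev)

    def photoelectric_fraction(self, energy_kev) -> np.ndarray:
        """Probability that an interaction is photoelectric."""
        return (self._interp(self.mu_photoelectric, energy_kev)
                / self._interp(self.mu_total, energy_kev))


class MaterialLibrary:
    """Bundled material set, indexed by name and by integer id (for the
    vectorized transport kernel)."""

    def __init__(self, materials: list[Material]):
        self.materials = list(materials)
        self._by_name = {m.name: m for m in self.materials}
        # dense per-material curves for fast vectorized lookup
        self._log_e = np.log(self.materials[0].energies)
        self._log_mu = np.stack([np.log(m.mu_total * m.density) for m in self.materials])
        self._pe_frac = np.stack([m.mu_photoelectric / m.mu_total for m in self.materials])

    def __getitem__(self, name: str) -> Material:
        try:
            return self._by_name[name]
        except KeyError:
            raise ValidationError(f"unknown material {name!r}") from None

    def index(self, name: str) -> int:
        return self.materials.index(self[name])

    def linear_mu(self, mat_idx: np.ndarray, energy_kev: np.ndarray) -> np.ndarray:
        """Linear attenuation (1/cm) for arrays of material ids and energies."""
        loge = np.log(energy_kev)
        out = np.empty_like(loge)
        for i in range(len(self.materials)):
            m = mat_idx == i
            if m.any():
                out[m] = np.exp(np.interp(loge[m], self._log_e, self._log_mu[i]))
        return out

    def pe_fraction(self, mat_idx: np.ndarray, energy_kev: np.ndarray) -> np.ndarray:
        out = np.empty(len(mat_idx))
        for i in range(len(self.materials)):
            m = mat_idx == i
            if m.any():
                out[m] = np.interp(energy_kev[m], self.materials[i].energies, self._pe_frac[i])
        return out

    def majorant(self, energy_kev: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Upper bound on the linear attenuation over the given materials."""
        idx = ([self.materials.index(self._by_name[n]) for n in names]
               if names else range(len(self.materials)))
        loge = np.log(np.asarray(energy_kev, float))
        curves = [np.exp(np.interp(loge, self._log_e, self._log_mu[i])) for i in idx]
        return np.max(curves, axis=0)


def load_material_library() -> MaterialLibrary:
    """Load the bundled attenuation table shipped with the package."""
    text = resources.files("ctdosim.data").joinpath("attenuation.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    mats = []
    for name in dict.fromkeys(r["material"] for r in rows):
        sub = [r for r in rows if r["material"] == name]
        mats.append(Material(
            name=name,
            density=float(sub[0]["density_g_cm3"]),
            energies=np.array([float(r["energy_kev"]) for r in sub]),
            mu_total=np.array([float(r["mu_total"]) for r in sub]),
            mu_photoelectric=np.array([float(r["mu_photoelectric"]) for r in sub]),
            mu_incoherent=np.array([float(r["mu_incoherent"]) for r in sub]),
        ))
    return MaterialLibrary(mats)
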