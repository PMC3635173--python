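"""Stylized age- and sex-dependent computational phantoms.

The phantom family replaces anatomically detailed hybrid body models with
stacked elliptical slabs: each axial section (head, neck, chest, abdomen,
pelvis, legs) is an elliptical cylinder of soft tissue containing nested
elliptical regions for skeleton, brain, lungs, colon, thyroid and breast.
The interface — reference age classes, stature-based selection, body-region
landmarks, organ masses, and a point-in-organ lookup for the transport
kernel — is the one a detailed phantom family would expose, so the
surrogate can be swapped out without touching the rest of the pipeline.

Coordinate convention: phantom-local z in mm, origin at the crown,
increasing caudally; x is lateral (patient left positive), y is
antero-posterior (anterior positive). The body axis is x = y = 0.

Red bone marrow is distributed over skeletal sites (skull, spine, pelvis,
other) with fixed per-age-class site fractions from the bundled
anthropometry file; the marrow dose is the fraction-weighted mean of the
site doses.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from .materials import MaterialLibrary, load_material_library

__all__ = [
    "AGE_CLASSES", "ORGANS", "BODY_REGIONS",
    "Ellipse", "Region", "AxialSlab", "OrganRegion", "StylizedPhantom",
    "build_reference_phantom", "select_phantom", "locate_region", "organ_mass",
    "load_anthropometry",
]

AGE_CLASSES = ("newborn", "1y", "5y", "10y", "15y", "adult")
#: representative age in years per class, used for nearest-age selection
AGE_OF_CLASS = {"newborn": 0.0, "1y": 1.0, "5y": 5.0, "10y": 10.0, "15y": 15.0, "adult": 20.0}
ORGANS = ("brain", "red_bone_marrow", "colon", "thyroid", "breast", "lungs", "remainder")
BODY_REGIONS = ("head", "chest", "abdomen")

# axial section lengths as fractions of standing height (head fraction is
# age-dependent and comes from the anthropometry file)
_SECTION_FRACTIONS = {"neck": 0.04, "chest": 0.17, "abdomen": 0.14, "pelvis": 0.08}
_MEAN_BODY_DENSITY = 1.02e-3  # g/mm^3


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in the axial (x, y) plane; mm."""

    cx: float
    cy: float
    a: float  # lateral semi-axis
    b: float  # antero-posterior semi-axis

    @property
    def area(self) -> float:
        return np.pi * self.a * self.b

    def contains(self, x, y):
        return ((np.asarray(x) - self.cx) / self.a) ** 2 + \
               ((np.asarray(y) - self.cy) / self.b) ** 2 <= 1.0

    def boundary(self, n: int = 64) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return self.cx + self.a * np.cos(t), self.cy + self.b * np.sin(t)


@dataclass(frozen=True)
class Region:
    """A nested tissue region within a slab."""

    label: str
    ellipse: Ellipse
    material: str


@dataclass(frozen=True)
class AxialSlab:
    """One axial section: outer body envelope plus nested regions.

    Point resolution is innermost-first: a point belongs to the smallest
    region containing it. Regions must therefore be pairwise disjoint or
    strictly nested — never partially overlapping.
    """

    label: str
    z0: float
    z1: float
    outer: Ellipse
    outer_material: str
    regions: tuple[Region, ...] = ()

    def __post_init__(self):
        if not self.z1 > self.z0:
            raise ValidationError(f"slab {self.label}: z1 must exceed z0")
        for r in self.regions:
            bx, by = r.ellipse.boundary()
            if not np.all(self.outer.contains(bx, by)):
                raise ValidationError(f"slab {self.label}: region {r.label} "
                                      "extends outside the body envelope")
        for i, ri in enumerate(self.regions):
            for rj in self.regions[i + 1:]:
                if not _nested_or_disjoint(ri.ellipse, rj.ellipse):
                    raise ValidationError(
                        f"slab {self.label}: regions {ri.label} and {rj.label} "
                        "partially overlap")

    @property
    def thickness(self) -> float:
        return self.z1 - self.z0


def _nested_or_disjoint(e1: Ellipse, e2: Ellipse, n: int = 64) -> bool:
    b1 = e2.contains(*e1.boundary(n))
    b2 = e1.contains(*e2.boundary(n))
    if b1.all() or b2.all():  # nested
        return True
    if not b1.any() and not b2.any() and not e1.contains(e2.cx, e2.cy) \
            and not e2.contains(e1.cx, e1.cy):  # disjoint
        return True
    return False


@dataclass(frozen=True)
class OrganRegion:
    """Maps an organ to geometric cells with mass fractions.

    ``extent`` entries are (slab index, region label, mass fraction); the
    fractions are the weights with which cell doses combine into the organ
    dose (for red bone marrow these are the skeletal-site fractions).
    """

    organ: str
    extent: tuple[tuple[int, str, float], ...]
    material: str
    total_mass: float  # g, reference anthropometry

    def __post_init__(self):
        fracs = np.array([f for _, _, f in self.extent])
        if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
            raise ValidationError(f"{self.organ}: mass fractions must be "
                                  "non-negative and sum to 1")
        if self.total_mass <= 0:
            raise ValidationError(f"{self.organ}: mass must be positive")


class StylizedPhantom:
    """A stacked-slab body model with organ regions and landmarks."""

    def __init__(self, age_class: str, sex: str, height: float, mass: float,
                 slabs: list[AxialSlab], organs: list[OrganRegion],
                 landmarks: dict[str, tuple[float, float]],
                 materials: MaterialLibrary | None = None):
        self.age_class = age_class
        self.sex = sex
        self.height = height  # cm
        self.mass = mass  # kg
        self.slabs = list(slabs)
        self.organs = {o.organ: o for o in organs}
        self.landmarks = dict(landmarks)
        self.materials = materials or load_material_library()
        self._validate()
        self._index_cells()

    # -- construction ------------------------------------------------------
    def _validate(self):
        edges = [(s.z0, s.z1) for s in self.slabs]
        for (a0, a1), (b0, b1) in zip(edges, edges[1:]):
            if not np.isclose(a1, b0):
                raise ValidationError("slabs must be contiguous and non-overlapping")
        if not (np.isclose(edges[0][0], 0.0) and np.isclose(edges[-1][1], self.height * 10)):
            raise ValidationError("slabs must cover [0, height*10] mm")
        z_prev = -np.inf
        for region in BODY_REGIONS:
            z0, z1 = self.landmarks[region]
            if not (z_prev <= z0 < z1 <= self.height * 10):
                raise ValidationError("landmarks must be ordered head < chest < "
                                      "abdomen and lie within the body")
            z_prev = z1

    def _index_cells(self):
        """Enumerate tally cells: per slab, nested regions sorted innermost
        (smallest area) first, then the outer envelope; a trailing cell
        collects deposits outside the body."""
        self._z_edges = np.array([s.z0 for s in self.slabs] + [self.slabs[-1].z1])
        self.cell_labels: list[str] = []
        self._cell_material: list[int] = []
        cell_mass: list[float] = []
        self._slab_regions: list[list[tuple[Ellipse, int]]] = []
        lib = self.materials
        for si, slab in enumerate(self.slabs):
            ordered = sorted(slab.regions, key=lambda r: r.ellipse.area)
            entries = []
            for r in ordered:
                cid = len(self.cell_labels)
                self.cell_labels.append(f"{slab.label}/{r.label}")
                self._cell_material.append(lib.index(r.material))
                inner = sum(q.ellipse.area for q in ordered
                            if q is not r and _inside(q.ellipse, r.ellipse))
                net = r.ellipse.area - inner
                cell_mass.append(net * slab.thickness * lib[r.material].density * 1e-3)
                entries.append((r.ellipse, cid))
            cid = len(self.cell_labels)
            self.cell_labels.append(f"{slab.label}/body")
            self._cell_material.append(lib.index(slab.outer_material))
            inner = sum(q.ellipse.area for q in ordered
                        if not any(_inside(q.ellipse, p.ellipse) for p in ordered if p is not q))
            net = slab.outer.area - inner
            cell_mass.append(net * slab.thickness * lib[slab.outer_material].density * 1e-3)
            entries.append((slab.outer, cid))
            self._slab_regions.append(entries)
        self.air_cell = len(self.cell_labels)
        self.cell_labels.append("air")
        self._cell_material.append(lib.index("air"))
        cell_mass.append(np.inf)
        self.cell_mass_g = np.array(cell_mass)
        self.cell_material = np.array(self._cell_material)
        self._cell_index = {lab: i for i, lab in enumerate(self.cell_labels)}

    # -- queries -----------------------------------------------------------
    @property
    def extent(self) -> tuple[float, float]:
        return 0.0, self.height * 10

    def lookup_cells(self, x, y, z) -> np.ndarray:
        """Vectorized point -> tally-cell id (innermost region wins)."""
        x, y, z = (np.asarray(v, float) for v in (x, y, z))
        out = np.full(x.shape, self.air_cell, dtype=np.int64)
        slab_of = np.searchsorted(self._z_edges, z, side="right") - 1
        in_body_z = (slab_of >= 0) & (slab_of < len(self.slabs))
        for si in range(len(self.slabs)):
            sel = in_body_z & (slab_of == si)
            if not sel.any():
                continue
            unassigned = sel.copy()
            for ellipse, cid in self._slab_regions[si]:
                hit = unassigned & ellipse.contains(x, y)
                out[hit] = cid
                unassigned &= ~hit
        return out

    def lookup_materials(self, x, y, z) -> np.ndarray:
        return self.cell_material[self.lookup_cells(x, y, z)]

    def cells_of(self, organ: str) -> list[tuple[int, float]]:
        """(cell id, weight) pairs used to turn cell doses into an organ dose."""
        if organ not in self.organs:
            raise ValidationError(f"organ {organ!r} not present in phantom")
        reg = self.organs[organ]
        out = []
        for si, label, frac in reg.extent:
            key = f"{self.slabs[si].label}/{label}"
            out.append((self._cell_index[key], frac))
        return out

    def bounding_halfwidth(self) -> float:
        """Radius of a cylinder enclosing every slab envelope, mm."""
        return max(max(abs(s.outer.cx) + s.outer.a, abs(s.outer.cy) + s.outer.b)
                   for s in self.slabs)

    def to_json(self) -> str:
        """Geometry dump for inspection."""
        return json.dumps({
            "age_class": self.age_class, "sex": self.sex,
            "height_cm": self.height, "mass_kg": self.mass,
            "landmarks": self.landmarks,
            "slabs": [{
                "label": s.label, "z0": s.z0, "z1": s.z1,
                "outer": vars(s.outer) | {"material": s.outer_material},
                "regions": [vars(r.ellipse) | {"label": r.label, "material": r.material}
                            for r in s.regions],
            } for s in self.slabs],
            "organs": [{"organ": o.organ, "total_mass_g": o.total_mass,
                        "extent": list(o.extent)} for o in self.organs.values()],
        }, indent=2)


def _inside(e1: Ellipse, e2: Ellipse) -> bool:
    """True when e1 lies strictly inside e2 (by sampled boundary)."""
    return e1.area < e2.area and bool(np.all(e2.contains(*e1.boundary())))


@lru_cache(maxsize=1)
def load_anthropometry() -> dict:
    text = resources.files("ctdosim.data").joinpath("anthropometry.yaml").read_text()
    return yaml.safe_load(text)


def _section_lengths(height_mm: float, head_frac: float) -> dict[str, float]:
    L = {"head": head_frac * height_mm}
    for k, f in _SECTION_FRACTIONS.items():
        L[k] = f * height_mm
    L["legs"] = height_mm - sum(L.values())
    return L


@lru_cache(maxsize=32)
def build_reference_phantom(age_class: str, sex: str) -> StylizedPhantom:
    """Construct the reference phantom for an age class and sex.

    Deterministic: geometry is derived entirely from the bundled
    anthropometry file (height, mass, organ masses, marrow site fractions).
    """
    if age_class not in AGE_CLASSES:
        raise ConfigurationError(f"unknown age class {age_class!r}; "
                                 f"expected one of {AGE_CLASSES}")
    if sex not in ("male", "female"):
        raise ConfigurationError(f"unknown sex {sex!r}")
    anthro = load_anthropometry()
    ref = anthro["reference"][sex][age_class]
    H = ref["height_cm"] * 10.0
    body_volume = ref["mass_kg"] * 1000 / 1.02 * 1e3  # mm^3
    L = _section_lengths(H, anthro["head_height_fraction"][age_class])

    a_h, b_h = 0.38 * L["head"], 0.46 * L["head"]
    trunk_len = L["chest"] + L["abdomen"] + L["pelvis"]
    a_t = np.sqrt(0.52 * body_volume / trunk_len / (np.pi * 0.75))
    b_t = 0.75 * a_t
    a_l = np.sqrt(0.30 * body_volume / L["legs"] / (np.pi * 0.55))
    b_l = 0.55 * a_l

    z = np.cumsum([0, L["head"], L["neck"], L["chest"], L["abdomen"], L["pelvis"], L["legs"]])
    E = Ellipse
    slabs = [
        AxialSlab("head", z[0], z[1], E(0, 0, a_h, b_h), "soft_tissue", (
            Region("brain", E(0, 0, 0.76 * a_h, 0.76 * b_h), "brain"),
            Region("skull", E(0, 0, 0.90 * a_h, 0.90 * b_h), "bone"),
        )),
        AxialSlab("neck", z[1], z[2], E(0, 0, 0.45 * a_h, 0.45 * b_h), "soft_tissue", (
            Region("spine", E(0, -0.5 * 0.45 * b_h, 0.22 * 0.45 * a_h, 0.22 * 0.45 * b_h), "bone"),
            Region("thyroid", E(0, 0.55 * 0.45 * b_h, 0.30 * 0.45 * a_h, 0.20 * 0.45 * b_h),
                   "soft_tissue"),
        )),
        AxialSlab("chest", z[2], z[3], E(0, 0, a_t, b_t), "soft_tissue", (
            Region("lung_left", E(0.50 * a_t, 0.05 * b_t, 0.32 * a_t, 0.60 * b_t), "lung"),
            Region("lung_right", E(-0.50 * a_t, 0.05 * b_t, 0.32 * a_t, 0.60 * b_t), "lung"),
            Region("spine", E(0, -0.72 * b_t, 0.12 * a_t, 0.14 * b_t), "bone"),
            Region("breast_left", E(0.32 * a_t, 0.82 * b_t, 0.15 * a_t, 0.10 * b_t),
                   "soft_tissue"),
            Region("breast_right", E(-0.32 * a_t, 0.82 * b_t, 0.15 * a_t, 0.10 * b_t),
                   "soft_tissue"),
        )),
        AxialSlab("abdomen", z[3], z[4], E(0, 0, a_t, 0.95 * b_t), "soft_tissue", (
            Region("spine", E(0, -0.72 * 0.95 * b_t, 0.12 * a_t, 0.14 * 0.95 * b_t), "bone"),
            Region("colon", E(0, 0.15 * 0.95 * b_t, 0.50 * a_t, 0.32 * 0.95 * b_t),
                   "soft_tissue"),
        )),
        AxialSlab("pelvis", z[4], z[5], E(0, 0, a_t, 0.85 * b_t), "soft_tissue", (
            Region("pelvic_bone_left", E(0.62 * a_t, -0.1 * 0.85 * b_t, 0.16 * a_t,
                                         0.40 * 0.85 * b_t), "bone"),
            Region("pelvic_bone_right", E(-0.62 * a_t, -0.1 * 0.85 * b_t, 0.16 * a_t,
                                          0.40 * 0.85 * b_t), "bone"),
            Region("colon", E(0, 0.1 * 0.85 * b_t, 0.28 * a_t, 0.30 * 0.85 * b_t),
                   "soft_tissue"),
        )),
        AxialSlab("legs", z[5], z[6], E(0, 0, a_l, b_l), "soft_tissue", (
            Region("femur_left", E(0.50 * a_l, 0, 0.14 * a_l, 0.25 * b_l), "bone"),
            Region("femur_right", E(-0.50 * a_l, 0, 0.14 * a_l, 0.25 * b_l), "bone"),
        )),
    ]

    sf = anthro["rbm_site_fractions"][age_class]
    # spine marrow is split over neck/chest/abdomen by section length
    spine_lens = np.array([L["neck"], L["chest"], L["abdomen"]])
    spine_w = sf["spine"] * spine_lens / spine_lens.sum()
    om = ref["organs"]
    organs = [
        OrganRegion("brain", ((0, "brain", 1.0),), "brain", om["brain"]),
        OrganRegion("thyroid", ((1, "thyroid", 1.0),), "soft_tissue", om["thyroid"]),
        OrganRegion("lungs", ((2, "lung_left", 0.5), (2, "lung_right", 0.5)),
                    "lung", om["lungs"]),
        OrganRegion("breast", ((2, "breast_left", 0.5), (2, "breast_right", 0.5)),
                    "soft_tissue", om["breast"]),
        OrganRegion("colon", ((3, "colon", 0.7), (4, "colon", 0.3)),
                    "soft_tissue", om["colon"]),
        OrganRegion("red_bone_marrow", (
            (0, "skull", sf["skull"]),
            (1, "spine", spine_w[0]), (2, "spine", spine_w[1]), (3, "spine", spine_w[2]),
            (4, "pelvic_bone_left", sf["pelvis"] / 2),
            (4, "pelvic_bone_right", sf["pelvis"] / 2),
            (5, "femur_left", sf["other"] / 2), (5, "femur_right", sf["other"] / 2),
        ), "bone", om["red_bone_marrow"]),
    ]
    phantom = StylizedPhantom(
        age_class, sex, ref["height_cm"], ref["mass_kg"], slabs, organs,
        landmarks={"head": (float(z[0]), float(z[1])),
                   "chest": (float(z[2]), float(z[3])),
                   "abdomen": (float(z[3]), float(z[4]))})
    # remainder: the soft-tissue envelope of every slab, weighted by cell mass
    body_cells = [phantom._cell_index[f"{s.label}/body"] for s in phantom.slabs]
    masses = phantom.cell_mass_g[body_cells]
    weights = masses / masses.sum()
    extent = tuple((si, "body", float(w)) for si, w in enumerate(weights))
    phantom.organs["remainder"] = OrganRegion(
        "remainder", extent, "soft_tissue", om["remainder"])
    return phantom


def select_phantom(age: float, sex: str, height: float | None = None,
                   weight: float | None = None) -> str:
    """Pick the reference age class most resembling a patient.

    Without stature the nearest reference age wins, ties to the younger
    class (smaller bodies receive more dose per unit exposure, so the
    tie-break is conservative). With both height (cm) and weight (kg) the
    class minimizing Euclidean distance in standardized (height, weight)
    space over the reference family of that sex wins.
    """
    if age < 0:
        raise ValidationError("age must be non-negative")
    if age > 25:
        raise ValidationError("age beyond the paediatric/young-adult range")
    if sex not in ("male", "female"):
        raise ConfigurationError(f"unknown sex {sex!r}")
    if height is not None and weight is not None:
        anthro = load_anthropometry()["reference"][sex]
        hs = np.array([anthro[c]["height_cm"] for c in AGE_CLASSES])
        ws = np.array([anthro[c]["mass_kg"] for c in AGE_CLASSES])
        d2 = ((height - hs) / hs.std()) ** 2 + ((weight - ws) / ws.std()) ** 2
        return AGE_CLASSES[int(np.argmin(d2))]
    ages = np.array([AGE_OF_CLASS[c] for c in AGE_CLASSES])
    dist = np.abs(age - ages)
    # ties go to the younger class: first minimum in ascending-age order
    return AGE_CLASSES[int(np.argmin(dist))]


def locate_region(phantom: StylizedPhantom, body_region: str) -> tuple[float, float]:
    """Landmark z-interval (mm) of a scannable body region."""
    if body_region not in BODY_REGIONS:
        raise ValidationError(f"unknown body region {body_region!r}; "
                              f"expected one of {BODY_REGIONS}")
    return phantom.landmarks[body_region]


def organ_mass(phantom: StylizedPhantom, organ: str) -> float:
    """Reference mass of an organ, grams."""
    if organ not in phantom.organs:
        raise ValidationError(f"organ {organ!r} not present in phantom")
    return phantom.organs[organ].total_mass
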