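# Methods

This document records the models implemented in `ctdosim`, the parameter
defaults and why they were chosen, what the synthetic generator does and
does not emulate, the numerical choices, and the limitations. Problem
sizes (cohort sizes, photon counts, grid resolutions) quoted here are this
package's own choices, selected to balance statistical resolution against
single-CPU runtime.

## Phantom model

Phantoms are stylized stacked elliptical slabs: each body section
(head, neck, chest, abdomen+pelvis, legs) is a stack of elliptical
cylinders of section-specific half-axes, with the z origin at the crown
and z increasing caudally (mm). Six age classes (`newborn`, `1y`, `5y`,
`10y`, `15y`, `adult`) × two sexes are built from a bundled anthropometry
table (`data/anthropometry.yaml`): reference heights, masses and organ
masses follow the standard reference-individual compilations used in
computational dosimetry. Organs (`brain`, `red_bone_marrow`, `colon`,
`thyroid`, `breast`, `lungs`, `remainder`) are nested ellipsoidal or slab
regions placed inside the body envelope; anatomical landmarks `head`,
`chest`, `abdomen` are ordered, non-overlapping z intervals used to map
scan ranges.

Red bone marrow is not a contiguous region: its dose is a fixed-fraction
weighted mean over skeletal sites (skull, spine, pelvis, other), with
age-dependent fractions stored in the anthropometry table; the marrow
distribution shifts from skull-dominant in infancy toward spine/pelvis in
adulthood, which is why the same head scan gives an infant a much larger
marrow dose than an adolescent.

Phantom selection takes the age at the exam date (ties between classes go
to the younger class); when height and weight are recorded, the nearest
reference individual in normalized (height, weight) space overrides the
age-based choice.

## Photon transport

A history-based Monte Carlo with:

- **Interactions**: incoherent (Compton) scattering sampled from the
  Klein–Nishina distribution by rejection in the energy ratio
  ε = E′/E ∈ [1/(1+2α), 1] (α = E/511.0 keV), and photoelectric absorption
  deposited locally. Coherent scattering and fluorescence are neglected
  (sub-percent effects at CT energies in soft tissue).
- **Geometry traversal**: Woodcock (delta) tracking against the majorant
  cross-section, so arbitrary cell shapes need only point lookups.
- **Energy deposition**: kerma approximation — energy transferred at the
  interaction site is deposited there; secondary electrons are not
  tracked (their range at ≤140 kVp is below the slab resolution).
- **Cutoff**: photons below 2 keV deposit locally and terminate.
- **Materials**: air, water, soft tissue, bone, lung from a bundled
  attenuation table (10–200 keV), log–log interpolated; energies outside
  the table are refused rather than extrapolated.
- **Source**: fan beam of the set collimation rotating about the phantom
  axis; polychromatic spectra are collapsed to one effective energy per
  kVp (80→50, 100→56, 120→62, 140→69 keV), a standard half-value-layer
  style simplification.
- **Conservation**: every run closes the balance
  (deposited + escaped + below-cutoff = input) to a relative 1e-9; the
  residual is exposed on the result object and tested.

CTDI is simulated in PMMA cylinders (160 mm head, 320 mm body) with a
100 mm pencil-chamber integration length:
`CTDIw = centre/3 + 2/3 × mean(4 peripheral positions)`.

## Organ-dose coefficients

`generate_coefficient_table` runs one axial rotation per (kVp, z) cell and
stores organ dose per 100 mAs normalized to the simulated CTDIw at that
kVp (head phantom inside the head landmark, body phantom elsewhere).
Tables carry per-cell Monte Carlo standard errors, the generation seed and
per-cell sub-seeds (any cell can be regenerated bit-identically), and are
serialized to HDF5. Lookup interpolates linearly in z and in log(kVp) and
refuses extrapolation outside the grid. Default production settings —
kVp grid (80, 100, 120, 140), 20 000 photons/cell — keep per-cell SE at
the few-percent level; the test suite uses coarser grids for speed.
`synthetic_coefficient_table` is a deterministic analytic stand-in with
the same interface (in-field plateau, exponential scatter tails, power-law
kVp scaling) used where Monte Carlo noise or cost is unwanted.

## Dose engine

A series is modelled as a rotation train stepped by `collimation × pitch`
across the mapped scan interval, with a fractional weight for the partial
last rotation; organ dose sums `c_T(z, kVp) × CTDIw × mAs/100` over
rotations. The scan interval comes from recorded start/end positions
(length preserved, centred on the landmark of the recorded body region)
or, failing that, from the landmark itself. CTDIw is resolved through a
three-tier hierarchy recorded in the provenance: a reported CTDIw (or
CTDIvol × pitch), else a scanner-class default from `data/nctdiw.yaml`
(era-typical single-slice and multi-slice values per kVp), else the
coefficient table's own simulated reference. The engine is exactly linear
in mAs and CTDIw and exactly additive over series and exams; missing
required parameters raise a reconstruction error (nothing is silently
defaulted), and kVp outside the table grid raises an extrapolation error.

## DICOM intake and grouping

Intake reads DICOM Part 10 headers (pydicom), maps the standard CT
attributes (KVP, Exposure, XRayTubeCurrent, ExposureTime,
SpiralPitchFactor, TotalCollimationWidth, SliceLocation, CTDIvol …) to
series records, groups files by study/series UID, and reports exactly the
set of absent fields — absence is preserved, never zero-filled. Files for
one examination must agree on patient identity (consistency error
otherwise). Body region can be recognized from axial pixel data via
per-slice features (mean HU, air fraction, bone fraction) and a
majority-vote classifier whose confidence is the majority share. Patients
are assigned to protocol groups (hospital × calendar period × scanner
model × exam type × age band) with half-open period intervals; protocol
tables round-trip through CSV.

## Missing-parameter uncertainty

Every missing technical parameter is a PDF (`point`, `uniform`,
`triangular`, `lognormal`, or `discrete_joint` over complete parameter
rows) with a sharing scope (`cohort`, `group`, `patient`) and a
confidence tier (`elicited` > `sparse` > `era_default`). The resolver
tiers: a matched group's protocol rows become one joint PDF over
(kVp, mAs, pitch, scan length) sharing a linkage id — a realization draws
one internally consistent row, never independent marginals; unmatched
groups fall back to era defaults (`data/era_defaults.yaml`), which must
narrow (never widen) in later eras since documentation improves over
time. Tube-current modulation is exempt from that rule because it only
exists in the later era; its dose-reducing factor is applied only when
mAs itself is imputed, since a recorded mAs already reflects modulation.

Draw seeding is `stable_seed(master, scope_key, linkage, realization)` —
an order-stable 31-bit SHA-256 hash — so realizations are reproducible
and independent of patient insertion order. Group-scope draws are shared
by all patients of a group within a realization (correlated dose errors);
patient-scope draws are independent. A paired replicate (same group draws,
fresh patient draws) yields the variance decomposition
`Var_unshared = E[(D − D′)²]/2`, with the shared part as the exact
complement. Recorded values always pass through untouched.

## Risk model

Stratified Poisson ERR: `rate = λ0(stratum)(1 + βD)`, D in Gy
(realization doses are mGy; the 1e-3 conversion is explicit at the module
boundary). Baselines are profiled analytically; β is maximized on the
one-dimensional profile and the 95% interval is the χ²(1) cutoff
(Δlogℓ = 1.92). Degenerate inputs (no dose contrast, no cases) and
boundary/unbounded intervals are flagged on the fit object, never raised.
Realization strategies: `fit_mean_dose` fits the per-patient mean;
`fit_all_realizations` fits each realization, combines estimates with
likelihood weights ∝ exp(ℓ_v − max ℓ), and reads the interval off the
weighted mixture of per-realization profile densities, so shared
between-realization spread widens it. When every realization's upper
limit is unbounded the combined interval is reported unbounded and
flagged.

## Synthetic cohort generator

The generator emulates, with known ground truth:

- a paediatric cohort (default 500 patients, 3 hospitals, exams
  1990–2010, ages in [0, 20), head/chest/abdomen at 0.5/0.2/0.3);
- per-hospital PACS transition dates splitting exams into the pre-PACS
  scenario (all technical parameters stripped; roster fields survive)
  and post-PACS (configurable independent per-field dropout; scan start
  and end are dropped together since both come from slice locations);
- questionnaire-style protocol tables (two joint rows per group, 2:1
  weights) drawn from the era defaults — the same pool the true
  parameters are drawn from, so Scenario-1 lookup is well specified;
- DICOM file sets for post-PACS exams (two single-frame files per series;
  absent attributes omitted from the header);
- labelled axial image stacks for the region classifier (head: skull
  ring, chest: two air-density lungs, abdomen: neither);
- Poisson outcomes under `rate = λ0(1 + β·D_Gy)` with default β = 2/Gy
  and λ0 = 2e-3 per person-year, sex strata, 5–15 person-years.

Ground-truth doses come from the same dose engine used for
reconstruction — there is no second dose model — so reconstruction from
fully observed parameters reproduces the truth to machine precision, and
any discrepancy isolates a masking/intake defect. The generator records
parameters at realistic precisions (integer mAs, since the DICOM Exposure
attribute is an integer string; 0.1 mm slice positions), so the DICOM
round trip is exact by construction rather than approximately.

Not emulated: scanner-specific bowtie filters and spectra, image noise
and artefacts beyond Gaussian HU noise, overlapping/multi-phase series,
contrast media, real anatomical variability beyond a stature override,
and informative missingness (dropout is independent of dose).

## Numerical choices

- Philox counter-based RNG everywhere; all seeds are 31-bit values
  derived from one master seed by SHA-256 hashing, so every derived seed
  stays below 2³¹ and streams are independent of iteration order.
- Exact algebraic invariants (mAs linearity, additivity,
  CTDIw = CTDIvol × pitch) hold bitwise; products with non-power-of-two
  factors are exact to the last ulp only (float associativity).
- Energy accounting in float64; balance enforced to 1e-9 relative.
- 2 keV transport cutoff; 10–200 keV material tables; no extrapolation
  anywhere (kVp, energy, z all refuse out-of-grid queries).
- HDF5 for dose arrays and coefficient tables; JSON (strict: non-finite
  mapped to null) for fits and manifests; CSV for flat tables.

## Problem sizes

Defaults were sized for a single CPU: 500-patient default cohorts (2 000
for risk-recovery runs), V = 20 realizations by default (100 for interval
studies; V beyond ~100 changes combined intervals little at this cohort
size), 20 000 photons per coefficient cell, 40 mm coefficient z step in
production and coarser in tests. The full pipeline on the default cohort
runs in well under a minute with synthetic tables; Monte Carlo
coefficient generation for all twelve phantoms at production settings is
minutes.

## Limitations

- Stylized slab phantoms misplace dose gradients near organ boundaries
  relative to voxel/hybrid phantoms; coefficients are smooth in z by
  construction.
- The effective-energy beam model ignores spectral hardening across the
  body, biasing deep-organ doses at low kVp.
- The kerma approximation slightly overestimates local dose near
  interfaces at 140 kVp.
- Era-default PDFs and the nCTDIw fallback table are editable study
  inputs with representative, not measured, values; results at the
  era-default tier inherit their width.
- The ERR maximum-likelihood estimator is right-skewed in small samples
  (few cases); at typical CT doses (~10 mGy) cohorts of a few thousand
  cannot bound β usefully — intervals are honest but wide.
- The region classifier is tuned to the generator's synthetic contrast
  signatures; real CT stacks would need retrained thresholds.
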