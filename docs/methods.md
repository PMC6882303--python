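# Methods

`robustrbe` studies how two families of uncertainty change the clinical
picture of intensity-modulated proton therapy (IMPT) plans for
base-of-skull tumors: systematic *physical* errors (patient set-up and
proton range) and *biological* uncertainty in the proton relative
biological effectiveness (RBE).  Because clinical plans and patient imaging
are not distributable, the package generates synthetic voxel phantoms that
reproduce the geometric predicament of these cases — a target wrapped
around or abutting the brainstem and overlapping the optic chiasm — and
forward-computes proton and photon dose on them with analytical models.
Everything downstream (LET_d, variable RBE weighting, worst-case scenario
analysis, DVH metrics and constraint bookkeeping) operates on those voxel
grids exactly as it would on grids exported from a treatment planning
system, and the generic raster reader accepts externally supplied grids.

## Synthetic phantoms

Structures are unions of analytic shapes rasterized by the
voxel-center-inside rule on an isotropic grid (default 3 mm): an
ellipsoidal head (water density 1.0 inside, 0 outside), brain, an
ellipsoidal CTV at the skull base, a vertical elliptic-cylinder brainstem
placed posterior to the CTV at a configurable gap (default 0 = abutting),
a small ellipsoidal chiasm (~0.5 cm^3) and two capsule-shaped optic
nerves running anterolaterally.  Two quantities are calibrated against the
raster rather than taken from the analytic shapes, each to a one-voxel
tolerance: the CTV volume (bisection on the ellipsoid scale) and the
chiasm position (bisection along the anterior axis until the requested
fraction of chiasm voxels — default 0.7, "most of the chiasm inside the
target" — lies inside the CTV).  Sub-voxel seeded jitter of shape centers
breaks raster symmetry so these bisections can resolve single voxels; it
also makes every phantom bit-reproducible from its spec and seed.

Cohorts jitter the base geometry: target volume × U(0.75, 1.25) (adult
base 25 cm^3, pediatric 15 cm^3 — no cohort volumes are published for
these cases, so these are modelling choices, not cohort-matched values),
overlap fraction + U(−0.15, +0.15) clipped to [0.35, 0.95].  The default
mix is 6 adult + 4 pediatric.  Prescriptions: adult 65.13 Gy(RBE) in 39
fractions, pediatric 50.4 Gy(RBE) in 28.

## Proton depth-dose and LET_d

Pristine Bragg curves integrate the power-law range-energy relation
R = αE^p (α = 0.0022 cm·MeV^−p, p = 1.77).  The track stopping power
S(r) = E(r)/(p·r) at residual range r is averaged over a Gaussian range
spectrum (σ = 1.2% of range) for the depth dose, and the dose-averaged
LET is the ratio of the second to the first moment,
LET_d = ⟨S²⟩/⟨S⟩.  The integrable singularities of S and S² at r → 0 are
removed exactly by power-substitution quadrature, which keeps both curves
smooth through the peak.  LET_d is capped at 20 keV/µm; the cap is reached
only distal to the Bragg peak where dose is already falling.  The curve is
calibrated so the dose maximum sits exactly at the requested range.  (At
ranges above ~20 cm the straggling width makes "peak at range" and
"distal-90% at range" incompatible at the 2 mm level; the peak convention
is used throughout.)  Entrance LET values follow directly from the
stopping-power model: ~0.66 keV/µm at 10 cm range, rising above
1.5 keV/µm only for sub-1.5 cm ranges.

SOBPs are non-negative least-squares stacks of pulled-back pristine peaks
with the flat-plateau target evaluated 2 mm inside the proximal edge and
3 mm inside the distal edge.  Pullback is modelled as energy degradation
of the distal beam, so all constituent peaks share the distal peak's
absolute straggling width; with the default pullback spacing of 2σ the
plateau ripple stays well under the 2% reporting threshold (larger ripple
raises an explicit planning error, never a silent acceptance).  The
distal-most peak always carries the largest weight, the classic SOBP
signature.  Note that SOBP LET_d ripples by a few hundredths of keV/µm
across the plateau (adjacent pullback peaks alternate in dominance); only
the pristine-beam LET_d is strictly monotone with depth.

## Plan model

Four fixed fields in a star arrangement (two superior-lateral at gantry
±90°/couch 40°, two inferior-anterior-lateral at gantry ±45°/couch −20°,
a documented stand-in consistent with beams roughly tangential to the
optic apparatus).  Each field deposits dose along straight parallel rays;
water-equivalent depth is the cumulative density-weighted path length
computed on a beam-aligned grid, and the published range-uncertainty
recipe (3.5% of range + 1 mm) sets the distal and proximal SOBP auto-fit
margins around the CTV's depth extent.

The lateral fluence profile emulates what inverse robust optimization
does to a delivered plan, since the package deliberately contains no
optimizer:

* aperture = CTV projection dilated by 1.5 penumbra sigma (so the target
  edge sits at the ~93% fluence level) **plus a 3 mm set-up margin** — a
  plan robustly optimized against ±3 mm shifts keeps the target covered
  under those shifts, which is equivalent to spreading the fluence;
* over each D-volume-constrained organ's shadow (outside the raw target
  shadow) the fluence is capped at 97% of constraint/prescription — the
  optimizer's hard OAR constraint, with a typical few-percent planning
  buffer so the nominal plan clears the limit;
* the profile is then smoothed with the Gaussian penumbra (default
  σ = 4 mm).

Plans are normalized once, at nominal geometry, so that median CTV dose ×
1.1 equals the per-fraction prescription (plans are "optimized" at the
constant clinical RBE).  Fluence maps, SOBP weights and the normalization
factor are then frozen: error scenarios re-run the full ray tracing with a
shifted isocenter and scaled ranges but must not re-fit or renormalize
anything, because a systematic error changes the delivered dose.

Without the set-up margin and the OAR cap, forward plans leave the
brainstem ~20% below its constraint and none of the breach phenomenology
of clinical robust plans appears; with them, nominal plans sit just below
constraint and errors or RBE push them over, which is the regime the
analysis is about.  These two rules are the package's design
interpretation of "robustly optimized" and were fixed before the study
defaults were frozen.

## Physical robustness

Twelve systematic scenarios: the cross of ±3 mm single-axis isocenter
shifts (x, y, z) with ±3.5% water-equivalent range scaling (the pairing
into 12 is forced by the scenario count; modulation scales with range).
Each scenario is recomputed, not interpolated.  Worst case is per metric:
the scenario giving the highest OAR value or the lowest CTV D95.  The
reported worst value is taken over scenarios ∪ {nominal}: the error-free
realization is guaranteed realizable, and for an organ sitting on the dose
plateau (the chiasm inside the CTV) every error slightly *lowers* the
metric, so a scenarios-only maximum could report a "worst case" better
than no error at all.  Per-scenario values and DVH min/max bands remain
scenarios-only.

## Variable RBE

The McNamara phenomenological model with the published fit constants
(p0 = 0.99064, p1 = 0.35605, p2 = 1.1012, p3 = −0.0038703):

    RBE_max = p0 + p1·LET_d/(α/β)_x
    RBE_min = p2 + p3·√((α/β)_x)·LET_d          (floored at 0)
    RBE = [√((α/β)_x² + 4·D_p·(α/β)_x·RBE_max + 4·D_p²·RBE_min²) − (α/β)_x] / (2·D_p)

with the analytic limit RBE_max at D_p = 0.  D_p is the *physical* dose
per fraction, taken as voxel total dose / n_fractions (uniform
fractionation assumed).  LET_d comes from the per-field dose-weighted
accumulation with the 0.5%-of-plan-maximum dose threshold; voxels below
the threshold fall back to RBE = 1.1.  Matched (α/β)_x for tumor and
normal tissue is the default (2, 3, 4 Gy analyses), with a per-structure
override map for the tumor-(α/β)_x = 10 Gy coverage analysis.  Whether
the original analysis floored RBE_min or capped LET is not documented;
flooring at zero is this package's documented choice (it only matters
above ~200 keV·√Gy/µm, far outside the supported range).

Fraction-scheme constraint transfer uses the BED-isoeffect relation
D1 = D2·(1 + d2/(α/β))/(1 + d1/(α/β)).  The shipped EQD2-style table
(brainstem 54, chiasm/nerves 55 Gy(RBE) at 2 Gy(RBE)/fx, (α/β)_x = 2) is
an editable stand-in for consensus constraint sets and is converted at
load time to the local fractionation.

## Photon comparator

A single coplanar arc of equispaced conformal beams (default 72; the
study config uses 36, which changes cohort means by well under a
percent): exponential attenuation at 0.05 cm^−1 (6 MV-like), aperture
conformal to the PTV (CTV + 3 mm) with the field edge 1.5σ outside it,
σ = 5 mm penumbra, plus a broad out-of-field component (12% of the
fluence smoothed with a 25 mm kernel) representing head leakage and
patient scatter.  Normalized to median PTV dose = prescription.  It is a
*surrogate* producing the characteristic rotational low-dose bath — it
performs no inverse planning and cannot reproduce physician trade-offs,
so modality comparisons computed from it must be labelled surrogate-based.

## Metrics

Cumulative DVHs with 0.05 Gy bins and linear interpolation; dose-at-volume
takes the hot end of tied-dose runs (hottest-volume convention), so all
DVH statistics agree with direct voxel-sorting order statistics to within
one bin width.  D95 coverage is reported as % of prescription.  Constraint
evaluation counts a value *at* the limit as a breach ("at or above").
Brain-minus-CTV is a mask set-difference at evaluation time.  Missing
structures skip their rules with an explicit warning.

## Problem sizes and determinism

The default study conditions — 10 phantoms at 3 mm voxels, 13 dose
computations per proton plan (nominal + 12 scenarios), 36-beam photon
arcs — run in a few minutes on one CPU; single-phantom unit tests use
4 mm voxels.  All randomness (phantom jitter) flows from explicit seeds;
plans, scenarios and metrics are deterministic given a phantom, so
repeated runs produce bit-identical tables.

## What the synthetic cohort can and cannot show

The phantoms reproduce the *topology* of the clinical problem (target-OAR
abutment and overlap, beam-stopping geometry) but not patient anatomy:
uniform water density, idealized shapes, no heterogeneities, no
delineation uncertainty, a forward plan surrogate instead of true inverse
optimization.  Passing tests therefore demonstrate the internal
consistency of the models and the *directional* claims — variable-RBE
hotspots exceed physical worst-case effects at the brainstem, both exceed
nominal, effects grow as (α/β)_x falls, and protons spare the normal
brain relative to a rotational photon bath — not the patient-specific
magnitudes of any clinical cohort.  Absolute breach volumes here are
smaller than clinically reported ones, chiefly because synthetic plans
are more conformal and targets more regular than reality.

## Known limitations

* No nuclear halo, spot-by-spot scanning structure, heterogeneity
  corrections or Monte Carlo transport; no range shifters.
* The 4-field star angles are a stand-in, not a clinical beam protocol.
* LET_d is analytic and track-model based; its absolute scale is
  model-dependent (the cap and the power-law constants set the end-of-range
  values).
* The photon surrogate has no MLC model or OAR-driven optimization.
* Scenario analysis covers systematic errors only — no random per-fraction
  errors, no intra-fraction motion, no fractionation interplay.
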