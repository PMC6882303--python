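"""Analytical proton SOBP dose engine and depth-dependent LET_d model.

Depth-dose model
----------------
Pristine Bragg curves come from numeric integration of the power-law
range-energy relation R = alpha * E^p (alpha = 0.0022 cm/MeV^p, p = 1.77),
which gives the track stopping power S(r) = E(r) / (p r) at residual range
r, averaged over a Gaussian range-straggling spectrum of width
sigma = 1.2% of range:

    dose(z)   ~ < S(R' - z) >_{R' ~ N(R0, sigma)}
    LET_d(z)  = < S^2 > / < S >        (dose-averaged track LET)

The r^(1/p - 1) singularity of S (and the r^(2/p - 2) one of S^2) is
absorbed analytically by power substitutions so the quadrature integrand is
smooth.  The nominal range R0 is calibrated so the dose maximum sits exactly
at the requested range.  LET_d is capped at 20 keV/um to keep the falloff
tail finite; the cap is only reached distal to the Bragg peak.

Spread-out Bragg peaks are non-negative least-squares stacks of pulled-back
pristine peaks.  Pullback is modelled as degradation of a fixed-energy beam,
so every constituent peak keeps the absolute straggling width of the
distal-most peak — this is what makes a ~2 sigma pullback spacing give a
flat plateau.

Ray geometry
------------
Dose is deposited along straight parallel rays per field.  Water-equivalent
depth is the cumulative density-weighted path length.  The lateral fluence
profile is the target aperture (CTV projection plus margin) convolved with a
Gaussian penumbra.  Plans are normalized so that median CTV dose times the
constant clinical RBE of 1.1 equals the per-fraction prescription; the
normalization factor is frozen at its nominal value so that error scenarios
change the delivered dose rather than being renormalized away.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage
from scipy.optimize import nnls
from scipy.stats import norm

from .grids import DOSE_PER_FX, LET_UNIT, ScalarGrid
from .phantom import Phantom, Prescription

# power-law range-energy relation for protons in water
ALPHA_CM_MEV = 0.0022
P_EXPONENT = 1.77
STRAGGLE_FRAC = 0.012      # sigma of the Gaussian range spectrum / range
LET_CAP_KEV_UM = 20.0
MEV_CM_TO_KEV_UM = 0.1
_NSIG = 5.0                # quadrature window half-width in straggle sigmas
_NQ = 96                   # quadrature points per depth

RANGE_MIN_CM = 1.0
RANGE_MAX_CM = 35.0

#: distal/proximal SOBP auto-fit margins: fraction of range plus absolute cm,
#: mirroring the clinical 3.5% + 1 mm range-uncertainty recipe
RANGE_MARGIN = (0.035, 0.1)

LET_DOSE_THRESHOLD = 0.005  # of plan maximum dose; below it LET_d is not reported


class PlanningError(ValueError):
    """Raised when a beam cannot produce a valid plan on the phantom."""


# ---------------------------------------------------------------------------
# pristine Bragg curves
# ---------------------------------------------------------------------------

def _raw_curves(R0, z, sigma):
    """Straggle-averaged <S> (arb) and LET_d (keV/um) at depths z."""
    b = 1.0 / P_EXPONENT
    c = b * ALPHA_CM_MEV ** (-b)
    rlo = np.maximum(R0 - _NSIG * sigma - z, 0.0)
    rhi = np.maximum(R0 + _NSIG * sigma - z, 0.0)
    frac = (np.arange(_NQ) + 0.5) / _NQ

    def integral(expo, const):
        lo = rlo ** expo
        hi = rhi ** expo
        x = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
        r = x ** (1.0 / expo)
        phi = norm.pdf(z[:, None] + r, R0, sigma)
        return const * phi.mean(axis=1) * (hi - lo)

    d = integral(b, c / b)
    s2 = integral(2 * b - 1, c * c / (2 * b - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        letd = np.where(d > 1e-9, s2 / np.maximum(d, 1e-300), 0.0)
    return d, np.minimum(letd * MEV_CM_TO_KEV_UM, LET_CAP_KEV_UM)


@dataclass(frozen=True)
class PristineCurve:
    """Normalized depth-dose and LET_d of one pristine Bragg peak."""

    range_cm: float
    depth_cm: np.ndarray
    dose: np.ndarray          # peak-normalized
    let_kev_um: np.ndarray

    def dose_at(self, depth_cm):
        return np.interp(depth_cm, self.depth_cm, self.dose, right=0.0)

    def let_at(self, depth_cm):
        return np.interp(depth_cm, self.depth_cm, self.let_kev_um)


def pristine_curve(range_cm: float, depth_step_mm: float = 0.5,
                   sigma_cm: float | None = None,
                   max_depth_cm: float | None = None) -> PristineCurve:
    """Pristine Bragg curve with its dose maximum at ``range_cm``.

    ``sigma_cm`` overrides the default straggling width (1.2% of range);
    SOBP construction passes the distal peak's width for pulled-back peaks.
    """
    if not RANGE_MIN_CM <= range_cm <= RANGE_MAX_CM:
        raise ValueError(
            f"range {range_cm} cm outside supported "
            f"[{RANGE_MIN_CM}, {RANGE_MAX_CM}] cm interval")
    if depth_step_mm <= 0:
        raise ValueError("depth_step_mm must be positive")
    sigma = STRAGGLE_FRAC * range_cm if sigma_cm is None else sigma_cm
    zmax = max_depth_cm or (range_cm + _NSIG * sigma + 0.5)
    z = np.arange(0.0, zmax, depth_step_mm / 10.0)
    R0 = range_cm
    for _ in range(3):  # place argmax(dose) at the requested range
        d, _ = _raw_curves(R0, z, sigma)
        R0 += range_cm - z[d.argmax()]
    d, let = _raw_curves(R0, z, sigma)
    return PristineCurve(range_cm, z, d / d.max(), let)


# ---------------------------------------------------------------------------
# spread-out Bragg peaks
# ---------------------------------------------------------------------------

#: plateau evaluation margins (cm) clear of the proximal shoulder and the
#: distal falloff
_PLATEAU_PROX_CM = 0.2
_PLATEAU_DIST_CM = 0.3
SOBP_FLATNESS_TOL = 0.02


def default_n_peaks(range_cm: float, modulation_cm: float) -> int:
    """Peak count giving a pullback spacing of about twice the straggling
    width of the distal peak."""
    if modulation_cm <= 0:
        return 1
    spacing = 2.0 * STRAGGLE_FRAC * range_cm
    return max(2, int(np.ceil(modulation_cm / spacing)) + 1)


def sobp_weights(range_cm: float, modulation_cm: float,
                 n_peaks: int | None = None, depth_step_mm: float = 0.2,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative pullback weights for a flat SOBP plateau.

    Returns ``(weights, peak_ranges_cm)``, distal peak first.  Raises
    :class:`PlanningError` if the composed plateau deviates from its mean by
    more than 2% — infeasible flatness is reported, never silently accepted.
    """
    if modulation_cm < 0 or modulation_cm >= range_cm:
        raise ValueError("need range_cm > modulation_cm >= 0")
    if n_peaks is None:
        n_peaks = default_n_peaks(range_cm, modulation_cm)
    if modulation_cm == 0:
        if n_peaks != 1:
            raise ValueError("modulation 0 is a single pristine peak")
        return np.array([1.0]), np.array([range_cm])
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2 for a nonzero modulation")

    sigma = STRAGGLE_FRAC * range_cm
    ranges = range_cm - np.linspace(0.0, modulation_cm, n_peaks)
    zmax = range_cm + _NSIG * sigma + 0.5
    z = np.arange(0.0, zmax, depth_step_mm / 10.0)
    A = np.column_stack([
        pristine_curve(r, depth_step_mm, sigma_cm=sigma, max_depth_cm=zmax)
        .dose_at(z) for r in ranges])
    lo = range_cm - modulation_cm + _PLATEAU_PROX_CM
    hi = range_cm - _PLATEAU_DIST_CM
    sel = (z >= lo) & (z <= hi)
    if sel.sum() < n_peaks:
        sel = (z >= range_cm - modulation_cm) & (z <= range_cm)
    w, _ = nnls(A[sel], np.ones(int(sel.sum())))
    plateau = (A @ w)[sel]
    dev = np.abs(plateau - plateau.mean()).max() / plateau.mean()
    if dev > SOBP_FLATNESS_TOL:
        raise PlanningError(
            f"SOBP plateau deviation {100 * dev:.2f}% exceeds "
            f"{100 * SOBP_FLATNESS_TOL:.0f}% (range {range_cm} cm, "
            f"modulation {modulation_cm} cm, {n_peaks} peaks)")
    return w, ranges


# ---------------------------------------------------------------------------
# beams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamSpec:
    """One proton field.

    Angles follow a beam's-eye convention on the phantom axes
    (x left-right, y anterior-posterior with +y posterior, z superior):
    ``gantry_angle`` is the source azimuth in the axial plane (0 deg =
    source anterior, positive toward the patient's left), ``couch_angle``
    elevates the source toward superior.  ``sobp_range_cm`` and
    ``modulation_cm`` may be left ``None`` for auto-fit to the CTV
    projection plus margins.
    """

    gantry_angle: float
    couch_angle: float = 0.0
    isocenter_mm: tuple[float, float, float] | None = None
    sobp_range_cm: float | None = None
    modulation_cm: float | None = None
    field_weight: float = 1.0
    lateral_sigma_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.field_weight < 0:
            raise ValueError("field_weight must be >= 0")
        if self.sobp_range_cm is not None and self.modulation_cm is not None:
            if not self.sobp_range_cm > self.modulation_cm >= 0:
                raise ValueError("need sobp_range_cm > modulation_cm >= 0")

    def direction(self) -> np.ndarray:
        """Unit propagation vector (source toward isocenter)."""
        th = np.deg2rad(self.gantry_angle)
        ph = np.deg2rad(self.couch_angle)
        source = np.array([np.sin(th) * np.cos(ph),
                           -np.cos(th) * np.cos(ph),
                           np.sin(ph)])
        return -source


def default_star_beams(lateral_sigma_mm: float = 4.0) -> list[BeamSpec]:
    """4-field star: two superior-lateral fields and two
    inferior-anterior-lateral fields roughly tangential to the optic
    apparatus.  A documented stand-in arrangement for base-of-skull plans."""
    return [
        BeamSpec(90.0, 40.0, lateral_sigma_mm=lateral_sigma_mm),
        BeamSpec(-90.0, 40.0, lateral_sigma_mm=lateral_sigma_mm),
        BeamSpec(45.0, -20.0, lateral_sigma_mm=lateral_sigma_mm),
        BeamSpec(-45.0, -20.0, lateral_sigma_mm=lateral_sigma_mm),
    ]


# ---------------------------------------------------------------------------
# beam-frame ray tracing
# ---------------------------------------------------------------------------

def _beam_basis(u: np.ndarray):
    u = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return u, v, w


class _BeamFrame:
    """Regular grid aligned with one beam: axis 0 is depth along the beam.

    The frame is anchored to the beam (its origin is expressed relative to
    the isocenter), so translating the isocenter moves the frame — and any
    frozen fluence map — rigidly with respect to the patient, which is
    exactly the systematic set-up error semantics.

    Provides water-equivalent depth (cumulative density-weighted path), the
    target aperture fluence, and resampling back to the phantom raster.
    """

    def __init__(self, phantom: Phantom, direction: np.ndarray,
                 iso_mm: np.ndarray, step_mm: float,
                 extent: tuple[np.ndarray, np.ndarray] | None = None):
        self.phantom = phantom
        self.step_mm = step_mm
        self.u, self.v, self.w = _beam_basis(direction)
        self.iso = np.asarray(iso_mm, float)

        shape = np.array(phantom.grid_shape)
        voxel = np.array(phantom.voxel_size)
        if extent is None:
            # beam-frame extents covering the patient bbox at nominal iso,
            # padded by 1 cm so shifted anatomy stays inside the frame
            half = (shape - 1) / 2.0 * voxel
            corners = np.array([[sx, sy, sz] for sx in (-half[0], half[0])
                                for sy in (-half[1], half[1])
                                for sz in (-half[2], half[2])]) - self.iso
            basis = np.stack([self.u, self.v, self.w])
            proj = corners @ basis.T
            lo, hi = proj.min(axis=0) - 10.0, proj.max(axis=0) + 10.0
        else:
            lo, hi = extent
        self.extent = (lo, hi)
        self.origin = lo
        self.n = np.maximum(((hi - lo) / step_mm).astype(int) + 2, 2)
        self._axes = [self.origin[k] + step_mm * np.arange(self.n[k])
                      for k in range(3)]
        self._voxel = voxel
        self._shape = shape

    def _world_to_index(self, pts_world):
        return (pts_world / self._voxel + (self._shape - 1) / 2.0)

    def sample(self, volume: np.ndarray, order: int = 1) -> np.ndarray:
        """Sample a phantom-raster volume onto the beam frame."""
        S, A, B = np.meshgrid(*self._axes, indexing="ij", sparse=False)
        pts = (self.iso[None, :]
               + S.reshape(-1, 1) * self.u[None, :]
               + A.reshape(-1, 1) * self.v[None, :]
               + B.reshape(-1, 1) * self.w[None, :])
        idx = self._world_to_index(pts).T
        # grid-constant: the half-voxel shell at the patient surface blends
        # toward zero instead of being dropped outright
        out = ndimage.map_coordinates(volume, idx, order=order, cval=0.0,
                                      mode="grid-constant", prefilter=False)
        return out.reshape(tuple(self.n))

    def wed_cm(self, density_rot: np.ndarray) -> np.ndarray:
        """Water-equivalent depth (cm) by midpoint cumulative sum along the
        beam axis."""
        cs = np.cumsum(density_rot, axis=0)
        return (cs - 0.5 * density_rot) * (self.step_mm / 10.0)

    def fluence(self, target_rot: np.ndarray, margin_mm: float,
                sigma_mm: float,
                caps: list[tuple[np.ndarray, float]] | None = None,
                ) -> np.ndarray:
        """Lateral fluence: target aperture dilated by ``margin_mm``,
        Gaussian-smoothed with the penumbra sigma.

        ``caps`` lists (organ shadow in the beam frame, relative fluence
        cap); the cap applies in the margin annulus where the organ shadow
        does not overlap the raw target shadow — the fluence-limiting that
        inverse planning with hard OAR constraints performs.
        """
        target_shadow = target_rot.any(axis=0)
        aperture = target_shadow
        if margin_mm > 0:
            dist = ndimage.distance_transform_edt(
                ~aperture, sampling=self.step_mm)
            aperture = dist <= margin_mm
        base = aperture.astype(np.float64)
        for organ_rot, ratio in caps or ():
            annulus = organ_rot.any(axis=0) & ~target_shadow
            base[annulus] = np.minimum(base[annulus], ratio)
        return ndimage.gaussian_filter(base, sigma_mm / self.step_mm)

    def to_phantom(self, field_rot: np.ndarray) -> np.ndarray:
        """Resample a beam-frame field back onto the phantom raster."""
        xs = self.phantom.voxel_centers_mm()
        X, Y, Z = np.meshgrid(*xs, indexing="ij", sparse=False)
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1) - self.iso
        basis = np.stack([self.u, self.v, self.w])
        sab = pts @ basis.T
        idx = ((sab - self.origin[None, :]) / self.step_mm).T
        out = ndimage.map_coordinates(field_rot, idx, order=1, cval=0.0,
                                      mode="grid-constant", prefilter=False)
        return out.reshape(self.phantom.grid_shape)


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

#: aperture margin in units of the penumbra sigma; 1.5 sigma puts the
#: target edge at the ~93% fluence level (clinical block-margin recipe)
APERTURE_MARGIN_SIGMA = 1.5

#: extra lateral aperture margin (mm) emulating what robust optimization
#: against +/-3 mm set-up errors does to a plan: it spreads the delivered
#: fluence so the target stays covered under a 3 mm shift
SETUP_MARGIN_MM = 3.0

#: planning buffer below hard OAR limits: the fluence cap over an organ
#: shadow targets 97% of the constraint, the way an optimizer objective is
#: set slightly below a hard constraint so the nominal plan clears it
OAR_CAP_BUFFER = 0.97


@dataclass
class FieldModel:
    """Fitted state of one field, frozen at nominal geometry: SOBP pullback
    stack, beam-frame extents and the lateral fluence map (the delivered
    aperture — error scenarios must not re-fit it)."""

    beam: BeamSpec
    iso_mm: np.ndarray
    range_cm: float
    modulation_cm: float
    weights: np.ndarray
    peak_ranges_cm: np.ndarray
    frame_extent: tuple[np.ndarray, np.ndarray] | None = None
    fluence_map: np.ndarray | None = None

    def depth_curves(self, range_scale: float = 1.0, step_mm: float = 0.5):
        """Composite SOBP dose and LET_d depth curves.

        ``range_scale`` multiplies every pullback peak's range and the
        straggling width (range errors scale the whole depth structure).
        Weights stay frozen.
        """
        ranges = self.peak_ranges_cm * range_scale
        sigma = STRAGGLE_FRAC * self.range_cm * range_scale
        zmax = ranges.max() + _NSIG * sigma + 0.5
        z = np.arange(0.0, zmax, step_mm / 10.0)
        dose = np.zeros_like(z)
        dose_let = np.zeros_like(z)
        for wgt, r in zip(self.weights, ranges):
            if wgt == 0:
                continue
            c = pristine_curve(r, step_mm, sigma_cm=sigma, max_depth_cm=zmax)
            d = wgt * c.dose_at(z)
            dose += d
            dose_let += d * c.let_at(z)
        with np.errstate(invalid="ignore", divide="ignore"):
            let = np.where(dose > 1e-12, dose_let / np.maximum(dose, 1e-300),
                           0.0)
        peak = dose.max()
        return z, dose / peak, let


@dataclass
class PlanDose:
    """One evaluated (nominal or scenario) plan state."""

    dose: ScalarGrid                 # physical Gy per fraction
    field_dose: list[np.ndarray]
    field_let: list[np.ndarray]
    letd: ScalarGrid | None = None   # keV/um, thresholded
    let_excluded: np.ndarray | None = None


def compute_plan_letd(field_dose: list[np.ndarray],
                      field_let: list[np.ndarray],
                      voxel_size: tuple[float, float, float],
                      threshold: float = LET_DOSE_THRESHOLD,
                      ) -> tuple[ScalarGrid, np.ndarray]:
    """Dose-averaged LET over field contributions.

    voxel LET_d = sum_i d_i L_i / sum_i d_i.  Voxels whose total dose falls
    below ``threshold`` of the plan maximum are set to 0 and returned in the
    excluded mask.
    """
    shapes = {d.shape for d in field_dose} | {l.shape for l in field_let}
    if len(shapes) != 1:
        raise ValueError("mismatched rasters among field contributions")
    total = np.sum(field_dose, axis=0)
    num = np.sum([d * l for d, l in zip(field_dose, field_let)], axis=0)
    excluded = total < threshold * total.max()
    with np.errstate(invalid="ignore", divide="ignore"):
        letd = np.where(~excluded, num / np.maximum(total, 1e-300), 0.0)
    grid = ScalarGrid(letd, LET_UNIT, voxel_size,
                      {"dose_threshold": threshold})
    return grid, excluded


class ProtonPlan:
    """A forward-computed multi-field SOBP plan on one phantom.

    Field ranges/modulations are auto-fitted to the CTV projection at
    nominal geometry, SOBP weights solved once, and the plan normalization
    (median CTV dose x 1.1 = per-fraction prescription) frozen.  Error
    scenarios re-run the full ray tracing with shifted isocenter and scaled
    ranges under the frozen normalization.
    """

    def __init__(self, phantom: Phantom, beams: list[BeamSpec] | None = None,
                 prescription: Prescription | None = None,
                 step_mm: float | None = None,
                 oar_limits: dict[str, float] | None = None):
        if beams is not None and len(beams) == 0:
            raise PlanningError("beams must be non-empty")
        self.phantom = phantom
        self.beams = beams if beams is not None else default_star_beams()
        self.prescription = prescription or phantom.prescription
        self.step_mm = step_mm or float(min(phantom.voxel_size))
        self._ctv = phantom.structures["CTV"]
        self._default_iso = phantom.centroid_mm("CTV")
        if oar_limits is None:
            from .metrics import CONSTRAINTS, KIND_DVH
            cs = CONSTRAINTS[phantom.patient_class]
            oar_limits = {r.structure: r.limit_gy_rbe for r in cs.rules
                          if r.kind == KIND_DVH
                          and r.structure in phantom.structures}
        self.oar_limits = oar_limits
        self.fields: list[FieldModel] = []
        self._fit()
        nominal = self._raw_compute()
        med = np.median(nominal.dose.values[self._ctv])
        if med <= 0:
            raise PlanningError("plan delivers no dose to the CTV")
        self.norm_factor = self.prescription.per_fraction_gy_rbe / (1.1 * med)
        self._nominal: PlanDose | None = None

    def _frame(self, fm_or_beam, iso: np.ndarray,
               shift_mm=(0.0, 0.0, 0.0), extent=None) -> _BeamFrame:
        beam = fm_or_beam.beam if isinstance(fm_or_beam, FieldModel) else fm_or_beam
        return _BeamFrame(self.phantom, beam.direction(),
                          iso + np.asarray(shift_mm, float), self.step_mm,
                          extent=extent)

    def _fit(self) -> None:
        ctv_f = self._ctv.astype(np.float64)
        for beam in self.beams:
            iso = (np.asarray(beam.isocenter_mm, float)
                   if beam.isocenter_mm is not None else self._default_iso)
            frame = self._frame(beam, iso)
            ctv_rot = frame.sample(ctv_f) > 0.5
            if not ctv_rot.any():
                raise PlanningError(
                    f"beam (gantry {beam.gantry_angle}, couch "
                    f"{beam.couch_angle}) misses the CTV entirely")
            if beam.sobp_range_cm is not None:
                rng_cm = beam.sobp_range_cm
                mod_cm = beam.modulation_cm or 0.0
            else:
                dens_rot = frame.sample(self.phantom.density)
                wed = frame.wed_cm(dens_rot)[ctv_rot]
                frac, absol = RANGE_MARGIN
                rng_cm = wed.max() * (1.0 + frac) + absol
                prox = max(wed.min() * (1.0 - frac) - absol, 0.05)
                mod_cm = rng_cm - prox
            weights, ranges = sobp_weights(rng_cm, mod_cm)
            caps = []
            for name, limit in self.oar_limits.items():
                ratio = min(1.0, OAR_CAP_BUFFER * limit
                            / self.prescription.total_gy_rbe)
                organ_rot = frame.sample(
                    self.phantom.structures[name].astype(np.float64)) > 0.5
                caps.append((organ_rot, ratio))
            fluence = frame.fluence(
                ctv_rot,
                APERTURE_MARGIN_SIGMA * beam.lateral_sigma_mm
                + SETUP_MARGIN_MM,
                beam.lateral_sigma_mm, caps=caps)
            self.fields.append(FieldModel(beam, iso, rng_cm, mod_cm,
                                          weights, ranges,
                                          frame_extent=frame.extent,
                                          fluence_map=fluence))

    def _raw_compute(self, shift_mm=(0.0, 0.0, 0.0), range_scale: float = 1.0,
                     with_let: bool = True) -> PlanDose:
        ph = self.phantom
        inside = ph.density > 0
        field_dose, field_let = [], []
        for fm in self.fields:
            frame = self._frame(fm, fm.iso_mm, shift_mm,
                                extent=fm.frame_extent)
            dens_rot = frame.sample(ph.density)
            wed = frame.wed_cm(dens_rot)
            fluence = fm.fluence_map
            z, dcurve, lcurve = fm.depth_curves(range_scale)
            dose_rot = fluence[None, :, :] * np.interp(
                wed, z, dcurve, right=0.0)
            d = frame.to_phantom(dose_rot) * fm.beam.field_weight
            d[~inside] = 0.0  # no absorbed dose outside the patient
            field_dose.append(d)
            if with_let:
                let_rot = np.interp(wed, z, lcurve)
                l = frame.to_phantom(let_rot)
                l[~inside] = 0.0
                field_let.append(l)
        total = np.sum(field_dose, axis=0)
        dose = ScalarGrid(total, DOSE_PER_FX, ph.voxel_size,
                          {"modality": "proton",
                           "shift_mm": list(map(float, shift_mm)),
                           "range_scale": float(range_scale)})
        return PlanDose(dose, field_dose, field_let)

    def compute(self, shift_mm=(0.0, 0.0, 0.0), range_scale: float = 1.0,
                with_let: bool = True) -> PlanDose:
        """Evaluate the plan, optionally under a systematic error."""
        pd = self._raw_compute(shift_mm, range_scale, with_let)
        pd.dose = pd.dose.scaled(self.norm_factor)
        pd.field_dose = [d * self.norm_factor for d in pd.field_dose]
        if with_let:
            pd.letd, pd.let_excluded = compute_plan_letd(
                pd.field_dose, pd.field_let, self.phantom.voxel_size)
        return pd

    def nominal(self) -> PlanDose:
        """Nominal (error-free) plan state, cached."""
        if self._nominal is None:
            self._nominal = self.compute()
        return self._nominal

    def to_dict(self) -> dict:
        """JSON-serializable fitted plan parameters (for re-entrancy)."""
        return {
            "prescription": {"total_gy_rbe": self.prescription.total_gy_rbe,
                             "n_fractions": self.prescription.n_fractions},
            "norm_factor": self.norm_factor,
            "step_mm": self.step_mm,
            "fields": [{
                "gantry_angle": fm.beam.gantry_angle,
                "couch_angle": fm.beam.couch_angle,
                "lateral_sigma_mm": fm.beam.lateral_sigma_mm,
                "field_weight": fm.beam.field_weight,
                "isocenter_mm": list(map(float, fm.iso_mm)),
                "range_cm": fm.range_cm,
                "modulation_cm": fm.modulation_cm,
                "weights": list(map(float, fm.weights)),
                "peak_ranges_cm": list(map(float, fm.peak_ranges_cm)),
            } for fm in self.fields],
        }


def compute_plan_dose(phantom: Phantom, beams: list[BeamSpec] | None = None,
                      prescription: Prescription | None = None,
                      ) -> ScalarGrid:
    """Nominal per-fraction physical dose of a multi-field SOBP plan."""
    return ProtonPlan(phantom, beams, prescription).nominal().dose
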