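"""Synthetic base-of-skull voxel phantoms.

The study geometry these phantoms emulate is a centrally located clinical
target volume (CTV) at the skull base that abuts the brainstem posteriorly
and overlaps most of the small optic chiasm, with the paired optic nerves
running anterolaterally from the chiasm — the anatomy that makes
base-of-skull sarcoma, chordoma and pediatric craniopharyngioma plans hard:
there is no room between target and critical organ.

Structures are generated as unions of simple analytic shapes (ellipsoids,
elliptic cylinders, capsule segments), rasterized on a regular voxel grid by
the voxel-center-inside rule.  Density is water (1.0) inside the external
contour and 0 outside.

Coordinate convention: 0-based voxel indices; world coordinates in mm at
voxel centers with the grid centered on the origin; axes are
(x: left-right, y: anterior-posterior with +y posterior,
z: inferior-superior with +z superior).

Two sizes are quantization-calibrated rather than taken from the analytic
shape: the CTV volume (scaled until the rasterized volume matches the
requested cm^3 to within one voxel) and the chiasm position (moved along the
anterior axis until the requested CTV-overlap fraction is met to within one
voxel).  Sub-voxel seeded jitter of shape centers breaks raster symmetry so
single-voxel resolution of both calibrations is attainable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

REQUIRED_STRUCTURES = (
    "CTV", "brainstem", "optic_chiasm", "optic_nerve_L", "optic_nerve_R",
    "brain", "external",
)

ADULT = "adult"
PEDIATRIC = "pediatric"


@dataclass(frozen=True)
class Prescription:
    """Total prescribed RBE-weighted dose and its fractionation."""

    total_gy_rbe: float
    n_fractions: int

    @property
    def per_fraction_gy_rbe(self) -> float:
        return self.total_gy_rbe / self.n_fractions


#: Clinical prescription presets: adult chondrosarcoma/chordoma scheme and
#: the pediatric craniopharyngioma scheme.
PRESCRIPTIONS = {
    ADULT: Prescription(65.13, 39),
    PEDIATRIC: Prescription(50.4, 28),
}


class GeometryError(ValueError):
    """Raised when a requested phantom geometry cannot be realized."""


@dataclass(frozen=True)
class PhantomSpec:
    """Reproducible recipe for one synthetic phantom.

    Identical spec (including ``random_seed``) always yields a bit-identical
    phantom.

    Parameters
    ----------
    random_seed : int
        Seeds the sub-voxel raster jitter.
    patient_class : str
        ``"adult"`` or ``"pediatric"``; selects head scale and prescription.
    target_volume_cm3 : float
        Rasterized CTV volume, met to within one voxel volume.
    chiasm_overlap_fraction : float
        Fraction of the optic chiasm volume lying inside the CTV, in [0, 1];
        met to within one voxel.
    brainstem_gap_mm : float
        CTV-to-brainstem margin; 0 means abutting (the default, matching the
        base-of-skull situation).
    voxel_mm : float
        Isotropic voxel edge length.
    """

    random_seed: int = 0
    patient_class: str = ADULT
    target_volume_cm3: float = 25.0
    chiasm_overlap_fraction: float = 0.7
    brainstem_gap_mm: float = 0.0
    voxel_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.patient_class not in (ADULT, PEDIATRIC):
            raise ValueError(f"unknown patient class {self.patient_class!r}")
        if self.target_volume_cm3 <= 0:
            raise ValueError("target_volume_cm3 must be positive")
        if not 0.0 <= self.chiasm_overlap_fraction <= 1.0:
            raise ValueError("chiasm_overlap_fraction must be in [0, 1]")
        if self.brainstem_gap_mm < 0:
            raise ValueError("brainstem_gap_mm must be >= 0")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")


@dataclass
class Phantom:
    """Voxel phantom: density grid plus named boolean structure masks."""

    voxel_size: tuple[float, float, float]
    density: np.ndarray
    structures: dict[str, np.ndarray]
    patient_class: str

    def __post_init__(self) -> None:
        for name in REQUIRED_STRUCTURES:
            if name not in self.structures:
                raise ValueError(f"missing required structure {name!r}")
        for name, mask in self.structures.items():
            if mask.shape != self.density.shape:
                raise ValueError(f"mask {name!r} shape differs from grid")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.density.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    @property
    def prescription(self) -> Prescription:
        return PRESCRIPTIONS[self.patient_class]

    def structure_volume_cm3(self, name: str) -> float:
        """Structure volume: voxel count times voxel volume, exactly."""
        return int(self.structures[name].sum()) * self.voxel_volume_cm3

    def mask(self, name: str) -> np.ndarray:
        if name == "brain-CTV":
            return self.structures["brain"] & ~self.structures["CTV"]
        return self.structures[name]

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers along each axis."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.grid_shape, self.voxel_size)
        )

    def centroid_mm(self, name: str) -> np.ndarray:
        xs = self.voxel_centers_mm()
        idx = np.nonzero(self.mask(name))
        return np.array([xs[a][idx[a]].mean() for a in range(3)])


# ---------------------------------------------------------------------------
# analytic shape rasterization
# ---------------------------------------------------------------------------

def _world_grids(shape, voxel):
    axes = [(np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(grids, center, semi):
    X, Y, Z = grids
    return (((X - center[0]) / semi[0]) ** 2
            + ((Y - center[1]) / semi[1]) ** 2
            + ((Z - center[2]) / semi[2]) ** 2) <= 1.0


def _elliptic_cylinder_z(grids, center, semi_xy, half_height):
    X, Y, Z = grids
    return ((((X - center[0]) / semi_xy[0]) ** 2
             + ((Y - center[1]) / semi_xy[1]) ** 2) <= 1.0) \
        & (np.abs(Z - center[2]) <= half_height)


def _capsule(grids, p0, p1, radius):
    """Tube of given radius around the segment p0-p1 (both ends rounded)."""
    X, Y, Z = np.broadcast_arrays(*grids)
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = float(d @ d)
    px, py, pz = X - p0[0], Y - p0[1], Z - p0[2]
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0)
    dx = px - t * d[0]
    dy = py - t * d[1]
    dz = pz - t * d[2]
    return dx * dx + dy * dy + dz * dz <= radius * radius


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _geometry_template(patient_class: str) -> dict:
    """Base geometry in mm.  Pediatric heads are scaled down ~12%."""
    s = 1.0 if patient_class == ADULT else 0.88
    return {
        "head_semi": np.array([80.0, 95.0, 75.0]) * s,
        "brain_semi": np.array([70.0, 82.0, 62.0]) * s,
        "brain_center": np.array([0.0, 0.0, 8.0]) * s,
        "ctv_center": np.array([0.0, 0.0, -15.0]) * s,
        "ctv_aspect": np.array([1.15, 1.0, 0.9]),
        "brainstem_semi_xy": np.array([10.0, 11.0]) * s,
        "brainstem_half_height": 32.0 * s,
        "chiasm_semi": np.array([9.0, 4.0, 3.5]) * s,
        "nerve_radius": 2.2,
        "nerve_length": 30.0 * s,
    }


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize one phantom from its spec.

    Raises
    ------
    GeometryError
        If the structures (plus a 2 cm margin) cannot fit in the grid, or if
        a quantization calibration cannot meet its one-voxel tolerance.
    """
    geo = _geometry_template(spec.patient_class)
    voxel = (spec.voxel_mm,) * 3
    extent = geo["head_semi"] + 20.0  # 2 cm margin around the head
    shape = tuple(int(np.ceil(2 * e / spec.voxel_mm)) for e in extent)
    grids = _world_grids(shape, voxel)
    vox_cm3 = spec.voxel_mm ** 3 / 1000.0

    rng = np.random.default_rng(spec.random_seed)
    # sub-voxel jitter decorrelates shape surfaces from the raster so the
    # volume/overlap bisections below can resolve single voxels
    jit = rng.uniform(-0.35, 0.35, size=(3, 3)) * spec.voxel_mm

    external = _ellipsoid(grids, (0, 0, 0), geo["head_semi"])
    brain = _ellipsoid(grids, geo["brain_center"], geo["brain_semi"]) & external

    # --- CTV: ellipsoid scaled until the rasterized volume matches ----------
    ctv_center = geo["ctv_center"] + jit[0]
    target_n = int(round(spec.target_volume_cm3 / vox_cm3))
    r0 = (spec.target_volume_cm3 * 1000.0 * 3.0
          / (4.0 * np.pi * np.prod(geo["ctv_aspect"]))) ** (1.0 / 3.0)
    if r0 * max(geo["ctv_aspect"]) > min(geo["brain_semi"]) :
        raise GeometryError("target volume too large for this head size")

    def ctv_count(scale):
        return int(_ellipsoid(grids, ctv_center,
                              geo["ctv_aspect"] * r0 * scale).sum())

    lo, hi = 0.5, 1.8
    if not ctv_count(lo) <= target_n <= ctv_count(hi):
        raise GeometryError("target volume outside supported range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ctv_count(mid) < target_n:
            lo = mid
        else:
            hi = mid
    ctv = _ellipsoid(grids, ctv_center, geo["ctv_aspect"] * r0 * hi)
    if abs(int(ctv.sum()) - target_n) > 1:
        raise GeometryError("CTV volume quantization exceeded one voxel")
    ctv &= external

    ctv_semi = geo["ctv_aspect"] * r0 * hi
    ctv_ymax = ctv_center[1] + ctv_semi[1]

    # --- brainstem: vertical elliptic cylinder posterior to the CTV ---------
    bs_center = np.array([
        ctv_center[0] + jit[1][0] * 0.2,
        ctv_ymax + spec.brainstem_gap_mm + geo["brainstem_semi_xy"][1],
        ctv_center[2] + jit[1][2] * 0.2,
    ])
    brainstem = _elliptic_cylinder_z(
        grids, bs_center, geo["brainstem_semi_xy"], geo["brainstem_half_height"]
    ) & external
    if not brainstem.any():
        raise GeometryError("brainstem fell outside the external contour")

    # --- chiasm: small ellipsoid moved anteriorly until the requested -------
    # fraction of its voxels lies inside the CTV
    ch_z = ctv_center[2] + 6.0 + jit[2][2] * 0.3
    ch_x = ctv_center[0] + jit[2][0]

    def chiasm_mask(offset):
        return _ellipsoid(grids, (ch_x, ctv_center[1] - offset, ch_z),
                          geo["chiasm_semi"])

    n_ch = int(chiasm_mask(0.0).sum())
    target_in = int(round(spec.chiasm_overlap_fraction * n_ch))

    def inside(offset):
        return int((chiasm_mask(offset) & ctv).sum())

    lo, hi = 0.0, float(geo["head_semi"][1])  # overlap decreases with offset
    if inside(lo) < target_in:
        raise GeometryError("requested chiasm overlap not achievable")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if inside(mid) >= target_in:
            lo = mid
        else:
            hi = mid
    chiasm = chiasm_mask(lo)
    if abs(int((chiasm & ctv).sum()) - target_in) > 1:
        raise GeometryError("chiasm overlap quantization exceeded one voxel")
    ch_center = np.array([ch_x, ctv_center[1] - lo, ch_z])
    chiasm &= external

    # --- optic nerves: capsules running anterolaterally from the chiasm -----
    ang = np.deg2rad(35.0)
    nerves = {}
    for sign, name in ((-1.0, "optic_nerve_L"), (+1.0, "optic_nerve_R")):
        p0 = ch_center + np.array([sign * geo["chiasm_semi"][0] * 0.6,
                                   -geo["chiasm_semi"][1] * 0.5, 0.0])
        p1 = p0 + geo["nerve_length"] * np.array(
            [sign * np.sin(ang), -np.cos(ang), 0.05])
        nerves[name] = _capsule(grids, p0, p1, geo["nerve_radius"]) & external

    density = np.where(external, 1.0, 0.0)
    structures = {
        "CTV": ctv, "brainstem": brainstem, "optic_chiasm": chiasm,
        "optic_nerve_L": nerves["optic_nerve_L"],
        "optic_nerve_R": nerves["optic_nerve_R"],
        "brain": brain, "external": external,
    }
    return Phantom(voxel, density, structures, spec.patient_class)


def sample_cohort(n: int, base_spec: PhantomSpec, seed: int,
                  adult_fraction: float = 0.6,
                  ) -> list[tuple[PhantomSpec, Phantom]]:
    """Generate ``n`` phantoms with jittered geometry parameters.

    The first ``round(adult_fraction * n)`` phantoms are adult, the rest
    pediatric (pediatric target volumes are scaled to 60% of the adult base
    volume).  Jitter distributions: target volume multiplied by
    U(0.75, 1.25); chiasm overlap fraction shifted by U(-0.15, +0.15) and
    clipped to [0.35, 0.95].  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_adult = int(round(adult_fraction * n))
    out = []
    for i in range(n):
        cls = ADULT if i < n_adult else PEDIATRIC
        vol_scale = 1.0 if cls == ADULT else 0.6
        vol = base_spec.target_volume_cm3 * vol_scale * rng.uniform(0.75, 1.25)
        ovl = float(np.clip(
            base_spec.chiasm_overlap_fraction + rng.uniform(-0.15, 0.15),
            0.35, 0.95))
        spec = replace(base_spec, patient_class=cls,
                       target_volume_cm3=float(vol),
                       chiasm_overlap_fraction=ovl,
                       random_seed=int(rng.integers(0, 2 ** 31 - 1)))
        out.append((spec, build_phantom(spec)))
    return out


# ---------------------------------------------------------------------------
# serialization: NIfTI label volume + density volume + JSON sidecar
# ---------------------------------------------------------------------------

def save_phantom(phantom: Phantom, stem: str | Path) -> None:
    stem = Path(stem)
    affine = np.diag(list(phantom.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(phantom.density.astype(np.float32), affine),
             stem.with_suffix(".density.nii.gz"))
    labels = np.zeros(phantom.grid_shape, dtype=np.uint16)
    label_map = {}
    for bit, name in enumerate(REQUIRED_STRUCTURES):
        labels |= phantom.structures[name].astype(np.uint16) << bit
        label_map[name] = bit
    nib.save(nib.Nifti1Image(labels, affine),
             stem.with_suffix(".structures.nii.gz"))
    sidecar = {"voxel_size_mm": list(phantom.voxel_size),
               "patient_class": phantom.patient_class,
               "structure_bits": label_map}
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_phantom(stem: str | Path) -> Phantom:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    density = np.asarray(
        nib.load(stem.with_suffix(".density.nii.gz")).dataobj, dtype=np.float64)
    labels = np.asarray(
        nib.load(stem.with_suffix(".structures.nii.gz")).dataobj,
        dtype=np.uint16)
    structures = {name: (labels >> bit) & 1 > 0
                  for name, bit in sidecar["structure_bits"].items()}
    return Phantom(tuple(sidecar["voxel_size_mm"]), density, structures,
                   sidecar["patient_class"])
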