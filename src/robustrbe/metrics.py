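"""Dose-volume histograms, dose metrics and constraint evaluation.

Implements the metrics the study design needs: DVHs (cumulative, absolute
and fractional volume), dose to the hottest fixed volume (D0.1cc), D95
target coverage expressed as % of prescription, mean/max dose, absolute
volume at or above a dose level (V>=limit in cm^3), and per-organ
constraint pass/fail bookkeeping.

Conventions: DVH bins are 0.05 Gy wide by default with linear interpolation
in dose; "at or above" comparisons count equality at a constraint limit as
a breach.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ScalarGrid
from .phantom import ADULT, PEDIATRIC, PRESCRIPTIONS, Phantom, Prescription

DEFAULT_BIN_GY = 0.05


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure.

    ``edges`` are dose values (Gy-like units of the source grid);
    ``cum_frac[i]`` / ``cum_cm3[i]`` are the fractional / absolute volume
    receiving at least ``edges[i]``.  The curve is monotone non-increasing,
    starts at 100% of the structure volume at dose 0 and reaches 0 above
    the structure maximum.
    """

    structure: str
    unit: str
    edges: np.ndarray
    cum_frac: np.ndarray
    cum_cm3: np.ndarray
    total_cm3: float


def compute_dvh(grid: ScalarGrid, mask: np.ndarray, structure: str = "",
                bin_width: float = DEFAULT_BIN_GY) -> DVH:
    """Cumulative DVH of ``grid`` over ``mask``."""
    if mask.shape != grid.shape:
        raise ValueError("mask and grid are not aligned")
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"empty mask for structure {structure!r}")
    doses = grid.values[mask]
    vox_cm3 = grid.voxel_volume_cm3
    top = float(doses.max()) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(doses, bins=edges)
    at_least = np.concatenate([[n], n - np.cumsum(counts)])
    return DVH(structure, grid.unit, edges, at_least / n,
               at_least * vox_cm3, n * vox_cm3)


def dose_at_volume(dvh: DVH, volume: float, percent: bool = False) -> float:
    """Minimum dose received by the hottest ``volume`` of the structure.

    ``volume`` is cm^3, or % of the structure volume when ``percent``;
    linear interpolation between DVH bins.
    """
    target = dvh.total_cm3 * volume / 100.0 if percent else volume
    if not 0 < target <= dvh.total_cm3 + 1e-12:
        raise ValueError(
            f"volume {target:.3g} cm^3 outside (0, {dvh.total_cm3:.3g}]")
    # the highest dose level still covering the target volume; on a flat
    # run of the cumulative curve (tied voxel doses) take the hot end,
    # matching the hottest-volume convention
    cum = dvh.cum_cm3
    i = int(np.nonzero(cum >= target - 1e-12)[0][-1])
    if i == len(cum) - 1:
        return float(dvh.edges[-1])
    frac = (cum[i] - target) / (cum[i] - cum[i + 1])
    return float(dvh.edges[i]
                 + frac * (dvh.edges[i + 1] - dvh.edges[i]))


def volume_at_dose(dvh: DVH, dose: float) -> float:
    """Absolute volume (cm^3) receiving at least ``dose``, interpolated."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return float(np.interp(dose, dvh.edges, dvh.cum_cm3, right=0.0))


def d95_percent(grid: ScalarGrid, mask: np.ndarray,
                prescription: Prescription,
                bin_width: float = DEFAULT_BIN_GY) -> float:
    """Near-minimum target coverage: D95 as % of the prescribed total."""
    dvh = compute_dvh(grid, mask, "CTV", bin_width)
    return 100.0 * dose_at_volume(dvh, 95.0, percent=True) \
        / prescription.total_gy_rbe


def mean_dose(grid: ScalarGrid, mask: np.ndarray) -> float:
    return float(grid.values[mask].mean())


def max_dose(grid: ScalarGrid, mask: np.ndarray) -> float:
    return float(grid.values[mask].max())


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

KIND_DVH = "D_volume"   # dose to the hottest fixed volume vs limit
KIND_MAX = "max"
KIND_MEAN = "mean"


@dataclass(frozen=True)
class ConstraintRule:
    """One organ-at-risk rule: statistic kind, optional volume, limit."""

    structure: str
    kind: str
    limit_gy_rbe: float
    volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.limit_gy_rbe <= 0:
            raise ValueError("limit must be positive")
        if self.kind == KIND_DVH and not self.volume_cm3:
            raise ValueError("D_volume rules carry a volume")
        if self.kind not in (KIND_DVH, KIND_MAX, KIND_MEAN):
            raise ValueError(f"unknown rule kind {self.kind!r}")


@dataclass(frozen=True)
class ConstraintSet:
    """Prescription plus the per-OAR dose limits of one protocol."""

    prescription: Prescription
    rules: tuple[ConstraintRule, ...] = field(default_factory=tuple)


def _protocol(cls: str) -> ConstraintSet:
    lim = {
        ADULT: {"serial": 58.0, "retina": 49.0, "lens": 6.5,
                "inner_ear": 52.0, "brainstem": 58.0},
        PEDIATRIC: {"serial": 50.0, "retina": 45.0, "lens": 6.0,
                    "inner_ear": 44.0, "brainstem": 50.4},
    }[cls]
    rules = [
        ConstraintRule("brainstem", KIND_DVH, lim["brainstem"], 0.1),
        ConstraintRule("spinal_cord", KIND_DVH, lim["serial"], 0.1),
        ConstraintRule("optic_nerve_L", KIND_DVH, lim["serial"], 0.1),
        ConstraintRule("optic_nerve_R", KIND_DVH, lim["serial"], 0.1),
        ConstraintRule("optic_chiasm", KIND_DVH, lim["serial"], 0.1),
        ConstraintRule("retina", KIND_MAX, lim["retina"]),
        ConstraintRule("lenses", KIND_MAX, lim["lens"]),
        ConstraintRule("inner_ear", KIND_MEAN, lim["inner_ear"]),
    ]
    if cls == ADULT:
        rules.append(ConstraintRule("parotid", KIND_MEAN, 30.0))
    return ConstraintSet(PRESCRIPTIONS[cls], tuple(rules))


#: Local-protocol constraint presets (adult chondrosarcoma/chordoma scheme
#: and pediatric craniopharyngioma scheme)
CONSTRAINTS = {ADULT: _protocol(ADULT), PEDIATRIC: _protocol(PEDIATRIC)}


def rule_value(grid: ScalarGrid, mask: np.ndarray, rule: ConstraintRule,
               bin_width: float = DEFAULT_BIN_GY) -> float:
    """Evaluate a rule's statistic on one structure."""
    if rule.kind == KIND_DVH:
        dvh = compute_dvh(grid, mask, rule.structure, bin_width)
        vol = min(rule.volume_cm3, dvh.total_cm3)
        return dose_at_volume(dvh, vol)
    if rule.kind == KIND_MAX:
        return max_dose(grid, mask)
    return mean_dose(grid, mask)


def evaluate_constraints(grid: ScalarGrid, phantom: Phantom,
                         constraints: ConstraintSet | None = None,
                         bin_width: float = DEFAULT_BIN_GY) -> pd.DataFrame:
    """Evaluate every rule on a total-dose grid.

    Returns a tidy frame (structure, kind, volume_cm3, value, limit,
    margin, breach).  A breach is a value at or above the limit.  Rules
    whose structure is absent from the phantom are skipped with an explicit
    warning, never silently.
    """
    constraints = constraints or CONSTRAINTS[phantom.patient_class]
    rows = []
    for rule in constraints.rules:
        if rule.structure not in phantom.structures:
            warnings.warn(
                f"structure {rule.structure!r} absent from phantom; "
                f"rule skipped", stacklevel=2)
            continue
        value = rule_value(grid, phantom.structures[rule.structure], rule,
                           bin_width)
        rows.append({
            "structure": rule.structure, "kind": rule.kind,
            "volume_cm3": rule.volume_cm3, "value": value,
            "limit": rule.limit_gy_rbe,
            "margin": rule.limit_gy_rbe - value,
            "breach": value >= rule.limit_gy_rbe,
        })
    return pd.DataFrame(rows)


def volume_at_constraint(grid: ScalarGrid, phantom: Phantom,
                         structure: str = "brainstem",
                         constraints: ConstraintSet | None = None,
                         bin_width: float = DEFAULT_BIN_GY) -> float:
    """Absolute volume (cm^3) of a structure irradiated at or above its
    protocol constraint dose."""
    constraints = constraints or CONSTRAINTS[phantom.patient_class]
    rule = next(r for r in constraints.rules if r.structure == structure)
    dvh = compute_dvh(grid, phantom.structures[structure], structure,
                      bin_width)
    return volume_at_dose(dvh, rule.limit_gy_rbe)


def dvh_table(dvhs: list[DVH], **labels) -> pd.DataFrame:
    """Tidy long-format export of DVH curves."""
    frames = []
    for dvh in dvhs:
        frames.append(pd.DataFrame({
            "structure": dvh.structure, "dose": dvh.edges,
            "volume_pct": 100.0 * dvh.cum_frac,
            "volume_cm3": dvh.cum_cm3, **labels}))
    return pd.concat(frames, ignore_index=True)
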