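"""Systematic physical-uncertainty scenarios and worst-case analysis.

Twelve scenarios are considered: the cross of +/-3 mm single-axis isocenter
shifts (x, y, z) with +/-3.5% water-equivalent range scaling.  Each scenario
assumes the same error is realized systematically through the whole course.
Dose under a scenario is recomputed by the ray-tracing engine (not
interpolated from the nominal grid), with the plan's fluence maps and
normalization frozen at their nominal values, so errors change the
delivered dose rather than being renormalized away.

Worst case is taken per metric independently: the scenario returning the
highest value for an OAR metric, the lowest for a CTV coverage metric.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ScalarGrid
from .metrics import (ConstraintSet, CONSTRAINTS, KIND_DVH, compute_dvh,
                      d95_percent, rule_value, volume_at_dose)
from .phantom import Phantom
from .proton_dose import ProtonPlan

SHIFT_MM = 3.0
RANGE_SCALES = (1.035, 0.965)
_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class Scenario:
    """One systematic error realization: a single-axis 3 mm isocenter shift
    combined with a +/-3.5% range scaling."""

    id: str
    isocenter_shift_mm: tuple[float, float, float]
    range_scale: float

    def __post_init__(self) -> None:
        shift = np.asarray(self.isocenter_shift_mm, float)
        if (np.count_nonzero(shift) != 1
                or abs(shift[shift != 0][0]) != SHIFT_MM):
            raise ValueError(
                f"shift must be exactly {SHIFT_MM} mm along a single axis")
        if self.range_scale not in RANGE_SCALES:
            raise ValueError(f"range_scale must be one of {RANGE_SCALES}")


def enumerate_scenarios() -> list[Scenario]:
    """The 12 scenarios: {+/-x, +/-y, +/-z shifts} x {+/-3.5% range}.

    Ids are stable strings like ``"y-3mm_range+3.5pct"``.
    """
    out = []
    for axis in range(3):
        for sign in (+1.0, -1.0):
            shift = [0.0, 0.0, 0.0]
            shift[axis] = sign * SHIFT_MM
            for scale in RANGE_SCALES:
                pct = (scale - 1.0) * 100.0
                sid = (f"{_AXES[axis]}{'+' if sign > 0 else '-'}"
                       f"{SHIFT_MM:.0f}mm_range{pct:+.1f}pct")
                out.append(Scenario(sid, tuple(shift), scale))
    return out


def apply_scenario(plan: ProtonPlan, scenario: Scenario,
                   with_let: bool = False) -> ScalarGrid:
    """Physical per-fraction dose of the plan under one scenario,
    recomputed from the frozen plan parameters."""
    pd_ = plan.compute(shift_mm=scenario.isocenter_shift_mm,
                       range_scale=scenario.range_scale, with_let=with_let)
    return pd_.dose.with_meta(scenario=scenario.id)


@dataclass
class EnvelopeResult:
    """Per-metric worst-case table and per-structure DVH envelope."""

    metrics: pd.DataFrame
    dvh_bands: dict[str, dict] = field(default_factory=dict)
    breach_fraction: float = float("nan")

    def worst(self, metric_id: str) -> float:
        row = self.metrics.set_index("metric").loc[metric_id]
        return float(row["worst"])


def worst_case(plan: ProtonPlan, phantom: Phantom,
               constraints: ConstraintSet | None = None,
               scenario_doses: dict[str, ScalarGrid] | None = None,
               band_structures: tuple[str, ...] = ("CTV", "brainstem",
                                                   "optic_chiasm"),
               ) -> EnvelopeResult:
    """Worst-case envelope of a plan over the 12 scenarios.

    All doses are evaluated as constant-RBE (1.1) weighted totals.  For
    each OAR rule the worst value is the maximum over scenarios; for CTV
    D95 coverage it is the minimum.  ``scenario_doses`` (scenario id ->
    per-fraction physical dose grid) may be supplied to reuse previously
    computed grids; otherwise the 12 grids are recomputed here.
    """
    constraints = constraints or CONSTRAINTS[phantom.patient_class]
    presc = constraints.prescription
    factor = 1.1 * presc.n_fractions  # per-fraction physical -> total RBE1.1
    scenarios = enumerate_scenarios()

    if scenario_doses is None:
        scenario_doses = {sc.id: apply_scenario(plan, sc)
                          for sc in scenarios}
    missing = [sc.id for sc in scenarios if sc.id not in scenario_doses]
    if missing:
        raise ValueError(f"missing scenario grids: {missing}")

    nominal_total = plan.nominal().dose.scaled(factor, "Gy(RBE)")
    totals = {sid: g.scaled(factor, "Gy(RBE)")
              for sid, g in scenario_doses.items()}

    rows = []
    active_rules = [r for r in constraints.rules
                    if r.structure in phantom.structures]
    n_breach = 0
    # The worst value is taken over the scenarios plus the nominal case:
    # the error-free realization is guaranteed realizable, so the reported
    # worst can never be more favorable than nominal.  (For structures at
    # the dose plateau every error can slightly lower an OAR metric, so a
    # scenarios-only maximum could fall below nominal.)
    for rule in active_rules:
        mask = phantom.structures[rule.structure]
        nom = rule_value(nominal_total, mask, rule)
        vals = {sid: rule_value(g, mask, rule) for sid, g in totals.items()}
        worst_sid = max(vals, key=vals.get)
        if vals[worst_sid] < nom:
            worst_sid, worst_val = "nominal", nom
        else:
            worst_val = vals[worst_sid]
        breaches = sum(v >= rule.limit_gy_rbe for v in vals.values())
        n_breach += breaches
        rows.append({
            "metric": f"{rule.structure}_{rule.kind}", "structure":
            rule.structure, "objective": "max", "nominal": nom,
            "worst": worst_val, "worst_scenario": worst_sid,
            "limit": rule.limit_gy_rbe, "n_scenarios_breaching": breaches,
            **{f"scenario:{sid}": v for sid, v in vals.items()},
        })

    # absolute volume at/above each volume-type rule's limit (the Figure-4
    # style statistic), worst = max over scenarios
    for rule in active_rules:
        if rule.kind != KIND_DVH:
            continue
        mask = phantom.structures[rule.structure]
        nom_dvh = compute_dvh(nominal_total, mask, rule.structure)
        nom = volume_at_dose(nom_dvh, rule.limit_gy_rbe)
        vals = {}
        for sid, g in totals.items():
            dvh = compute_dvh(g, mask, rule.structure)
            vals[sid] = volume_at_dose(dvh, rule.limit_gy_rbe)
        worst_sid = max(vals, key=vals.get)
        if vals[worst_sid] < nom:
            worst_sid, worst_val = "nominal", nom
        else:
            worst_val = vals[worst_sid]
        rows.append({
            "metric": f"{rule.structure}_V_at_limit_cm3",
            "structure": rule.structure, "objective": "max",
            "nominal": nom, "worst": worst_val,
            "worst_scenario": worst_sid, "limit": rule.limit_gy_rbe,
            "n_scenarios_breaching": np.nan,
            **{f"scenario:{sid}": v for sid, v in vals.items()},
        })

    ctv = phantom.structures["CTV"]
    nom_d95 = d95_percent(nominal_total, ctv, presc)
    vals = {sid: d95_percent(g, ctv, presc) for sid, g in totals.items()}
    worst_sid = min(vals, key=vals.get)
    if vals[worst_sid] > nom_d95:
        worst_sid, worst_val = "nominal", nom_d95
    else:
        worst_val = vals[worst_sid]
    rows.append({
        "metric": "CTV_D95_pct", "structure": "CTV", "objective": "min",
        "nominal": nom_d95, "worst": worst_val,
        "worst_scenario": worst_sid, "limit": np.nan,
        "n_scenarios_breaching": 0,
        **{f"scenario:{sid}": v for sid, v in vals.items()},
    })

    bands = {}
    for name in band_structures:
        if name not in phantom.structures:
            continue
        mask = phantom.structures[name]
        nom_dvh = compute_dvh(nominal_total, mask, name)
        edges = nom_dvh.edges
        lo = np.full_like(nom_dvh.cum_cm3, np.inf)
        hi = np.zeros_like(nom_dvh.cum_cm3)
        for g in totals.values():
            dvh = compute_dvh(g, mask, name)
            cum = np.interp(edges, dvh.edges, dvh.cum_cm3, right=0.0)
            lo = np.minimum(lo, cum)
            hi = np.maximum(hi, cum)
        bands[name] = {"dose": edges, "nominal_cm3": nom_dvh.cum_cm3,
                       "min_cm3": lo, "max_cm3": hi}

    frac = n_breach / (len(scenarios) * max(len(active_rules), 1))
    return EnvelopeResult(pd.DataFrame(rows), bands, frac)


def scenario_table() -> pd.DataFrame:
    """CSV-exportable scenario listing (id, dx, dy, dz, range scale)."""
    rows = [{"id": sc.id, "dx_mm": sc.isocenter_shift_mm[0],
             "dy_mm": sc.isocenter_shift_mm[1],
             "dz_mm": sc.isocenter_shift_mm[2],
             "range_scale": sc.range_scale}
            for sc in enumerate_scenarios()]
    return pd.DataFrame(rows)
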