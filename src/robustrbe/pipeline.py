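"""Desk-scale study orchestration.

Runs the whole analysis from a single configuration: synthetic cohort
generation, proton planning (nominal dose + LET_d), the 12-scenario
physical robustness analysis, variable-RBE weighting for a list of
(alpha/beta)_x values plus a tumor-(alpha/beta)_x override, the photon-arc
comparator, DVH/metric tables, fraction-scheme constraint conversion and a
provenance record.  Every stage is re-entrant from the serialized
intermediates in the output directory.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import ScalarGrid, save_grid
from .metrics import (CONSTRAINTS, compute_dvh, d95_percent, dvh_table,
                      evaluate_constraints, mean_dose, volume_at_constraint)
from .phantom import (ADULT, PRESCRIPTIONS, Phantom, PhantomSpec,
                      load_phantom, sample_cohort, save_phantom)
from .photon_surrogate import ArcSpec, compute_arc_dose
from .proton_dose import ProtonPlan
from .radiobiology import (RBEParams, convert_constraint_table,
                           rbe_weighted_dose)
from .robustness import apply_scenario, enumerate_scenarios, scenario_table, worst_case

log = logging.getLogger("robustrbe")


@dataclass
class StudyConfig:
    """Configuration of one study run (YAML-serializable)."""

    seed: int = 0
    n_adult: int = 6
    n_pediatric: int = 4
    voxel_mm: float = 3.0
    target_volume_cm3: float = 25.0
    chiasm_overlap_fraction: float = 0.7
    brainstem_gap_mm: float = 0.0
    alpha_beta_list: tuple[float, ...] = (2.0, 3.0, 4.0)
    ctv_alpha_beta_override: float = 10.0
    arc_n_angles: int = 36
    save_grids: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_adult + self.n_pediatric < 1:
            raise ValueError("cohort must contain at least one phantom")
        if len(self.alpha_beta_list) == 0:
            raise ValueError("alpha_beta_list must be non-empty")
        if any(ab <= 0 for ab in self.alpha_beta_list):
            raise ValueError("alpha_beta values must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _timed(stage):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.error("stage %s: FAILED", stage)
                raise RuntimeError(f"stage {stage!r} failed") from None
            log.info("stage %s: done in %.1f s", stage,
                     time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def cohort_specs(config: StudyConfig) -> list[tuple[PhantomSpec, Phantom]]:
    base = PhantomSpec(voxel_mm=config.voxel_mm,
                       target_volume_cm3=config.target_volume_cm3,
                       chiasm_overlap_fraction=config.chiasm_overlap_fraction,
                       brainstem_gap_mm=config.brainstem_gap_mm)
    n = config.n_adult + config.n_pediatric
    return sample_cohort(n, base, seed=config.seed,
                         adult_fraction=config.n_adult / n)


@_timed("generate-cohort")
def generate_cohort(config: StudyConfig, outdir: Path) -> list[Phantom]:
    pdir = outdir / "phantoms"
    pdir.mkdir(parents=True, exist_ok=True)
    phantoms = []
    for i, (spec, phantom) in enumerate(cohort_specs(config)):
        save_phantom(phantom, pdir / f"phantom_{i:02d}")
        (pdir / f"phantom_{i:02d}.spec.json").write_text(
            json.dumps(asdict(spec), indent=1))
        phantoms.append(phantom)
    return phantoms


def _load_cohort(outdir: Path) -> list[Phantom]:
    pdir = outdir / "phantoms"
    stems = sorted(pdir.glob("phantom_*.json"))
    stems = [p for p in stems if not p.name.endswith(".spec.json")]
    if not stems:
        raise FileNotFoundError(f"no phantoms under {pdir}; run "
                                "generate-cohort first")
    return [load_phantom(p.with_suffix("")) for p in stems]


@_timed("plan")
def plan_cohort(config: StudyConfig, outdir: Path,
                phantoms: list[Phantom] | None = None) -> list[ProtonPlan]:
    phantoms = phantoms or _load_cohort(outdir)
    plans = []
    gdir = outdir / "grids"
    gdir.mkdir(parents=True, exist_ok=True)
    for i, phantom in enumerate(phantoms):
        plan = ProtonPlan(phantom)
        nom = plan.nominal()
        (outdir / "grids" / f"plan_{i:02d}.json").write_text(
            json.dumps(plan.to_dict(), indent=1))
        if config.save_grids:
            save_grid(nom.dose.with_meta(plan=i, scenario="nominal"),
                      gdir / f"dose_nominal_{i:02d}.nii.gz")
            save_grid(nom.letd.with_meta(plan=i),
                      gdir / f"letd_nominal_{i:02d}.nii.gz")
        plans.append(plan)
    return plans


@_timed("analyze-robustness")
def analyze_robustness(config: StudyConfig, outdir: Path,
                       phantoms: list[Phantom], plans: list[ProtonPlan]):
    gdir = outdir / "grids"
    gdir.mkdir(parents=True, exist_ok=True)
    scenario_table().to_csv(outdir / "scenarios.csv", index=False)
    envelopes = []
    scenario_doses_all = []
    for i, (phantom, plan) in enumerate(zip(phantoms, plans)):
        doses = {}
        for sc in enumerate_scenarios():
            grid = apply_scenario(plan, sc)
            doses[sc.id] = grid
            if config.save_grids:
                save_grid(grid.with_meta(plan=i),
                          gdir / f"dose_{sc.id}_{i:02d}.nii.gz")
        env = worst_case(plan, phantom, scenario_doses=doses)
        env.metrics.insert(0, "phantom", i)
        envelopes.append(env)
        scenario_doses_all.append(doses)
    pd.concat([e.metrics for e in envelopes], ignore_index=True).to_csv(
        outdir / "robustness_metrics.csv", index=False)
    return envelopes, scenario_doses_all


@_timed("analyze-rbe")
def analyze_rbe(config: StudyConfig, outdir: Path,
                phantoms: list[Phantom], plans: list[ProtonPlan]):
    gdir = outdir / "grids"
    gdir.mkdir(parents=True, exist_ok=True)
    rbe_grids: list[dict] = []
    for i, (phantom, plan) in enumerate(zip(phantoms, plans)):
        nom = plan.nominal()
        n_fx = plan.prescription.n_fractions
        per = {}
        for ab in config.alpha_beta_list:
            g = rbe_weighted_dose(nom.dose, nom.letd,
                                  RBEParams("mcnamara", ab), n_fx,
                                  excluded=nom.let_excluded)
            per[f"ab{ab:g}"] = g
            if config.save_grids:
                save_grid(g.with_meta(plan=i),
                          gdir / f"dose_mcnamara_ab{ab:g}_{i:02d}.nii.gz")
        ab0 = config.alpha_beta_list[0]
        g = rbe_weighted_dose(
            nom.dose, nom.letd, RBEParams("mcnamara", ab0), n_fx,
            excluded=nom.let_excluded,
            override={"CTV": config.ctv_alpha_beta_override},
            structures=phantom.structures)
        per[f"ab{ab0:g}_ctv{config.ctv_alpha_beta_override:g}"] = g
        if config.save_grids:
            save_grid(g.with_meta(plan=i),
                      gdir / f"dose_mcnamara_ctv_override_{i:02d}.nii.gz")
        rbe_grids.append(per)
    return rbe_grids


@_timed("photon-surrogate")
def photon_cohort(config: StudyConfig, outdir: Path,
                  phantoms: list[Phantom]) -> list[ScalarGrid]:
    gdir = outdir / "grids"
    gdir.mkdir(parents=True, exist_ok=True)
    grids = []
    arc = ArcSpec(n_angles=config.arc_n_angles)
    for i, phantom in enumerate(phantoms):
        g = compute_arc_dose(phantom, arc=arc)
        if config.save_grids:
            save_grid(g.with_meta(plan=i), gdir / f"dose_photon_{i:02d}.nii.gz")
        grids.append(g)
    return grids


@_timed("report")
def report(config: StudyConfig, outdir: Path, phantoms, plans,
           envelopes, rbe_grids, photon_grids) -> pd.DataFrame:
    """Per-phantom / per-analysis metric table plus DVH export."""
    rows = []
    dvh_rows = []
    for i, (phantom, plan) in enumerate(zip(phantoms, plans)):
        presc = plan.prescription
        factor = 1.1 * presc.n_fractions
        nom11 = plan.nominal().dose.scaled(factor, "Gy(RBE)")
        bmc = phantom.mask("brain-CTV")
        ctv = phantom.structures["CTV"]

        def add(analysis, grid):
            rows.append({
                "phantom": i, "patient_class": phantom.patient_class,
                "analysis": analysis,
                "ctv_d95_pct": d95_percent(grid, ctv, presc),
                "mean_brain_minus_ctv": mean_dose(grid, bmc),
                "brainstem_v_constraint_cm3":
                    volume_at_constraint(grid, phantom, "brainstem"),
                "chiasm_v_constraint_cm3":
                    volume_at_constraint(grid, phantom, "optic_chiasm"),
                "integral_dose_gy_l":
                    grid.values[phantom.structures["external"]].sum()
                    * phantom.voxel_volume_cm3 / 1000.0,
            })
            for s in ("CTV", "brainstem", "optic_chiasm"):
                dvh = compute_dvh(grid, phantom.structures[s], s)
                dvh_rows.append(dvh_table([dvh], phantom=i,
                                          analysis=analysis))

        add("nominal_rbe11", nom11)
        for name, per in rbe_grids[i].items():
            add(f"mcnamara_{name}", per)
        add("photon_surrogate", photon_grids[i])
        wc = envelopes[i].metrics.set_index("metric")
        rows.append({
            "phantom": i, "patient_class": phantom.patient_class,
            "analysis": "worst_case_rbe11",
            "ctv_d95_pct": float(wc.loc["CTV_D95_pct", "worst"]),
            "mean_brain_minus_ctv": np.nan,
            "brainstem_v_constraint_cm3":
                float(wc.loc["brainstem_V_at_limit_cm3", "worst"]),
            "chiasm_v_constraint_cm3":
                float(wc.loc["optic_chiasm_V_at_limit_cm3", "worst"]),
            "integral_dose_gy_l": np.nan,
        })
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "metrics.csv", index=False)
    pd.concat(dvh_rows, ignore_index=True).to_csv(
        outdir / "dvh.csv", index=False)

    # constraint evaluation of the nominal plans
    frames = []
    for i, (phantom, plan) in enumerate(zip(phantoms, plans)):
        factor = 1.1 * plan.prescription.n_fractions
        df = evaluate_constraints(plan.nominal().dose.scaled(factor,
                                                             "Gy(RBE)"),
                                  phantom)
        df.insert(0, "phantom", i)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "constraints_nominal.csv", index=False)

    # EQD2-style constraint transfer to the adult scheme
    d1 = PRESCRIPTIONS[ADULT].per_fraction_gy_rbe
    convert_constraint_table(d1).to_csv(
        outdir / "constraints_converted.csv", index=False)
    return table


def run_study(config: StudyConfig, outdir: str | Path) -> Path:
    """Run every stage; returns the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    config.to_yaml(outdir / "config.yaml")

    phantoms = generate_cohort(config, outdir)
    plans = plan_cohort(config, outdir, phantoms)
    envelopes, _ = analyze_robustness(config, outdir, phantoms, plans)
    rbe_grids = analyze_rbe(config, outdir, phantoms, plans)
    photon_grids = photon_cohort(config, outdir, phantoms)
    report(config, outdir, phantoms, plans, envelopes, rbe_grids,
           photon_grids)

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_phantoms": len(phantoms),
        "n_scenarios": len(enumerate_scenarios()),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return outdir


# ---------------------------------------------------------------------------
# cohort summaries used by the study-level analyses
# ---------------------------------------------------------------------------

def cohort_summary(metrics: pd.DataFrame,
                   robustness: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of the headline metrics per analysis, with the
    worst-case brainstem volume merged in from the robustness table."""
    agg = metrics.groupby("analysis").agg(
        ctv_d95_pct=("ctv_d95_pct", "mean"),
        mean_brain_minus_ctv=("mean_brain_minus_ctv", "mean"),
        brainstem_v_mean=("brainstem_v_constraint_cm3", "mean"),
        brainstem_v_sd=("brainstem_v_constraint_cm3", "std"),
    ).reset_index()
    bs = robustness[robustness["metric"] == "brainstem_D_volume"]
    agg.attrs["brainstem_breach_fraction"] = float(
        bs["n_scenarios_breaching"].sum() / (12 * len(bs))) if len(bs) else np.nan
    return agg
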