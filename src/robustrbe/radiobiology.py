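"""RBE models and fraction-scheme (BED-isoeffect) dose conversion.

Two RBE models are supported: the clinical constant 1.1, and the McNamara
phenomenological variable-RBE model, a linear-quadratic-based fit to the
pre-2014 proton RBE measurement database.  The variable model expresses RBE
as a function of the proton physical dose per fraction D_p, the
dose-averaged LET (LET_d) and the reference photon tissue ratio (alpha/beta)_x:

    RBE_max = p0 + p1 * LET_d / (a/b)_x
    RBE_min = p2 + p3 * sqrt((a/b)_x) * LET_d      (floored at 0)
    RBE = ( sqrt((a/b)_x^2 + 4 D_p (a/b)_x RBE_max + 4 D_p^2 RBE_min^2)
            - (a/b)_x ) / (2 D_p)

with fit constants p0 = 0.99064, p1 = 0.35605, p2 = 1.1012,
p3 = -0.0038703.  At D_p = 0 the analytic limit is RBE_max.  The model
predicts increased RBE for low (a/b)_x and high LET_d, and tends to RBE_min
as the dose per fraction grows.

Constraint transfer between fractionation schemes uses the BED-isoeffect
relation

    D_1 = D_2 * (1 + d_2/(a/b)_x) / (1 + d_1/(a/b)_x)

where D_2 is a total constraint dose expressed at d_2 Gy(RBE) per fraction
(EQD2-style tables use d_2 = 2) and d_1 is the per-fraction dose of the
target scheme.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import DOSE_RBE, DOSE_TOTAL, ScalarGrid, UnitError

# McNamara fit constants (dimensionless)
P0 = 0.99064
P1 = 0.35605
P2 = 1.1012
P3 = -0.0038703

CONSTANT_RBE = 1.1

MODEL_CONSTANT = "constant_1p1"
MODEL_MCNAMARA = "mcnamara"


@dataclass(frozen=True)
class RBEParams:
    """RBE model selection with its tissue parameter.

    ``alpha_beta_x`` is the global (a/b)_x in Gy; a per-structure override
    (e.g. a tumor value of 10 Gy) is applied through the ``override`` map of
    :func:`rbe_weighted_dose`.
    """

    model: str = MODEL_MCNAMARA
    alpha_beta_x: float = 2.0

    def __post_init__(self) -> None:
        if self.model not in (MODEL_CONSTANT, MODEL_MCNAMARA):
            raise ValueError(f"unknown RBE model {self.model!r}")
        if self.alpha_beta_x <= 0:
            raise ValueError("alpha_beta_x must be positive")


def rbe_mcnamara(dose_per_fx, letd, alpha_beta_x):
    """Voxelwise McNamara RBE.

    Parameters are broadcast together: physical dose per fraction (Gy),
    LET_d (keV/um) and (a/b)_x (Gy, scalar or voxel map).  Negative inputs
    raise; D_p = 0 returns the analytic limit RBE_max.
    """
    d = np.asarray(dose_per_fx, dtype=np.float64)
    L = np.asarray(letd, dtype=np.float64)
    ab = np.asarray(alpha_beta_x, dtype=np.float64)
    if np.any(d < 0) or np.any(L < 0):
        raise ValueError("dose and LET_d must be non-negative")
    if np.any(ab <= 0):
        raise ValueError("alpha_beta_x must be positive")
    rbe_max = P0 + P1 * L / ab
    rbe_min = np.maximum(P2 + P3 * np.sqrt(ab) * L, 0.0)
    d_safe = np.where(d > 0, d, 1.0)
    root = np.sqrt(ab * ab + 4 * d_safe * ab * rbe_max
                   + 4 * d_safe * d_safe * rbe_min * rbe_min)
    rbe = (root - ab) / (2 * d_safe)
    return np.where(d > 0, rbe, rbe_max)


def rbe_weighted_dose(physical_dose: ScalarGrid, letd: ScalarGrid | None,
                      params: RBEParams, n_fractions: int,
                      excluded: np.ndarray | None = None,
                      override: dict[str, float] | None = None,
                      structures: dict[str, np.ndarray] | None = None,
                      ) -> ScalarGrid:
    """RBE-weighted total dose in Gy(RBE).

    ``physical_dose`` may be tagged per-fraction (``Gy/fx``) or total
    (``Gy``); the per-fraction dose entering the RBE formula is always
    total / ``n_fractions`` under the uniform-fractionation assumption.
    Voxels in ``excluded`` (the 0.5%-of-max LET_d dose threshold) fall back
    to the constant RBE of 1.1.  ``override`` maps structure names to
    (a/b)_x values and needs ``structures`` masks (e.g. CTV at 10 Gy while
    normal tissue keeps the global value).
    """
    if physical_dose.unit == "Gy/fx":
        total = physical_dose.values * n_fractions
    elif physical_dose.unit == DOSE_TOTAL:
        total = physical_dose.values
    else:
        raise UnitError(
            f"need physical dose (Gy or Gy/fx), got {physical_dose.unit!r}")

    if params.model == MODEL_CONSTANT:
        out = total * CONSTANT_RBE
    else:
        if letd is None:
            raise ValueError("variable RBE needs a LET_d grid")
        if letd.unit != "keV/um":
            raise UnitError(f"LET grid has unit {letd.unit!r}")
        if letd.shape != physical_dose.shape:
            raise ValueError("dose and LET grids are not aligned")
        ab = np.full(physical_dose.shape, params.alpha_beta_x)
        if override:
            if structures is None:
                raise ValueError("override needs structure masks")
            for name, value in override.items():
                ab[structures[name]] = value
        rbe = rbe_mcnamara(total / n_fractions, letd.values, ab)
        if excluded is not None:
            rbe = np.where(excluded, CONSTANT_RBE, rbe)
        out = total * rbe
    meta = dict(physical_dose.meta)
    meta.update(rbe_model=params.model, alpha_beta_x=params.alpha_beta_x,
                n_fractions=n_fractions,
                alpha_beta_override=dict(override) if override else None)
    return ScalarGrid(out, DOSE_RBE, physical_dose.voxel_size, meta)


# ---------------------------------------------------------------------------
# BED-isoeffect constraint conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EQDParams:
    """Inputs of the BED-isoeffect conversion.

    D2: total constraint dose Gy(RBE) at d2 Gy(RBE) per fraction (source
    scheme); d1: per-fraction dose of the target scheme; alpha_beta_x in Gy.
    """

    D2: float
    d2: float
    d1: float
    alpha_beta_x: float

    def __post_init__(self) -> None:
        if min(self.D2, self.d2, self.d1) <= 0:
            raise ValueError("doses must be positive")
        if self.alpha_beta_x <= 0:
            raise ValueError("alpha_beta_x must be positive")


def eqd_convert(params: EQDParams) -> float:
    """Total isoeffective dose D1 in the target fractionation scheme."""
    ab = params.alpha_beta_x
    return params.D2 * (1 + params.d2 / ab) / (1 + params.d1 / ab)


#: Editable EQD2-style constraint table for adult brain structures
#: (total dose at 2 Gy(RBE) per fraction, (a/b)_x = 2 Gy assumed for brain
#: tissue).  Representative published consensus-style values; meant to be
#: replaced by the user's own table via configuration.
EQD2_CONSTRAINTS = {
    "brainstem": {"D2": 54.0, "d2": 2.0, "alpha_beta_x": 2.0},
    "optic_chiasm": {"D2": 55.0, "d2": 2.0, "alpha_beta_x": 2.0},
    "optic_nerve_L": {"D2": 55.0, "d2": 2.0, "alpha_beta_x": 2.0},
    "optic_nerve_R": {"D2": 55.0, "d2": 2.0, "alpha_beta_x": 2.0},
}


def convert_constraint_table(d1: float,
                             table: dict[str, dict] | None = None,
                             ) -> pd.DataFrame:
    """Convert an EQD2-style constraint table to a ``d1``-per-fraction
    scheme.  Returns a tidy frame with the source and converted limits."""
    table = table if table is not None else EQD2_CONSTRAINTS
    rows = []
    for structure, entry in table.items():
        params = EQDParams(D2=entry["D2"], d2=entry["d2"], d1=d1,
                           alpha_beta_x=entry["alpha_beta_x"])
        rows.append({"structure": structure, "D2_gy_rbe": entry["D2"],
                     "d2_gy_rbe": entry["d2"], "d1_gy_rbe": d1,
                     "alpha_beta_x": entry["alpha_beta_x"],
                     "D1_gy_rbe": eqd_convert(params)})
    return pd.DataFrame(rows)
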