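"""Unit-tagged scalar voxel fields shared by the dose and LET engines.

A :class:`ScalarGrid` couples a voxel array with a mandatory unit tag and a
provenance metadata dictionary.  Arithmetic between grids with different unit
tags raises, which catches the classic planning bug of summing a physical
dose with an RBE-weighted one.

Units used throughout the package:

``Gy/fx``    physical absorbed dose per fraction
``Gy``       total physical absorbed dose
``Gy(RBE)``  total RBE-weighted dose
``keV/um``   dose-averaged linear energy transfer in water
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

DOSE_PER_FX = "Gy/fx"
DOSE_TOTAL = "Gy"
DOSE_RBE = "Gy(RBE)"
LET_UNIT = "keV/um"

_KNOWN_UNITS = {DOSE_PER_FX, DOSE_TOTAL, DOSE_RBE, LET_UNIT}


class UnitError(ValueError):
    """Raised when grid arithmetic mixes incompatible unit tags."""


@dataclass
class ScalarGrid:
    """A scalar field on a phantom raster with a unit tag and provenance.

    Parameters
    ----------
    values : ndarray
        Voxel values, same shape as the phantom grid.
    unit : str
        One of ``Gy/fx``, ``Gy``, ``Gy(RBE)``, ``keV/um``.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    meta : dict
        Free-form provenance (plan id, scenario id, RBE model id ...).
    """

    values: np.ndarray
    unit: str
    voxel_size: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in _KNOWN_UNITS:
            raise UnitError(f"unknown unit tag {self.unit!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("grid values must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def _check_compatible(self, other: "ScalarGrid") -> None:
        if not isinstance(other, ScalarGrid):
            raise TypeError("can only combine with another ScalarGrid")
        if other.unit != self.unit:
            raise UnitError(f"unit mismatch: {self.unit!r} vs {other.unit!r}")
        if other.shape != self.shape:
            raise ValueError("grid shape mismatch")

    def __add__(self, other: "ScalarGrid") -> "ScalarGrid":
        self._check_compatible(other)
        return ScalarGrid(self.values + other.values, self.unit,
                          self.voxel_size, dict(self.meta))

    def scaled(self, factor: float, unit: str | None = None) -> "ScalarGrid":
        """Return a copy scaled by ``factor``, optionally retagged.

        Retagging is how per-fraction physical dose becomes total dose
        (factor = number of fractions) or constant-RBE weighted dose
        (factor = 1.1).
        """
        return ScalarGrid(self.values * factor, unit or self.unit,
                          self.voxel_size, dict(self.meta))

    def with_meta(self, **kwargs) -> "ScalarGrid":
        meta = dict(self.meta)
        meta.update(kwargs)
        return ScalarGrid(self.values, self.unit, self.voxel_size, meta)


def save_grid(grid: ScalarGrid, path: str | Path) -> None:
    """Write a grid as NIfTI plus a JSON sidecar carrying unit and meta."""
    path = Path(path)
    affine = np.diag(list(grid.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(grid.values.astype(np.float32), affine), path)
    sidecar = {"unit": grid.unit, "voxel_size_mm": list(grid.voxel_size),
               "meta": grid.meta}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_grid(path: str | Path) -> ScalarGrid:
    path = Path(path)
    img = nib.load(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    return ScalarGrid(np.asarray(img.dataobj, dtype=np.float64),
                      sidecar["unit"],
                      tuple(sidecar["voxel_size_mm"]),
                      sidecar.get("meta", {}))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")
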