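"""Rotational photon-arc comparator dose model.

A deliberately simple stand-in for an inversely planned photon arc: a
single coplanar arc of equispaced beams, each exponentially attenuated
(6 MV-like effective attenuation, 0.05 cm^-1) with an idealized aperture
conformal to the PTV projection (CTV plus a 3 mm margin), normalized so
that the median PTV dose equals the prescription.  It produces the
characteristic low-dose photon bath that decreases with distance from the
target, which is what modality-comparison metrics (integral dose, mean
normal-brain dose) need.  It is a surrogate, not a model of any clinical
delivery technique, and reports labelled with it must say so.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import DOSE_TOTAL, ScalarGrid
from .phantom import Phantom, Prescription
from .proton_dose import _BeamFrame, BeamSpec, PlanningError


@dataclass(frozen=True)
class ArcSpec:
    """Geometry of the surrogate arc.

    ``scatter_fraction`` and ``scatter_sigma_mm`` model the out-of-field
    dose of a megavoltage photon field (head leakage plus patient scatter)
    as a broad Gaussian component of the lateral fluence profile; clinical
    out-of-field doses within a few cm of a 6 MV field edge are of order
    5-15% of the central-axis dose, hence the 12% default.
    """

    n_angles: int = 72
    attenuation_per_cm: float = 0.05
    ptv_margin_mm: float = 3.0
    penumbra_sigma_mm: float = 5.0
    scatter_fraction: float = 0.12
    scatter_sigma_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.n_angles < 8:
            raise ValueError("n_angles must be >= 8")
        if self.attenuation_per_cm <= 0:
            raise ValueError("attenuation must be positive")
        if not 0 <= self.scatter_fraction < 1:
            raise ValueError("scatter_fraction must be in [0, 1)")


def ptv_mask(phantom: Phantom, margin_mm: float = 3.0) -> np.ndarray:
    """PTV = CTV expanded by a uniform margin."""
    ctv = phantom.structures["CTV"]
    dist = ndimage.distance_transform_edt(~ctv, sampling=phantom.voxel_size)
    return dist <= margin_mm


def compute_arc_dose(phantom: Phantom, prescription: Prescription | None = None,
                     arc: ArcSpec = ArcSpec()) -> ScalarGrid:
    """Total photon dose (Gy) of the surrogate arc on a phantom."""
    prescription = prescription or phantom.prescription
    ptv = ptv_mask(phantom, arc.ptv_margin_mm)
    if (ptv & ~phantom.structures["external"]).any():
        raise PlanningError("PTV extends outside the external contour")

    ptv_f = ptv.astype(np.float64)
    inside = phantom.density > 0
    iso = phantom.centroid_mm("CTV")
    total = np.zeros(phantom.grid_shape)
    for gantry in np.linspace(0.0, 360.0, arc.n_angles, endpoint=False):
        beam = BeamSpec(gantry_angle=float(gantry), couch_angle=0.0)
        frame = _BeamFrame(phantom, beam.direction(), iso,
                           float(min(phantom.voxel_size)))
        dens_rot = frame.sample(phantom.density)
        wed = frame.wed_cm(dens_rot)
        # field edge 1.5 sigma outside the PTV so the high-isodose surface
        # (not the 50% line) covers the target
        primary = frame.fluence(frame.sample(ptv_f) > 0.5,
                                1.5 * arc.penumbra_sigma_mm,
                                arc.penumbra_sigma_mm)
        scatter = ndimage.gaussian_filter(
            primary, arc.scatter_sigma_mm / frame.step_mm)
        fluence = ((1.0 - arc.scatter_fraction) * primary
                   + arc.scatter_fraction * scatter)
        dose_rot = fluence[None, :, :] * np.exp(
            -arc.attenuation_per_cm * wed)
        contrib = frame.to_phantom(dose_rot)
        contrib[~inside] = 0.0
        total += contrib

    med = np.median(total[ptv])
    if med <= 0:
        raise PlanningError("arc delivers no dose to the PTV")
    total *= prescription.total_gy_rbe / med
    return ScalarGrid(total, DOSE_TOTAL, phantom.voxel_size,
                      {"modality": "photon_surrogate",
                       "n_angles": arc.n_angles})
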