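import numpy as np
import pytest

from robustrbe.phantom import ADULT, Phantom, PhantomSpec, build_phantom
from robustrbe.proton_dose import BeamSpec, ProtonPlan


@pytest.fixture(scope="session")
def adult_phantom() -> Phantom:
    """Default adult phantom at a coarse 4 mm raster (fast unit tests)."""
    return build_phantom(PhantomSpec(random_seed=1, voxel_mm=4.0))


@pytest.fixture(scope="session")
def adult_plan(adult_phantom) -> ProtonPlan:
    return ProtonPlan(adult_phantom)


@pytest.fixture(scope="session")
def nominal(adult_plan):
    return adult_plan.nominal()


def make_water_phantom(shape=(40, 56, 40), voxel=3.0,
                       ctv_semi=(15.0, 18.0, 14.0)) -> Phantom:
    """Uniform water block with a centered ellipsoidal CTV; the remaining
    required structures are small displaced boxes (synthetic stand-ins so
    the Phantom contract is satisfied for beam-physics tests)."""
    density = np.ones(shape)
    axes = [(np.arange(n) - (n - 1) / 2.0) * voxel for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    ctv = ((X / ctv_semi[0]) ** 2 + (Y / ctv_semi[1]) ** 2
           + (Z / ctv_semi[2]) ** 2) <= 1.0
    external = np.ones(shape, dtype=bool)

    def box(center, half):
        return ((np.abs(X - center[0]) <= half)
                & (np.abs(Y - center[1]) <= half)
                & (np.abs(Z - center[2]) <= half))

    structures = {
        "CTV": ctv,
        "external": external,
        "brain": box((0, 0, 20), 15.0),
        "brainstem": box((0, 30, 0), 8.0),
        "optic_chiasm": box((0, -25, 8), 5.0),
        "optic_nerve_L": box((-15, -30, 8), 4.0),
        "optic_nerve_R": box((15, -30, 8), 4.0),
    }
    return Phantom((voxel,) * 3, density, structures, ADULT)


@pytest.fixture(scope="session")
def water_phantom() -> Phantom:
    return make_water_phantom()


@pytest.fixture(scope="session")
def single_beam_plan(water_phantom) -> ProtonPlan:
    """One anterior pristine-like beam (explicit range, zero modulation is
    exercised separately; here a small SOBP) on the water block."""
    beam = BeamSpec(gantry_angle=0.0, couch_angle=0.0, sobp_range_cm=10.0,
                    modulation_cm=4.0, lateral_sigma_mm=4.0)
    return ProtonPlan(water_phantom, beams=[beam])
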