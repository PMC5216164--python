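import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import seegplan as sp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_icosphere():
    return sp.icosphere(3, 1.0, name="unit_sphere")


@pytest.fixture(scope="session")
def unit_icosphere_bvh(unit_icosphere):
    return sp.build_bvh(unit_icosphere)


@pytest.fixture(scope="session")
def nested_gm():
    """Unperturbed 70/55 mm grey-matter shell."""
    return sp.GmModel(sp.icosphere(3, 70.0, "gm_outer"), sp.icosphere(3, 55.0, "gm_inner"))


@pytest.fixture(scope="session")
def planted_scene():
    return sp.planted_conflict_scene(seed=0)


@pytest.fixture(scope="session")
def planted_sets(planted_scene):
    cfg = sp.PlanningConfig()
    return [
        sp.plan_single(T, planted_scene, cfg, target_id=name)
        for name, T in planted_scene.targets
    ]


@pytest.fixture(scope="session")
def small_scene():
    """A compact conflict-free phantom used by several pipeline tests."""
    spec = sp.PhantomSpec(
        seed=7, skull_subdivisions=3, n_vessels=3, n_sulci=2, n_targets=3,
        gm_subdivisions=3,
    )
    return sp.generate_phantom(spec)


def make_parallel_cylinder_bvh(distance_mm: float, length: float = 60.0, sides: int = 64):
    """Vessel cylinder of radius 1 mm whose surface runs parallel to the
    x-axis trajectory [0, length] at the given surface distance (axis offset
    distance + 1); extends past both trajectory ends so f_crit is constant."""
    axis_off = distance_mm + 1.0
    curve = np.linspace([-20.0, axis_off, 0.0], [length + 20.0, axis_off, 0.0], 10)
    tube = sp.make_tube(curve, 1.0, sides=sides, name="vessel:cyl")
    return sp.build_bvh(tube)
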