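import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pvlhemo.core import SystoleDrive, ThresholdSpec
from pvlhemo.rheostress import snapshot_stress
from pvlhemo.severity import FlowSnapshot
from pvlhemo.synthdata import (
    PoiseuilleSpec,
    icosphere,
    keyframe_set,
    newtonian_params,
    poiseuille_snapshot,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: Keyframe chamber volumes, diastole to systole (mm^3).
STUDY_VOLUMES = (173_803.0, 122_935.0, 81_943.0, 68_484.0)


@pytest.fixture(scope="session")
def poiseuille():
    """Poiseuille snapshot (tau_wall = 400 Pa, n_r = 200) with tau populated."""
    spec = PoiseuilleSpec(tau_wall=400.0, n_r=200)
    return spec, snapshot_stress(poiseuille_snapshot(spec), newtonian_params(spec.mu))


@pytest.fixture(scope="session")
def sphere_keyframes():
    """Concentric-sphere keyframes r = 20, 15, 12, 10 mm: analytic volume oracle."""
    radii = (20.0, 15.0, 12.0, 10.0)
    vols = [4.0 / 3.0 * np.pi * r**3 for r in radii]
    return keyframe_set(icosphere(radii[0], subdivisions=3), vols), radii


@pytest.fixture
def toy_snapshot():
    """Two cells, three wall faces: every metric computable by hand."""
    return FlowSnapshot(
        time=0.1,
        cell_volume=np.array([1e-9, 3e-9]),
        cell_centroid=np.zeros((2, 3)),
        cell_velocity=np.array([[4.0, 0, 0], [0, 2.0, 0]]),
        cell_grad_v=np.zeros((2, 3, 3)),
        cell_tau=np.array([350.0, 500.0]),
        wall_area=np.array([1.0e-6, 2.0e-6, 5.0e-6]),
        wall_tau=np.array([350.0, 250.0, 420.0]),
        wall_pressure=np.array([100.0, 200.0, 50.0]),
        wall_group=np.array(["wall-pvl", "wall-pvl", "wall-lv"]),
    )


@pytest.fixture(scope="session")
def table3_drive():
    return SystoleDrive.from_volumes(STUDY_VOLUMES[0] * 1e-9, STUDY_VOLUMES[-1] * 1e-9)


@pytest.fixture
def threshold():
    return ThresholdSpec(tau_c=300.0)
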