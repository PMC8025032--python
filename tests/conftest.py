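import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pactangio as pa

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_run():
    """Noiseless broadband simulation + reconstruction of the reference
    inclusion phantom under flat fluence (shared by simulator and
    acceptance tests; ~10 s)."""
    return pa.phantom_experiment(flat_fluence=True, broadband=True)


@pytest.fixture(scope="session")
def t1_scene():
    """One baseline (pre-treatment) synthetic scene with its ground truth."""
    spec = pa.VascularSceneSpec(seed=11)
    scene, gt = pa.make_vascular_scene(spec)
    return spec, scene, gt


@pytest.fixture(scope="session")
def t1_analysis(t1_scene):
    """Full analysis products of the baseline scene."""
    _, scene, gt = t1_scene
    return pa.analyze_scene(scene, gt)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 0.0
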