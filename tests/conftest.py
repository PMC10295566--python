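import numpy as np
import pytest

from gaitkit import PipelineConfig
from gaitkit.kinematics import AngleSignal
from gaitkit.synthetic import WalkerSpec, generate_walker


@pytest.fixture
def config():
    return PipelineConfig(depth_axis="+z")


@pytest.fixture(scope="session")
def walker():
    """Zero-noise stick-walker with exact truth profiles."""
    spec = WalkerSpec(seed=1)
    pose, truth = generate_walker(spec)
    return spec, pose, truth


def make_signal(theta, visibility=None, fps=30.0, joint="knee", side="near"):
    theta = np.asarray(theta, dtype=float)
    if visibility is None:
        visibility = np.ones_like(theta)
    return AngleSignal(joint, side, theta, np.asarray(visibility, float), fps)
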