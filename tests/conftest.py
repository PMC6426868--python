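import warnings

import numpy as np
import pytest

from infantdot import phantom
from infantdot.config import PipelineConfig
from infantdot.pipeline import StudyContext, build_study


@pytest.fixture(scope="session")
def ctx() -> StudyContext:
    """Default desk-scale study: 40^3 grid at 2 mm, 5x6 probe, Jacobian."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_study(PipelineConfig(seed=0))


@pytest.fixture(scope="session")
def head(ctx):
    return ctx.head


@pytest.fixture(scope="session")
def S(ctx):
    return ctx.S


@pytest.fixture(scope="session")
def small_head():
    """Cheap 24^3 phantom for tests that do not need the full study."""
    return phantom.build_layered_phantom(grid_shape=(24, 24, 24), voxel_size_mm=2.0)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
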