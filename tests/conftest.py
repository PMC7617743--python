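import numpy as np
import pytest

from circumnaut.camera import make_converging_rig
from circumnaut.synthetic import default_scene


@pytest.fixture(scope="session")
def rig():
    return make_converging_rig()


@pytest.fixture(scope="session")
def scene():
    return default_scene()


@pytest.fixture(scope="session")
def scene_points():
    """Random world points inside the plant/support working volume."""
    rng = np.random.default_rng(42)
    return np.column_stack(
        [
            rng.uniform(-50, 150, 300),
            rng.uniform(-80, 80, 300),
            rng.uniform(0, 300, 300),
        ]
    )
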