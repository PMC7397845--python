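import numpy as np
import pytest

from blinktrack import SensorGeometry, load_default_model


@pytest.fixture(scope="session")
def geometry():
    return SensorGeometry()


@pytest.fixture(scope="session")
def indoor_model():
    return load_default_model("indoor")


@pytest.fixture(scope="session")
def outdoor_model():
    return load_default_model("outdoor")


def random_event_arrays(rng: np.random.Generator, n: int, geometry: SensorGeometry):
    """Valid random events, unsorted in time."""
    return (
        rng.integers(0, geometry.width, n),
        rng.integers(0, geometry.height, n),
        rng.integers(0, 10_000_000, n),
        rng.integers(0, 2, n),
    )
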