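import numpy as np
import pytest

from microtarget.annotation import TargetOffsets
from microtarget.kinematics import InitialAlignment
from microtarget.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def example_setup():
    """The worked-example targeting setup: alignment (10, 10) deg with
    target offsets (-3.3, 5.4) deg."""
    return InitialAlignment(10.0, 10.0), TargetOffsets(-3.3, 5.4)


@pytest.fixture(scope="session")
def default_phantom():
    """One noise-free phantom volume + ground truth, shared across tests."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_ground_truth(default_phantom):
    return default_phantom[1]


def random_alignment_offsets(rng, n, tilt_range=30.0, knife_range=45.0, offset_range=85.0):
    """Random targeting setups for property sweeps: alignment tilts within
    realistic machine ranges and offsets bounded away from the degenerate
    +/-90 deg target rotation."""
    for _ in range(n):
        yield (
            InitialAlignment(
                float(rng.uniform(-tilt_range, tilt_range)),
                float(rng.uniform(-knife_range, knife_range)),
            ),
            TargetOffsets(
                float(rng.uniform(-offset_range, offset_range)),
                float(rng.uniform(-offset_range, offset_range)),
            ),
        )
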