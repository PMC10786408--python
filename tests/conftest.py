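import numpy as np
import pytest

from spinocereb import (ArmModel, Topology,
                        generate_flexion_extension, generate_min_jerk)

Q_FLEXED = np.array([1.1, 1.6])
Q_EXTENDED = np.array([0.3, 0.4])


@pytest.fixture(scope="session")
def bell_task():
    """Moderate-speed cyclic flexion-extension benchmark trajectory."""
    return generate_flexion_extension(Q_FLEXED, Q_EXTENDED, 2.3, 0.001)


@pytest.fixture(scope="session")
def short_task():
    """A fast, short task for cheap closed-loop tests."""
    return generate_flexion_extension(Q_FLEXED, Q_EXTENDED, 1.0, 0.001)


@pytest.fixture(scope="session")
def reach():
    return generate_min_jerk(Q_EXTENDED, Q_FLEXED, 1.0, 0.001)


@pytest.fixture(scope="session")
def tiny_topology():
    """Smallest useful network: 2 * 3^4 = 162 granule cells."""
    return Topology(n_mf_per_signal=3, n_pc=8)


@pytest.fixture(scope="session")
def reduced_topology():
    """Reduced-scale network used for closed-loop experiments."""
    return Topology(n_mf_per_signal=5, n_pc=40)


@pytest.fixture(scope="session")
def arm_model():
    return ArmModel()
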