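import numpy as np
import pytest

from velstore import (
    CouplingTerms,
    StateVector,
    TimeConstants,
    VSModel,
    build_pull,
    coupling_from_tilt,
)


@pytest.fixture
def canonical_tcs() -> TimeConstants:
    """Roll/pitch/yaw decay time constants of 5, 5 and 18 s."""
    return TimeConstants(5.0, 5.0, 18.0)


@pytest.fixture
def pull15(canonical_tcs) -> VSModel:
    """Backward-pull model whose subjective up is tilted 15 degrees."""
    return build_pull(
        canonical_tcs, coupling_from_tilt(15.0, "roll-yaw", canonical_tcs)
    )


@pytest.fixture
def yaw_okan_x0() -> StateVector:
    """Canonical post-yaw-stimulation initial state: 20 deg/s in yaw only."""
    return StateVector(0.0, 0.0, 20.0)


def random_model(rng: np.random.Generator, with_gain: bool = True) -> VSModel:
    """A random non-degenerate model in the canonical regime.

    Roll/pitch time constants 2-10 s, yaw 8-30 s with at least a 1 s gap
    to the faster axes, couplings up to +/-0.3 /s, gain in [0.5, 1].
    """
    tau_r = rng.uniform(2.0, 10.0)
    tau_p = rng.uniform(2.0, 10.0)
    tau_y = rng.uniform(max(tau_r, tau_p) + 1.0, 30.0)
    coupling = CouplingTerms(rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3))
    gain = rng.uniform(0.5, 1.0) if with_gain else 1.0
    return VSModel(TimeConstants(tau_r, tau_p, tau_y), coupling, gain)
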