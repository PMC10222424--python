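import numpy as np
import pytest

from unipos_ecg.cardiac_model import (PhantomConfig, StimulusProtocol,
                                      build_phantom, default_probes,
                                      run_simulation)


@pytest.fixture(scope="session")
def small_phantom():
    """100x100 phantom: cheapest grid the builder accepts."""
    return build_phantom(PhantomConfig(grid_shape=(100, 100)))


@pytest.fixture(scope="session")
def default_protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def short_recording(small_phantom, default_protocol):
    """Two stimulus periods on the small phantom (shared across tests)."""
    return run_simulation(small_phantom, default_protocol,
                          default_probes(small_phantom),
                          duration=2 * default_protocol.period)


@pytest.fixture(scope="session")
def steady_recording():
    """Eight beats on the default 150x150 phantom; beats 5+ are near the
    periodic steady state and suitable for morphology checks."""
    phantom = build_phantom(PhantomConfig())
    protocol = StimulusProtocol()
    return run_simulation(phantom, protocol, default_probes(phantom),
                          duration=8 * protocol.period)
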