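import numpy as np
import pytest

from isoload.synth import (
    NoiseConfig,
    ProtocolSpec,
    generate_participant,
    generate_session,
    default_protocols,
)


@pytest.fixture(scope="session")
def participant():
    return generate_participant(3)


@pytest.fixture(scope="session")
def short_protocol():
    """A compact two-set protocol for fast full-channel tests."""
    return ProtocolSpec("MI", 77.0, 2, 6, 60.0, 0.92,
                        baseline_s=30.0, recovery_s=150.0)


@pytest.fixture(scope="session")
def li_protocol():
    return default_protocols()["LI"]


@pytest.fixture(scope="session")
def li_noiseless(participant, li_protocol):
    return generate_session(participant, li_protocol, 42,
                            noise=NoiseConfig.noiseless(), channels=("mech",))


@pytest.fixture(scope="session")
def short_session(participant, short_protocol):
    return generate_session(participant, short_protocol, 11)


@pytest.fixture(scope="session")
def short_session_noiseless(participant, short_protocol):
    return generate_session(participant, short_protocol, 11,
                            noise=NoiseConfig.noiseless())
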