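import pytest

from arteryring.solver import SolverSettings


@pytest.fixture(scope="session")
def settings():
    """Default solver settings shared across the suite."""
    return SolverSettings()
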