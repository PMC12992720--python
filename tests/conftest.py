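import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_consensus():
    """One structured synthetic element shared by read-only tests."""
    from ervscape.synthetic_data import SimParams, make_consensus

    return make_consensus(SimParams(seed=11), "consensusX")
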