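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
def all_requirements():
    """Balanced cofactor requirements for every shipped network."""
    from emplix.networks import balance, shipped_networks

    return {
        key: balance(net)[1] for key, net in shipped_networks().items()
    }
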