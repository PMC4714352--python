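import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: The published 37-nt light-strand replication origin sequence.
OL_SEQUENCE = "CCTTTCCCCCGCCTACTATAGGACTAAAGGCGGGGGA"


@pytest.fixture(scope="session")
def canonical_table():
    from mitochar import load_canonical_table

    return load_canonical_table()


@pytest.fixture(scope="session")
def synthetic_bundle():
    """Default synthetic mitogenome (seed 42): (sequence, table, truth record)."""
    from mitochar import generate_mitogenome

    return generate_mitogenome(seed=42)


@pytest.fixture()
def ol_sequence():
    return OL_SEQUENCE
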