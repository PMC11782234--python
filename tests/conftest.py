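import pytest

from avnode import build_variant


@pytest.fixture(scope="session")
def variant1():
    """Shared variant-1 topology; session scope so the engine's settling,
    threshold and sinus caches are reused across tests."""
    return build_variant(1)


@pytest.fixture(scope="session")
def variant2():
    return build_variant(2)


@pytest.fixture(scope="session")
def variant3():
    return build_variant(3)
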