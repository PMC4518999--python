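import pytest

from thermoflux.tsac import build_constrained_model, build_core_model


@pytest.fixture(scope="session")
def core_model():
    """Constrained core model (hydrogenase constraint set applied).

    Session-scoped: tests must not mutate it (strain/knockout helpers copy).
    """
    return build_constrained_model()


@pytest.fixture(scope="session")
def raw_core_model():
    """Core model before the hydrogenase constraints."""
    return build_core_model()
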