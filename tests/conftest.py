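import pytest

from flavopath import load_table1_fixture
from flavopath.synth import default_config, generate


@pytest.fixture(scope="session")
def fixture_table():
    """The bundled 26-provenance flavonoid content table."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def synth_cohort():
    """One default synthetic cohort (26 samples) with its truth."""
    return generate(default_config(), seed=11)


@pytest.fixture(scope="session")
def synth_large():
    """A large synthetic cohort (n = 498) for estimator checks."""
    cfg = default_config()
    cfg.samples_per_group = (83,) * 6
    return generate(cfg, seed=7)
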