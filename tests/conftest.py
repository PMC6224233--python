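import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from agemeta.synthetic import CompendiumSpec, generate_compendium

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_compendium():
    """Three small studies with planted effects, shared across tests."""
    spec = CompendiumSpec(
        n_studies=3, genes_total=300, n_young=8, n_old=8,
        frac_up=0.1, frac_down=0.1, effect_size_delta=1.2, seed=123,
    )
    return generate_compendium(spec)


@pytest.fixture(scope="session")
def null_compendium():
    """A single-study global-null compendium (no planted effects)."""
    spec = CompendiumSpec(
        n_studies=1, genes_total=2000, n_young=10, n_old=10,
        frac_up=0.0, frac_down=0.0, effect_size_delta=0.0, seed=7,
    )
    return generate_compendium(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
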