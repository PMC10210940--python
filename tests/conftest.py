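import pytest
from hypothesis import HealthCheck, settings

from stcmine.core import PipelineConfig
from stcmine.simulate import SimSpec, make_genome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 4 clades x 30, 20+20+20 decoys."""
    return make_genome(SimSpec(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced fixture for fast end-to-end runs."""
    return make_genome(
        SimSpec(
            family_size=8,
            n_prenyltransferase_like=5,
            n_unrelated=5,
            n_wrong_length=5,
            seed=3,
        )
    )


@pytest.fixture()
def cfg():
    return PipelineConfig()
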