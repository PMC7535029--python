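import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast study-generation spec shared across tests."""
    from dictqc.synth import CohortSpec

    return CohortSpec(
        n_studies=3,
        element_count_range=(60, 180),
        forms_range=(3, 8),
        seed=20240
    )


@pytest.fixture(scope="session")
def small_package(small_spec):
    from dictqc.synth import generate_study

    return generate_study(small_spec, 0)
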