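import pytest

from tastecoda.extraction import build_response_table, filter_tracked
from tastecoda.synth import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort (both groups, seed 1), shared read-only."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_table(default_cohort):
    imaging = [s for s in default_cohort.sessions if s.day_kind != "conditioning"]
    tracked, _ = filter_tracked(imaging)
    return build_response_table(tracked)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_animals_per_group=2, n_cells_per_animal=10, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    imaging = [s for s in small_cohort.sessions if s.day_kind != "conditioning"]
    tracked, _ = filter_tracked(imaging)
    return build_response_table(tracked)
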