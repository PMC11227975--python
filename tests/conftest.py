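import numpy as np
import pytest

from tauspread import CohortConfig, generate_cohort

SMALL_NETWORK_SIZES = (9, 11, 7, 7, 4, 9, 13)  # 60 regions, same 7 networks


def small_config(**overrides) -> CohortConfig:
    """A fast cohort configuration for unit tests (60 regions, 15 template subjects)."""
    kwargs = dict(
        n_subjects=60,
        n_regions=60,
        network_sizes=SMALL_NETWORK_SIZES,
        n_template_subjects=15,
        n_timeseries_frames=120,
        seed=11,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
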