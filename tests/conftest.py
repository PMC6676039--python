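import numpy as np
import pytest

from scatterhist.synthetic import (
    SyntheticCohortConfig,
    generate_cohort,
    generate_exact_cohort,
)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Default-generator cohort with all noise sources off."""
    config = SyntheticCohortConfig(
        seed=11, noise_sd=0.0, fraction_noise_sd=0.0, pixel_jitter_sd=0.0
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def exact_cohort():
    """Noise-free cohort whose curves lie exactly in the fitted families."""
    config = SyntheticCohortConfig(seed=2)
    return generate_exact_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SyntheticCohortConfig(seed=7))


@pytest.fixture(scope="session")
def exact_loo(exact_cohort):
    """LOO-CV predictions on the exact-family cohort (expensive; shared)."""
    from scatterhist.pipeline import loo_cv

    cohort, _ = exact_cohort
    return loo_cv(cohort)


@pytest.fixture(scope="session")
def noise_free_loo(noise_free_cohort):
    """LOO-CV predictions on the zero-noise default-generator cohort."""
    from scatterhist.pipeline import loo_cv

    cohort, _, _ = noise_free_cohort
    return loo_cv(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
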