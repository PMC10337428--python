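import pytest

from lifetriage import (
    DEFAULT_PARAMS,
    DEFAULT_THRESHOLDS,
    GeneratorConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def thresholds():
    return DEFAULT_THRESHOLDS


@pytest.fixture(scope="session")
def cohort_small():
    """A 2,000-patient seeded subsample of the default cohort."""
    return generate_cohort(GeneratorConfig.default(seed=7, max_patients=2000))


@pytest.fixture(scope="session")
def cohort_large():
    """A 12,000-patient seeded subsample for calibration checks."""
    return generate_cohort(GeneratorConfig.default(seed=11, max_patients=12000))
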