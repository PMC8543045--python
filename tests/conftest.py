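import numpy as np
import pytest

from ecgnoise import (
    CohortConfig,
    generate_cohort,
    generate_noise_bank,
    generate_record,
)


@pytest.fixture(scope="session")
def bank500():
    """Full 30-minute noise bank at 500 Hz, shared across tests."""
    return generate_noise_bank(500, 20260929)


@pytest.fixture(scope="session")
def normal_record():
    return generate_record("Normal", 30.0, 500.0, np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny short-duration cohort for plumbing tests (not study-scale)."""
    cfg = CohortConfig(
        counts={"AF": 4, "Normal": 4, "STD": 4},
        duration_range_s=(8.0, 14.0),
        seed=7,
    )
    return generate_cohort(cfg)
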