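import numpy as np
import pytest

from dyadsync import PupilTrace, SyntheticConfig, assemble_dyad


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def dyad_and_truth(default_config):
    """One full synthetic dyad shared across tests (read-only)."""
    return assemble_dyad(default_config, dyad_id="dyad01")


@pytest.fixture
def ramp_trace() -> PupilTrace:
    """Noiseless linear trace d(t) = 4 + 0.1 t at 200 Hz over 10 s."""
    t = np.arange(2000) / 200.0
    return PupilTrace(t, 4.0 + 0.1 * t, np.ones(t.size, dtype=bool))


def random_masked_trace(rng: np.random.Generator, n: int = 400) -> PupilTrace:
    """Small random trace with a random validity mask (>= 3 valid samples)."""
    t = np.arange(n) / 200.0
    d = 5.0 + rng.normal(0, 0.2, n)
    valid = rng.uniform(size=n) > 0.3
    while valid.sum() < 3:
        valid[rng.integers(n)] = True
    return PupilTrace(t, np.where(valid, d, np.nan), valid)
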