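import numpy as np
import pytest

from cyclesync import NoiseSpec, SimulationConfig, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_noise():
    return NoiseSpec(mean_tau=24.0, sigma_tau=3.0, sigma_dna0=0.05)


@pytest.fixture
def zero_noise():
    return NoiseSpec(mean_tau=24.0, sigma_tau=0.0, sigma_dna0=0.0)


@pytest.fixture
def small_sync_timecourse(default_noise):
    """200-cell synchronized run, cheap enough for unit tests."""
    config = SimulationConfig(n_cells=200, noise=default_noise, seed=42)
    return simulate_population(config)


@pytest.fixture
def small_async_timecourse(default_noise):
    config = SimulationConfig(
        n_cells=200, noise=default_noise, init_mode="asynchronous", seed=43
    )
    return simulate_population(config)


def kuiper_brute_force(x1, x2):
    """Independent oracle: evaluate both step CDFs at every pooled point."""
    x1 = list(x1)
    x2 = list(x2)
    pooled = sorted(set(x1) | set(x2))

    def cdf(sample, v):
        return sum(1 for s in sample if s <= v) / len(sample)

    d_plus = max(max(cdf(x1, v) - cdf(x2, v) for v in pooled), 0.0)
    d_minus = max(max(cdf(x2, v) - cdf(x1, v) for v in pooled), 0.0)
    return d_plus + d_minus
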