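import numpy as np
import pytest

from ervscan import SimulationConfig, simulate_annotation, simulate_counts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact planted-young study: 40 subfamilies, 10 vs 5 samples.

    8 of 40 planted keeps the Mann-Whitney age contrast powered (expected
    two-sided p below 0.01 when every planted subfamily is young).
    """
    return SimulationConfig(
        seed=42,
        n_subfamilies=40,
        n_genes=10,
        n_chromosomes=2,
        chromosome_length_bp=1_200_000,
        genic_overlap_fraction=0.2,
        n_planted=8,
        planted_fold_change=8.0,
        planted_age_tier="young",
        baseline_mean_range=(50.0, 150.0),
        n_non_icu=6,
        n_icu=4,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate_annotation(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_annotation):
    return simulate_counts(small_config, small_annotation.truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
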