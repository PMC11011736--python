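import numpy as np
import pytest

from craterspec import CD_LINES, SyntheticConfig, generate, split_by_group

CAL_GROUPS = ["Group1", "Group2", "Group3"]
PRED_GROUPS = ["Group4"]


@pytest.fixture(scope="session")
def benchmark():
    """The standard six-brand benchmark dataset (fixed seed)."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def benchmark_split(benchmark):
    return split_by_group(benchmark, CAL_GROUPS, PRED_GROUPS)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Homogeneous noise-free dataset: intensities exactly linear in concentration."""
    cfg = SyntheticConfig(seed=2, noise_cv=0.0, ref_cv=0.0, brand_factors=(1.0,) * 6)
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cd_line():
    return CD_LINES[2]  # Cd I 228.80 nm
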