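import numpy as np
import pytest

from patchrefine.bench import run_benchmark_seed
from patchrefine.synthetic import SyntheticConfig, generate_pair

N_BENCH_SEEDS = 10


@pytest.fixture(scope="session")
def bench_results():
    """Full training/evaluation benchmark over several seeds (slow, shared)."""
    return [run_benchmark_seed(seed) for seed in range(N_BENCH_SEEDS)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def synth_pair():
    cfg = SyntheticConfig(image_size=(96, 96), seed=7)
    image, mask, hard = generate_pair(cfg, 0)
    return image, mask, hard
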