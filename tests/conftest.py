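import numpy as np
import pytest

from chaperkit.synthetic import (SyntheticSystemConfig,
                                 build_synthetic_scaffold,
                                 simulate_scaffold_and_tails)


@pytest.fixture(scope="session")
def scaffold():
    return build_synthetic_scaffold(SyntheticSystemConfig())


@pytest.fixture(scope="session")
def small_system():
    """Scaffold + energy-refined tail ensemble + truth, modest size."""
    cfg = SyntheticSystemConfig(n_conformers=400, seed=42)
    return simulate_scaffold_and_tails(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
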