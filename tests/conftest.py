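import numpy as np
import pytest

import ipdevo as ip


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_run():
    """A small but non-trivial finished run shared by lineage/stats tests."""
    cfg = ip.ExperimentConfig(
        side=6, total_updates=400, n_replicates=2, mu=0.05, r=0.05, master_seed=9
    )
    return cfg, [ip.run(cfg, replicate=i) for i in range(cfg.n_replicates)]
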