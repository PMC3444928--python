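import numpy as np
import pytest

from polysnp.pipeline import RunConfig, run_discovery
from polysnp.simulate import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset (3 amplicons, 12 genotypes)."""
    return simulate_dataset(SimConfig(n_amplicons=3, depth=10, seed=1))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One reduced-scale end-to-end discovery run shared across tests."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = RunConfig(out_dir=str(out), seed=11,
                    simulate=SimConfig(n_amplicons=6, depth=12, seed=11))
    manifest = run_discovery(cfg)
    return cfg, manifest, out
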