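import numpy as np
import pytest

from peaknorm.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A compact simulated two-sample experiment written to disk once.

    300 common peaks (10% with a true log2 effect of 2), 50 unique peaks per
    sample, 4x global intensity ratio, on a 5 Mb single-chromosome genome.
    """
    config = SimulationConfig(
        n_common=300,
        n_unique1=50,
        n_unique2=50,
        genome={"chr1": 5_000_000},
        min_spacing=4000,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("sim_small")
    experiment = simulate_experiment(config, outdir=outdir)
    return experiment, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
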