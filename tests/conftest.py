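import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

from dhmscan.coverage import SignalTrack, make_track
from dhmscan.simulate import SimConfig, generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20130528)


def track_from_values(values, norm_factor=1.0, starts=None):
    """Build a SignalTrack directly from per-base arrays (test helper)."""
    values = {c: np.asarray(v) for c, v in values.items()}
    sizes = {c: len(v) for c, v in values.items()}
    if starts is None:
        starts = {c: np.zeros(n, dtype=np.int32) for c, n in sizes.items()}
    return SignalTrack(chrom_sizes=sizes, counts=values, starts=starts,
                       norm_factor=norm_factor)


@pytest.fixture(scope="session")
def smoke_config():
    return SimConfig(chrom_sizes={"chrSim": 200_000}, n_genes=20, n_spikes=10,
                     reversal_fraction=1.0, seed=17)


@pytest.fixture(scope="session")
def smoke_experiment(smoke_config):
    """Three-condition smoke-scale simulation with fitted tracks."""
    exp = generate_experiment(smoke_config)
    exp["tracks"] = {c: make_track(r, smoke_config.chrom_sizes)
                     for c, r in exp["reads"].items()}
    return exp
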