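import numpy as np
import pytest

from pollenmir.simdata import SimulationConfig, build_world, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SMALL_CONFIG = SimulationConfig(
    seed=11,
    n_ests=60,
    n_known_mirnas=15,
    n_novel_precursors=8,
    libraries=(("UM", 30_000), ("BCP", 30_000), ("TCP", 30_000)),
    n_de_mirnas=5,
    # at 30k reads per library an RPM of 50 is ~1.5 expected counts;
    # plant fold changes at an abundance the library size can resolve
    de_min_rpm=1000.0,
    n_target_pairs=10,
    n_decoy_targets=2,
)


@pytest.fixture(scope="session")
def small_world():
    """A small deterministic synthetic experiment (in memory)."""
    return build_world(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_simdir(tmp_path_factory):
    """The same small experiment written to disk."""
    outdir = tmp_path_factory.mktemp("sim")
    world = simulate(SMALL_CONFIG, outdir)
    return outdir, world
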