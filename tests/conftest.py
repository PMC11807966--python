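import numpy as np
import pytest

from gliascan.catalogue import load_packaged_catalogue


@pytest.fixture(scope="session")
def catalogue():
    return load_packaged_catalogue()


@pytest.fixture(scope="session")
def by_name(catalogue):
    return {r.name: r for r in catalogue}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small error-free simulated run shared by round-trip tests."""
    from gliascan.simulate import SimConfig, simulate_run

    cfg = SimConfig(
        n_lines=3, templates_per_line=8, error_rate=0.0, pseudogene_fraction=0.0, seed=123
    )
    out = tmp_path_factory.mktemp("sim_clean")
    return simulate_run(cfg, load_packaged_catalogue(), out)
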