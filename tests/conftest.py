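import pytest

from intronpa import SimulationConfig, grass_tree, simulate_dataset


@pytest.fixture(scope="session")
def grass6():
    """Five-grass tree with the Arabidopsis outgroup tip."""
    return grass_tree(with_outgroup=True)


@pytest.fixture(scope="session")
def grass5():
    return grass_tree(with_outgroup=False)


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """A small exact-render synthetic dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("simdata")
    cfg = SimulationConfig(n_clusters=60, seed=11)
    ds = simulate_dataset(cfg, str(outdir))
    return str(outdir), ds
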