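import numpy as np
import pytest

from wmhnet import factors, plsr, synth


@pytest.fixture(scope="session")
def config():
    return synth.SimConfig(seed=7)


@pytest.fixture(scope="session")
def phenotypes(config):
    return synth.simulate_phenotypes(config)


@pytest.fixture(scope="session")
def atlas():
    return synth.make_atlas(7)


@pytest.fixture(scope="session")
def connectomes(config, phenotypes, atlas):
    cs = synth.simulate_connectomes(phenotypes, atlas, config)
    cs.validate()
    return cs


@pytest.fixture(scope="session")
def scored(phenotypes):
    return factors.fluid_factor(phenotypes)


@pytest.fixture(scope="session")
def edge_map():
    return plsr.EdgeMap(246)


@pytest.fixture(scope="session")
def xy(connectomes, scored, edge_map):
    X = edge_map.stack(connectomes.matrices)
    Y = np.column_stack(
        [
            scored["age_years"].to_numpy(float),
            scored["fluid"].to_numpy(float),
            np.log(scored["wmh_global_k07"].to_numpy(float)),
        ]
    )
    return X, Y
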