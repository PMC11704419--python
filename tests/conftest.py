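import numpy as np
import pytest

import spotgae as sg


@pytest.fixture(scope="session")
def hex_small():
    """Small hex fixture: 10x10 lattice, 60 genes, 4 bands."""
    cfg = sg.standard_small(rows=10, cols=10, n_genes=60)
    ds, truth = sg.make_dataset(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def trained_small(hex_small):
    """A short seeded training run shared by downstream tests."""
    ds, _ = hex_small
    pp = sg.preprocess(ds, sg.PreprocessConfig())
    g = sg.build_sng_knn(pp.coords, 6)
    cfg = sg.TrainingConfig(dims=(64, 16), epochs=60, seed=11)
    params, log = sg.fit(pp, g, cfg)
    return pp, g, params, log


@pytest.fixture
def tiny_graph():
    """5-node graph: a path 0-1-2-3 plus isolated node 4."""
    return sg.SpatialNeighborGraph(5, {(0, 1), (1, 2), (2, 3)}, "knn")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
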