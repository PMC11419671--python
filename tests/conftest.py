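import numpy as np
import pytest

from trlmap.pipeline import make_demo
from trlmap.synthetic_data import AtlasConfig, simulate_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """A compact atlas with one planted doublet cluster and one enriched cluster."""
    config = AtlasConfig(
        n_clusters=6,
        cells_per_cluster=60,
        n_genes=60,
        doublet_rate=0.03,
        doublet_cluster_ids=frozenset({"C05"}),
        doublet_cluster_rate=0.5,
        n_clonotypes=80,
        n_reactive_clonotypes=12,
        reactive_cluster_weights={"C00": 0.8, "C01": 0.04, "C02": 0.04,
                                  "C03": 0.04, "C04": 0.04, "C05": 0.04},
        seed=11,
    )
    return config, simulate_atlas(config)


@pytest.fixture(scope="session")
def demo_workspace(tmp_path_factory):
    ws = tmp_path_factory.mktemp("demo_ws")
    return make_demo(seed=7, outdir=ws)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
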