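import numpy as np
import pytest

from symbiomics.simulate import PathwaySpec, SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A reduced study layout: 2+2 ingroup isolates, 1 outgroup, 8 short genes."""
    return SimulationConfig(
        n_isolates_clade_a=2,
        n_isolates_clade_b=2,
        n_outgroups=1,
        gene_length_codons=120,
        pathway_plan=[
            PathwaySpec("histidine", "EAA", 2, 0.15, 1),
            PathwaySpec("thiamine", "vitamin", 2, 0.10, 1),
            PathwaySpec("background", "background", 4, 0.20, 0),
        ],
        tree_depth=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    """Generated file bundle for the small config (shared across tests)."""
    out = tmp_path_factory.mktemp("bundle")
    truth, paths = generate_dataset(small_config, str(out))
    return {"config": small_config, "truth": truth, "paths": paths, "dir": str(out)}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
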