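import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from panhgt.synthetic_data import (  # noqa: E402
    HGTPlanEntry,
    SimulationConfig,
    simulate_collection,
)


@pytest.fixture(scope="session")
def small_config():
    """Cheap simulation used by most integration-style unit tests."""
    return SimulationConfig(n_species=3, genomes_per_species=2,
                            core_families=24, accessory_families=10,
                            mean_gene_len_codons=100, intergenic_bp=300,
                            plasmids_per_genome=2, plasmid_groups=2, seed=7)


@pytest.fixture(scope="session")
def small_collection(small_config):
    return simulate_collection(small_config)


@pytest.fixture(scope="session")
def small_hgt_collection(small_config):
    import dataclasses

    cfg = dataclasses.replace(
        small_config, hgt_plan=(HGTPlanEntry("S1", "S2", 8, 0.004),))
    return simulate_collection(cfg)
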