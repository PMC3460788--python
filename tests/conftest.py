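import pytest

from vrvar.synthetic_data import SimulationConfig, StrainGroup, generate_reference, simulate_strains

SMALL_GROUPS = (
    StrainGroup("lab", 4, 1.2, 0.8, "lab_derived", "domesticus"),
    StrainGroup("wild_dom", 1, 1.5, 0.0, "wild_derived", "domesticus"),
    StrainGroup("wild_mus", 1, 4.7, 0.0, "wild_derived", "musculus"),
    StrainGroup("wild_spr", 1, 13.2, 0.0, "wild_derived", "spretus"),
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_clusters=10, genes_per_cluster=3, seed=11,
                            strain_groups=SMALL_GROUPS)


@pytest.fixture(scope="session")
def reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def strain_data(reference, small_config):
    return simulate_strains(reference, small_config)


@pytest.fixture(scope="session")
def rich_config():
    """High event rates so every planted-event kind is well represented."""
    return SimulationConfig(n_clusters=15, genes_per_cluster=2, seed=21,
                            strain_groups=SMALL_GROUPS, stop_gain_rate=0.4,
                            indel_rate=0.4, deletion_rate=0.3,
                            duplication_rate=0.3, unresolvable_rate=0.1)


@pytest.fixture(scope="session")
def rich_reference(rich_config):
    return generate_reference(rich_config)


@pytest.fixture(scope="session")
def rich_data(rich_reference, rich_config):
    return simulate_strains(rich_reference, rich_config)
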