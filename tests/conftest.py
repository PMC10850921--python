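import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_reference():
    from cplineage import synthdata

    return synthdata.simulate_reference_genome(1, (20000, 5000, 4000, 5000))


@pytest.fixture(scope="session")
def lineage_sim(small_reference):
    """Five-taxon lineage simulation with planted SNPs and INDELs."""
    from cplineage import synthdata

    tree = synthdata.fig_tree(scale=3, indels_per_branch=2)
    genomes, truth = synthdata.simulate_lineages(small_reference, tree, seed=7)
    return genomes, truth


@pytest.fixture(scope="session")
def marker_panel():
    from cplineage import datasets

    return datasets.load_marker_panel()


@pytest.fixture(scope="session")
def genotype_table():
    from cplineage import datasets

    return datasets.load_genotype_table()


@pytest.fixture(scope="session")
def flow_peaks():
    from cplineage import datasets

    return datasets.load_flow_peaks()


@pytest.fixture(scope="session")
def expanded_accessions(genotype_table):
    from cplineage import synthdata

    return synthdata.expand_plastid_table(genotype_table)
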