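import pytest

from polyevol import syndata
from polyevol.syndata import DivergenceSchedule


@pytest.fixture(scope="session")
def small_allopolyploid():
    """A small assembled allotetraploid simulation shared across tests."""
    genomes, truth = syndata.gen_allopolyploid(
        DivergenceSchedule([("AD", 0.04)]), 30, seed=7, n_codons=300)
    return genomes, truth


@pytest.fixture(scope="session")
def pseudogene_world():
    """Genome with 20 inserted pseudogenes of known category."""
    genomes, _ = syndata.gen_allopolyploid(
        DivergenceSchedule([("AD", 0.04)]), 30, seed=17, n_codons=300)
    g2, loci, truth = syndata.gen_pseudogenes(
        genomes["At"], {"duplicated": 1, "processed": 1, "fragmented": 1},
        20, seed=18)
    return g2, loci, truth
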