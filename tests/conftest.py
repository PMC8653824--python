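import pytest

from marktax import SimConfig, simulate
from marktax.taxonomy import Rank


@pytest.fixture(scope="session")
def small_truth():
    """A small but fully structured simulated data set shared across tests."""
    config = SimConfig(
        n_phyla=2,
        classes_per_phylum=2,
        orders_per_class=2,
        families_per_order=2,
        genera_per_family=2,
        species_per_genus=2,
        genomes_per_species=2,
        seq_length=400,
        multi_copy_fraction=0.1,
        decoy_fraction=0.1,
        seed=11,
    )
    return simulate(config)


@pytest.fixture()
def toy_taxonomy():
    """Three genomes: two species of one genus plus one sibling genus."""
    from marktax import Lineage, TaxonomyTable

    def lin(genus, species):
        return Lineage(
            names={
                Rank.PHYLUM: "Phy",
                Rank.CLASS: "Cls",
                Rank.ORDER: "Ord",
                Rank.FAMILY: "Fam",
                Rank.GENUS: genus,
                Rank.SPECIES: species,
            }
        )

    return TaxonomyTable(
        {
            "A1": lin("GenA", "GenA sp1"),
            "A2": lin("GenA", "GenA sp2"),
            "B1": lin("GenB", "GenB sp1"),
        }
    )
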