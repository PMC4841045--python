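import pytest

from taxopep import (
    DigestionParams,
    SimulationConfig,
    TaxonomyNode,
    TaxonomyTree,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def toy_tree() -> TaxonomyTree:
    """Two bacterial phyla (one genus with two species, one genus with one)
    plus a human-like outgroup under a second superkingdom."""
    return TaxonomyTree(
        [
            TaxonomyNode("root", "root", "root", None),
            TaxonomyNode("bact", "Bacteria", "superkingdom", "root"),
            TaxonomyNode("firm", "Firmicutes", "phylum", "bact"),
            TaxonomyNode("strep", "Streptococcus", "genus", "firm"),
            TaxonomyNode("s_mitis", "Streptococcus mitis", "species", "strep"),
            TaxonomyNode("s_oralis", "Streptococcus oralis", "species", "strep"),
            TaxonomyNode("bacteroidetes", "Bacteroidetes", "phylum", "bact"),
            TaxonomyNode("prevotella", "Prevotella", "genus", "bacteroidetes"),
            TaxonomyNode("p_oris", "Prevotella oris", "species", "prevotella"),
            TaxonomyNode("euk", "Eukaryota", "superkingdom", "root"),
            TaxonomyNode("chordata", "Chordata", "phylum", "euk"),
            TaxonomyNode("homo", "Homo", "genus", "chordata"),
            TaxonomyNode("h_sapiens", "Homo sapiens", "species", "homo"),
        ]
    )


@pytest.fixture(scope="session")
def default_params() -> DigestionParams:
    return DigestionParams()


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset shared across tests (read-only)."""
    config = SimulationConfig(
        seed=11,
        n_phyla=3,
        genera_per_phylum=2,
        species_per_genus=2,
        proteins_per_species=6,
        protein_length_mean=180.0,
        protein_length_sd=40.0,
        cross_species_copy_prob=0.4,
        samples_per_state=3,
        fold_changes={"gen01.01": 0.5},
    )
    return simulate_dataset(config)
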