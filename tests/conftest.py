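import numpy as np
import pytest

from paleologs import (
    GeneTree,
    SpeciesInfo,
    SpeciesTree,
    default_species_tree,
    map_genes_to_species,
    reconcile,
)


@pytest.fixture(scope="session")
def two_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("(Atha,Orsa)Root;")


@pytest.fixture(scope="session")
def three_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("(Atha,(Orsa,Zzma)Inner)Root;")


@pytest.fixture(scope="session")
def angiosperm_tree() -> SpeciesTree:
    return default_species_tree()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def reconcile_newick(newick: str, species_tree: SpeciesTree):
    """Parse a gene tree, map leaves by species-code prefix, reconcile."""
    gt = GeneTree.from_newick(newick)
    gmap = map_genes_to_species(gt, set(species_tree.species()))
    return reconcile(gt, species_tree, gmap)
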