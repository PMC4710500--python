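"""Shared fixtures: small deterministic communities and a toy taxonomy."""

import pytest

from metatx import simulate
from metatx.taxonomy import TaxNode, TaxonomyTree


@pytest.fixture(scope="session")
def small_community():
    """A 28-gene three-member community with 10% rRNA and 1% error."""
    spec, data = simulate.three_member_community(seed=0, genes_per_member=(10, 10, 8))
    reads, truth = simulate.simulate_reads(spec, data)
    return spec, data, reads, truth


@pytest.fixture(scope="session")
def toy_tree():
    """root -> Bacteria -> {Firmicutes -> Clostridia -> Clostridiales,
    Bacteroidetes -> Bacteroidia -> Bacteroidales} with two genera each."""
    nodes = [
        TaxNode(1, 1, "no rank", "root"),
        TaxNode(2, 1, "superkingdom", "Bacteria"),
        TaxNode(10, 2, "phylum", "Firmicutes"),
        TaxNode(11, 10, "class", "Clostridia"),
        TaxNode(12, 11, "order", "Clostridiales"),
        TaxNode(13, 12, "family", "Clostridiaceae"),
        TaxNode(14, 13, "genus", "Clostridium"),
        TaxNode(15, 14, "species", "Clostridium a"),
        TaxNode(16, 13, "genus", "Anaerotruncus"),
        TaxNode(17, 16, "species", "Anaerotruncus b"),
        TaxNode(20, 2, "phylum", "Bacteroidetes"),
        TaxNode(21, 20, "class", "Bacteroidia"),
        TaxNode(22, 21, "order", "Bacteroidales"),
        TaxNode(23, 22, "family", "Bacteroidaceae"),
        TaxNode(24, 23, "genus", "Bacteroides"),
        TaxNode(25, 24, "species", "Bacteroides c"),
    ]
    return TaxonomyTree(nodes)
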