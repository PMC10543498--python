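"""Shared fixtures: toy taxonomies and small synthetic communities."""

from __future__ import annotations

import pytest

from microatlas.taxonomy import Taxonomy, TaxonomyNode


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    """root=1 -> Bacteria=2 -> GenusA=10 {spA1=100, spA2=101}; GenusB=11 -> spB1=110."""
    return Taxonomy(
        [
            TaxonomyNode(1, 1, "root", "root"),
            TaxonomyNode(2, 1, "superkingdom", "Bacteria"),
            TaxonomyNode(10, 2, "genus", "GenusA"),
            TaxonomyNode(11, 2, "genus", "GenusB"),
            TaxonomyNode(100, 10, "species", "spA1"),
            TaxonomyNode(101, 10, "species", "spA2"),
            TaxonomyNode(110, 11, "species", "spB1"),
        ]
    )


@pytest.fixture(scope="session")
def small_community():
    """3 genera x 1 species, 10 kb genomes — quick classifier fixtures."""
    from microatlas import synthetic_community

    return synthetic_community(n_genera=3, genome_length=10_000, seed=11)
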