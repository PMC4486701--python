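"""Shared fixtures and random-structure builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from metabarcode.taxonomy import (
    CANONICAL_RANKS,
    NO_RANK,
    TaxNode,
    Taxonomy,
    build_guide_tree,
)


def random_taxonomy(rng: np.random.Generator, n_nodes: int) -> Taxonomy:
    """A random rooted tree with arbitrary rank labels (root = kingdom)."""
    nodes = {1: TaxNode(1, 1, "kingdom", "root")}
    ranks = list(CANONICAL_RANKS[1:]) + [NO_RANK] * 3
    for nid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, nid))
        rank = ranks[int(rng.integers(len(ranks)))]
        nodes[nid] = TaxNode(nid, parent, rank, f"n{nid}")
    return Taxonomy(nodes)


def random_guide(rng: np.random.Generator, taxonomy: Taxonomy, n_refs: int):
    """Hang ``n_refs`` references at random (possibly internal) nodes."""
    ids = sorted(taxonomy.nodes)
    ref_map = {
        f"r{i}": int(ids[int(rng.integers(len(ids)))]) for i in range(n_refs)
    }
    return build_guide_tree(taxonomy, ref_map)


@pytest.fixture
def mini_taxonomy() -> Taxonomy:
    """Seven-rank toy taxonomy with an uncultured leaf and a rank gap.

    Nodes 1-7 form a complete kingdom->species lineage; node 8 is a second
    species of the same genus; node 10 is a complete-lineage species named
    "uncultured bacterium"; node 11 hangs directly off the family (its
    lineage lacks the genus rank).
    """
    nodes = {
        1: TaxNode(1, 1, "kingdom", "Bacteria"),
        2: TaxNode(2, 1, "phylum", "Proteobacteria"),
        3: TaxNode(3, 2, "class", "Gammaproteobacteria"),
        4: TaxNode(4, 3, "order", "Enterobacterales"),
        5: TaxNode(5, 4, "family", "Enterobacteriaceae"),
        6: TaxNode(6, 5, "genus", "Escherichia"),
        7: TaxNode(7, 6, "species", "Escherichia coli"),
        8: TaxNode(8, 6, "species", "Escherichia fergusonii"),
        9: TaxNode(9, 5, "genus", "Salmonella"),
        10: TaxNode(10, 9, "species", "uncultured bacterium"),
        11: TaxNode(11, 5, "species", "Enterobacteriaceae sp."),
    }
    return Taxonomy(nodes)


@pytest.fixture
def mini_guide(mini_taxonomy):
    """Five references: two complete species, one genus-level, one
    uncultured, one with a gapped lineage."""
    return build_guide_tree(
        mini_taxonomy,
        {"refA": 7, "refB": 8, "refG": 6, "refU": 10, "refM": 11},
    )
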