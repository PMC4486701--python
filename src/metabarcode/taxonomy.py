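"""Ranked taxonomy model, NCBI-dump parsing, LCA queries and the guide tree.

The substrate for taxonomic binning is a rooted tree whose nodes carry one
of the seven canonical ranks (kingdom, phylum, class, order, family, genus,
species) or ``no-rank`` for intermediate levels.  Intermediate NCBI ranks
(subclass, tribe, ...) are folded onto ``no-rank`` at load time so that rank
projection only ever sees the canonical ladder.

Reference sequences hang at their annotated node; :class:`GuideTree` caches
per-subtree reference counts so assignment can score candidate nodes cheaply.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

CANONICAL_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
NO_RANK = "no-rank"
RANK_DEPTH = {rank: i for i, rank in enumerate(CANONICAL_RANKS)}

#: Lineage name fragments that mark a reference as taxonomically uninformative.
DEFAULT_UNCULTURED_PATTERNS = ("uncultured", "environmental sample", "unidentified")

_VALID_RANKS = set(CANONICAL_RANKS) | {NO_RANK}
_RANK_ALIASES = {
    "no rank": NO_RANK,
    "norank": NO_RANK,
    "superkingdom": "kingdom",
    "domain": "kingdom",
}


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy table or guide-tree mapping."""


@dataclass(frozen=True)
class TaxNode:
    """One taxonomy node; the root is its own parent."""

    node_id: int
    parent_id: int
    rank: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.rank not in _VALID_RANKS:
            raise TaxonomyError(
                f"invalid rank {self.rank!r} for node {self.node_id}; "
                f"expected one of {sorted(_VALID_RANKS)}"
            )


class Taxonomy:
    """A validated rooted tree of :class:`TaxNode` objects.

    Validation guarantees a unique root (the single node with
    ``parent_id == node_id``), that every parent resolves, and that every
    node reaches the root (no cycles).
    """

    def __init__(self, nodes: Mapping[int, TaxNode]):
        self.nodes: dict[int, TaxNode] = dict(nodes)
        if not self.nodes:
            raise TaxonomyError("taxonomy is empty")
        self.root_id = self._validate()
        self._children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.node_id != self.root_id:
                self._children[node.parent_id].append(node.node_id)
        for kids in self._children.values():
            kids.sort()
        self._depth: dict[int, int] = {}

    def _validate(self) -> int:
        roots = [n.node_id for n in self.nodes.values() if n.parent_id == n.node_id]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"node {node.node_id} has unknown parent {node.parent_id}"
                )
        resolved = {root}
        for nid in self.nodes:
            trail: list[int] = []
            seen: set[int] = set()
            cur = nid
            while cur not in resolved:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected involving node {cur}")
                seen.add(cur)
                trail.append(cur)
                cur = self.nodes[cur].parent_id
            resolved.update(trail)
        return root

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.nodes

    def node(self, node_id: int) -> TaxNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown taxonomy node {node_id}") from None

    def parent(self, node_id: int) -> int | None:
        node = self.node(node_id)
        return None if node_id == self.root_id else node.parent_id

    def children(self, node_id: int) -> list[int]:
        self.node(node_id)
        return self._children[node_id]

    def path_to_root(self, node_id: int) -> list[int]:
        """Node ids from ``node_id`` (first) up to the root (last), inclusive."""
        path = [self.node(node_id).node_id]
        while path[-1] != self.root_id:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def depth(self, node_id: int) -> int:
        """Edges between ``node_id`` and the root (root has depth 0)."""
        if node_id not in self._depth:
            self._depth[node_id] = len(self.path_to_root(node_id)) - 1
        return self._depth[node_id]

    def iter_postorder(self) -> Iterator[int]:
        stack: list[tuple[int, bool]] = [(self.root_id, False)]
        while stack:
            nid, expanded = stack.pop()
            if expanded:
                yield nid
            else:
                stack.append((nid, True))
                for child in self._children[nid]:
                    stack.append((child, False))


@dataclass
class GuideTree:
    """The taxonomy annotated with where each reference sequence hangs.

    ``leaves_under[n]`` counts the reference sequences mapped anywhere in the
    subtree rooted at ``n`` (references annotated at internal nodes count at
    that node).
    """

    taxonomy: Taxonomy
    ref_to_leaf: dict[str, int]
    refs_at: dict[int, tuple[str, ...]]
    leaves_under: dict[int, int]

    @property
    def n_refs(self) -> int:
        return len(self.ref_to_leaf)


def lca(taxonomy: Taxonomy, node_ids: Iterable[int]) -> int:
    """Deepest node ancestral to (or equal to) every node in ``node_ids``."""
    ids = list(node_ids)
    if not ids:
        raise ValueError("lca requires a non-empty set of node ids")
    paths = [list(reversed(taxonomy.path_to_root(n))) for n in ids]
    ancestor = taxonomy.root_id
    for level in zip(*paths):
        if all(x == level[0] for x in level):
            ancestor = level[0]
        else:
            break
    return ancestor


def rank_ancestor(taxonomy: Taxonomy, node_id: int, rank: str) -> int | None:
    """The unique ancestor-or-self of ``node_id`` at ``rank``, or ``None``.

    ``None`` signals that the lineage has no node at that canonical rank.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"rank must be one of {CANONICAL_RANKS}, got {rank!r}")
    for nid in taxonomy.path_to_root(node_id):
        if taxonomy.nodes[nid].rank == rank:
            return nid
    return None


def is_complete_path(
    taxonomy: Taxonomy,
    node_id: int,
    uncultured_patterns: Iterable[str] = DEFAULT_UNCULTURED_PATTERNS,
) -> bool:
    """Whether the lineage covers all seven ranks with informative names.

    A lineage is complete when every canonical rank is populated and no
    lineage name contains one of the placeholder patterns (case-insensitive
    substring match, e.g. "uncultured bacterium").
    """
    lineage = [taxonomy.nodes[n] for n in taxonomy.path_to_root(node_id)]
    present = {n.rank for n in lineage}
    if not all(r in present for r in CANONICAL_RANKS):
        return False
    patterns = [p.lower() for p in uncultured_patterns]
    for node in lineage:
        name = node.name.lower()
        if any(p in name for p in patterns):
            return False
    return True


def build_guide_tree(taxonomy: Taxonomy, ref_to_taxid: Mapping[str, int]) -> GuideTree:
    """Attach reference sequences to the taxonomy and count subtree members."""
    if not ref_to_taxid:
        raise TaxonomyError("guide tree requires at least one mapped reference")
    bad = sorted(str(r) for r, t in ref_to_taxid.items() if t not in taxonomy)
    if bad:
        raise TaxonomyError(
            "reference ids with unresolvable taxids: " + ", ".join(bad)
        )
    refs_at: dict[int, list[str]] = defaultdict(list)
    for ref, taxid in ref_to_taxid.items():
        refs_at[taxid].append(ref)
    leaves_under: dict[int, int] = {}
    for nid in taxonomy.iter_postorder():
        total = len(refs_at.get(nid, ()))
        for child in taxonomy.children(nid):
            total += leaves_under[child]
        leaves_under[nid] = total
    return GuideTree(
        taxonomy=taxonomy,
        ref_to_leaf=dict(ref_to_taxid),
        refs_at={nid: tuple(refs) for nid, refs in refs_at.items()},
        leaves_under=leaves_under,
    )


# ---------------------------------------------------------------------------
# parsing

def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            yield from fh
    elif hasattr(source, "read"):
        yield from source
    else:
        yield from source


def _split_dump_line(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def _normalize_rank(raw: str) -> str:
    rank = raw.strip().lower()
    rank = _RANK_ALIASES.get(rank, rank)
    return rank if rank in _VALID_RANKS else NO_RANK


def load_taxonomy(nodes_table, names_table=None, fmt: str = "ncbi_dump") -> Taxonomy:
    """Load and validate a taxonomy from nodes/names tables.

    ``fmt="ncbi_dump"`` expects the NCBI dump dialect (fields separated by
    ``\\t|\\t``, records terminated by ``\\t|``): nodes carry (id, parent,
    rank), names carry (id, name, unique name, name class) of which only
    "scientific name" rows are used.  ``fmt="tsv"`` is a plain 3-column
    (id, parent, rank) / 2-column (id, name) fallback.

    Ranks outside the canonical seven are loaded as ``no-rank``; duplicate
    node ids, orphan parents, missing roots and cycles raise
    :class:`TaxonomyError`.
    """
    if fmt not in ("ncbi_dump", "tsv"):
        raise ValueError(f"unknown taxonomy format {fmt!r}")

    raw_nodes: dict[int, tuple[int, str]] = {}
    for line in _iter_lines(nodes_table):
        if not line.strip():
            continue
        fields = _split_dump_line(line) if fmt == "ncbi_dump" else line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise TaxonomyError(f"nodes table row has fewer than 3 fields: {line!r}")
        try:
            nid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxonomyError(f"non-integer node/parent id in row {line!r}") from exc
        if nid in raw_nodes:
            raise TaxonomyError(f"duplicate node id {nid}")
        raw_nodes[nid] = (parent, _normalize_rank(fields[2]))

    names: dict[int, str] = {}
    if names_table is not None:
        for line in _iter_lines(names_table):
            if not line.strip():
                continue
            fields = _split_dump_line(line) if fmt == "ncbi_dump" else line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise TaxonomyError(f"names table row has fewer than 2 fields: {line!r}")
            if fmt == "ncbi_dump" and len(fields) >= 4 and fields[3].strip() != "scientific name":
                continue
            names[int(fields[0])] = fields[1].strip()

    nodes = {
        nid: TaxNode(nid, parent, rank, names.get(nid, f"node_{nid}"))
        for nid, (parent, rank) in raw_nodes.items()
    }
    return Taxonomy(nodes)


def write_taxonomy_tsv(taxonomy: Taxonomy, nodes_handle, names_handle) -> None:
    """Write the 3-column TSV fallback dialect (inverse of ``fmt="tsv"``)."""

    def _handle(h, write):
        if isinstance(h, (str, Path)):
            with open(h, "wt") as fh:
                write(fh)
        else:
            write(h)

    def _nodes(fh: io.TextIOBase) -> None:
        for nid in sorted(taxonomy.nodes):
            node = taxonomy.nodes[nid]
            fh.write(f"{node.node_id}\t{node.parent_id}\t{node.rank}\n")

    def _names(fh: io.TextIOBase) -> None:
        for nid in sorted(taxonomy.nodes):
            fh.write(f"{nid}\t{taxonomy.nodes[nid].name}\n")

    _handle(nodes_handle, _nodes)
    _handle(names_handle, _names)
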