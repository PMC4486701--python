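"""Taxonomic assignment of queries and profile aggregation.

Each query's retained candidate taxa are mapped to a single taxonomy node
by minimizing a weighted false-negative/false-positive score over the guide
tree:

    score(n) = q * FN(n) + (1 - q) * FP(n)

where FN(n) counts matched references outside the subtree of ``n`` and
FP(n) counts unmatched guide-tree references inside it.  The minimum is
taken over *every* taxonomy node (ties broken deepest-first, then smallest
node id), so the optimum cannot be missed by a candidate heuristic.  With
``q = 1`` the score reduces to FN alone and the optimum is exactly the
lowest common ancestor of the matched taxa.

Assignments aggregate into cumulative taxonomic profiles: a read assigned
at a species increments that species and every ancestor, so per-rank
tables read off the counts of the nodes at each rank.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .hit_filter import MatchFile
from .taxonomy import CANONICAL_RANKS, GuideTree, Taxonomy

logger = logging.getLogger(__name__)

DEFAULT_Q = 0.5
ASSIGNED = "assigned"
UNASSIGNED = "unassigned"

_RANK_PREFIX = {
    "kingdom": "k__", "phylum": "p__", "class": "c__", "order": "o__",
    "family": "f__", "genus": "g__", "species": "s__",
}


@dataclass(frozen=True)
class Assignment:
    query_id: str
    node_id: int | None
    assigned_rank: str | None
    status: str
    abundance: int = 1

    def __post_init__(self) -> None:
        if (self.status == UNASSIGNED) != (self.node_id is None):
            raise ValueError("status and node_id are inconsistent")


@dataclass
class TaxonomicProfile:
    """Cumulative per-node read counts plus per-rank tables."""

    node_counts: dict[int, int]
    rank_tables: dict[str, dict[int, int]]
    total_assigned: int
    total_unassigned: int


def assign_query(match_taxids: Iterable[int], guide: GuideTree, q: float = DEFAULT_Q) -> int | None:
    """Optimal taxonomy node for one query's matched taxa; None if empty.

    Matched taxa are weighted by their reference multiplicity in the guide
    tree (a matched taxon with no directly mapped reference still counts
    once, which preserves the exact q=1/LCA equivalence).
    """
    ids = {int(t) for t in match_taxids}
    if not ids:
        return None
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    tax = guide.taxonomy
    for t in ids:
        tax.node(t)  # raises KeyError on unresolved taxid

    weight = {t: max(1, len(guide.refs_at.get(t, ()))) for t in ids}
    refs = {t: len(guide.refs_at.get(t, ())) for t in ids}
    total_w = sum(weight.values())

    # matched mass under every node, accumulated along root paths
    w_under: dict[int, int] = defaultdict(int)     # virtual weights, for FN
    r_under: dict[int, int] = defaultdict(int)     # actual matched refs, for FP
    for t in ids:
        for nid in tax.path_to_root(t):
            w_under[nid] += weight[t]
            r_under[nid] += refs[t]

    best_key: tuple[float, int, int] | None = None
    best_node: int | None = None
    for nid in tax.nodes:
        fn = total_w - w_under.get(nid, 0)
        fp = guide.leaves_under[nid] - r_under.get(nid, 0)
        key = (q * fn + (1.0 - q) * fp, -tax.depth(nid), nid)
        if best_key is None or key < best_key:
            best_key = key
            best_node = nid
    return best_node


def _display_rank(taxonomy: Taxonomy, node_id: int) -> str | None:
    """Rank of the node, or of its nearest ranked ancestor for no-rank nodes."""
    for nid in taxonomy.path_to_root(node_id):
        if taxonomy.nodes[nid].rank in CANONICAL_RANKS:
            return taxonomy.nodes[nid].rank
    return None


def assign_all(
    matches: MatchFile,
    guide: GuideTree,
    q: float = DEFAULT_Q,
    abundances: Mapping[str, int] | None = None,
    query_ids: Iterable[str] | None = None,
) -> list[Assignment]:
    """One assignment per query; queries absent from the match file are
    unassigned.  Abundance joins from dereplication when provided (missing
    ids warn and default to 1)."""
    qids = list(query_ids) if query_ids is not None else sorted(matches.entries)
    out: list[Assignment] = []
    missing_abundance = 0
    for qid in qids:
        taxids = matches.taxid_set(qid)
        node = assign_query(taxids, guide, q) if taxids else None
        if abundances is not None:
            if qid in abundances:
                ab = int(abundances[qid])
            else:
                missing_abundance += 1
                ab = 1
        else:
            ab = 1
        if node is None:
            out.append(Assignment(qid, None, None, UNASSIGNED, ab))
        else:
            out.append(
                Assignment(qid, node, _display_rank(guide.taxonomy, node), ASSIGNED, ab)
            )
    if missing_abundance:
        logger.warning(
            "%d queries missing from the abundance table; defaulted to 1",
            missing_abundance,
        )
    return out


def summarize_profile(
    assignments: Iterable[Assignment], taxonomy: Taxonomy
) -> TaxonomicProfile:
    """Cumulative, abundance-weighted counts over the taxonomy."""
    node_counts: dict[int, int] = defaultdict(int)
    total_assigned = 0
    total_unassigned = 0
    for a in assignments:
        if a.node_id is None:
            total_unassigned += a.abundance
            continue
        total_assigned += a.abundance
        for nid in taxonomy.path_to_root(a.node_id):
            node_counts[nid] += a.abundance
    rank_tables = {
        rank: {
            nid: c
            for nid, c in node_counts.items()
            if taxonomy.nodes[nid].rank == rank
        }
        for rank in CANONICAL_RANKS
    }
    return TaxonomicProfile(dict(node_counts), rank_tables, total_assigned, total_unassigned)


def lineage_string(taxonomy: Taxonomy, node_id: int) -> str:
    """Rank-prefixed lineage string, e.g. ``k__Bacteria;p__...;s__...``."""
    by_rank: dict[str, str] = {}
    for nid in taxonomy.path_to_root(node_id):
        node = taxonomy.nodes[nid]
        if node.rank in _RANK_PREFIX and node.rank not in by_rank:
            by_rank[node.rank] = node.name
    parts = [
        _RANK_PREFIX[r] + by_rank.get(r, "") for r in CANONICAL_RANKS if r in by_rank
    ]
    return ";".join(parts)


# ---------------------------------------------------------------------------
# outputs

def write_per_read_csv(
    assignments: Iterable[Assignment], taxonomy: Taxonomy, handle_or_path
) -> None:
    def _write(fh):
        w = csv.writer(fh)
        w.writerow(["query_id", "taxid", "name", "rank", "lineage", "abundance"])
        for a in assignments:
            if a.node_id is None:
                w.writerow([a.query_id, "", "", "", "", a.abundance])
            else:
                node = taxonomy.nodes[a.node_id]
                w.writerow(
                    [
                        a.query_id, a.node_id, node.name,
                        a.assigned_rank or "", lineage_string(taxonomy, a.node_id),
                        a.abundance,
                    ]
                )

    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "wt", newline="") as fh:
            _write(fh)
    else:
        _write(handle_or_path)


def read_per_read_csv(source, taxonomy: Taxonomy) -> list[Assignment]:
    """Inverse of :func:`write_per_read_csv` sufficient to rebuild a profile."""

    def _read(fh) -> list[Assignment]:
        out: list[Assignment] = []
        reader = csv.reader(fh)
        next(reader, None)
        for row in reader:
            if not row:
                continue
            qid, taxid, _name, rank, _lineage, abundance = row
            if taxid == "":
                out.append(Assignment(qid, None, None, UNASSIGNED, int(abundance)))
            else:
                out.append(
                    Assignment(qid, int(taxid), rank or None, ASSIGNED, int(abundance))
                )
        return out

    if isinstance(source, (str, Path)):
        with open(source, "rt", newline="") as fh:
            return _read(fh)
    return _read(source)


def write_rank_counts_csv(
    profile: TaxonomicProfile, taxonomy: Taxonomy, handle_or_path
) -> None:
    def _write(fh):
        w = csv.writer(fh)
        w.writerow(["rank", "taxid", "name", "count"])
        for rank in CANONICAL_RANKS:
            table = profile.rank_tables.get(rank, {})
            for nid, c in sorted(table.items(), key=lambda kv: (-kv[1], kv[0])):
                w.writerow([rank, nid, taxonomy.nodes[nid].name, c])

    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "wt", newline="") as fh:
            _write(fh)
    else:
        _write(handle_or_path)


def write_profile_newick(
    profile: TaxonomicProfile, taxonomy: Taxonomy, handle_or_path
) -> None:
    """Newick tree of observed nodes; node labels carry ``name|count``."""
    observed = {nid for nid, c in profile.node_counts.items() if c > 0}

    def _write(fh):
        if not observed:
            fh.write(";\n")
            return
        from skbio import TreeNode

        nodes: dict[int, TreeNode] = {}
        for nid in sorted(observed, key=taxonomy.depth):
            label = f"{taxonomy.nodes[nid].name}|{profile.node_counts[nid]}"
            t = TreeNode(name=label)
            nodes[nid] = t
            if nid != taxonomy.root_id:
                parent = None
                for anc in taxonomy.path_to_root(nid)[1:]:
                    if anc in nodes:
                        parent = nodes[anc]
                        break
                if parent is not None:
                    parent.append(t)
        root_nid = min(observed, key=taxonomy.depth)
        nodes[root_nid].write(fh)

    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "wt") as fh:
            _write(fh)
    else:
        _write(handle_or_path)


def write_outputs(
    profile: TaxonomicProfile,
    assignments: Sequence[Assignment],
    taxonomy: Taxonomy,
    out_dir,
) -> dict[str, Path]:
    """Emit the per-read CSV, per-rank counts CSV and Newick profile tree."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "per_read": out / "per_read_assignments.csv",
        "rank_counts": out / "rank_counts.csv",
        "tree": out / "profile.nwk",
    }
    write_per_read_csv(assignments, taxonomy, paths["per_read"])
    write_rank_counts_csv(profile, taxonomy, paths["rank_counts"])
    write_profile_newick(profile, taxonomy, paths["tree"])
    return paths
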