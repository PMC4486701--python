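"""End-to-end composition: prep -> similarity search -> filter -> assign.

In production the pipeline consumes alignments produced by an external
aligner (BLAST tabular or SAM).  For self-contained benchmarks this module
also provides :func:`search_hits`, an exhaustive pairwise edit-distance
similarity search (banded, via edlib) that plays the aligner's role so a
complete run needs nothing outside the package, plus
:func:`build_synthetic_dataset`, which wires the synthetic taxonomy,
reference database, community and read simulator into one truth-labeled
dataset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .amplicon_sim import (
    DEFAULT_READ_LEN,
    PrimerPair,
    V5V6_CORE_LEN,
    V5V6_PRIMERS,
    extract_amplicons,
    sample_community,
    simulate_paired_reads,
    simulate_reference_db,
    simulate_taxonomy,
)
from .hit_filter import (
    DEFAULT_BITSCORE_FRACTION,
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    HitRecord,
    MatchFile,
    build_match_file,
)
from .read_prep import (
    DEFAULT_MAX_MISMATCH_RATIO,
    DEFAULT_MIN_LEN,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_PHRED_CUTOFF,
    DereplicatedSet,
    PrepResult,
    ReadPair,
    dereplicate,
    prep_pairs,
)
from .tax_assign import (
    ASSIGNED,
    DEFAULT_Q,
    UNASSIGNED,
    Assignment,
    _display_rank,
    assign_query,
)
from .taxonomy import (
    DEFAULT_UNCULTURED_PATTERNS,
    GuideTree,
    Taxonomy,
    build_guide_tree,
)

_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


def _alignment_columns(cigar: str) -> int:
    return sum(int(n) for n, _ in _CIGAR_OP.findall(cigar))


def search_hits(
    queries: Iterable[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    *,
    max_distance_frac: float = 0.12,
    min_report_identity: float = 90.0,
) -> list[HitRecord]:
    """All-vs-all infix similarity search used in self-contained runs.

    Each query is aligned inside every reference (semi-global mode, so the
    query must fit within the reference); alignments whose edit distance
    exceeds ``max_distance_frac`` of the query length are pruned early.
    Identity is the matched fraction of alignment columns; coverage is 100
    because the whole query aligns in infix mode.  The hit score is the
    count of matched columns, which plays the bit-score's role in the
    best-score tolerance rule.
    """
    hits: list[HitRecord] = []
    for qid, qseq in queries:
        if not qseq:
            continue
        k = max(1, int(len(qseq) * max_distance_frac))
        for rid, rseq in references:
            fast = edlib.align(qseq, rseq, mode="HW", task="distance", k=k)
            if fast["editDistance"] < 0:
                continue
            full = edlib.align(qseq, rseq, mode="HW", task="path")
            columns = _alignment_columns(full["cigar"] or "")
            if columns == 0:
                continue
            dist = full["editDistance"]
            identity = 100.0 * max(columns - dist, 0) / columns
            if identity < min_report_identity:
                continue
            hits.append(
                HitRecord(
                    qid, rid, identity, 100.0, float(max(columns - dist, 0)),
                    (0, len(qseq)), qlen=len(qseq),
                )
            )
    return hits


@dataclass
class PipelineResult:
    """Per-pair assignments plus the intermediate stage artifacts."""

    assignments: list[Assignment]
    prep: PrepResult
    derep: DereplicatedSet
    match_file: MatchFile
    guide: GuideTree


def run_pipeline(
    pairs: Sequence[ReadPair],
    references: Sequence[tuple[str, str]],
    ref_to_taxid: Mapping[str, int],
    taxonomy: Taxonomy,
    *,
    q: float = DEFAULT_Q,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    bitscore_fraction: float = DEFAULT_BITSCORE_FRACTION,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
    phred_cutoff: int = DEFAULT_PHRED_CUTOFF,
    min_len: int = DEFAULT_MIN_LEN,
    uncultured_patterns: Iterable[str] = DEFAULT_UNCULTURED_PATTERNS,
) -> PipelineResult:
    """Classify read pairs end to end against an in-memory reference.

    Pairs that merge are dereplicated and classified through their unique
    consensus; pairs that stay unmerged (or are dropped by trimming) are
    reported unassigned — the self-contained search aligns single
    consensus sequences only, so unmerged pairs are outside its scope.
    Output order follows the input pair order and every input pair yields
    exactly one assignment.
    """
    guide = build_guide_tree(taxonomy, ref_to_taxid)
    prep = prep_pairs(
        pairs,
        min_overlap=min_overlap,
        max_mismatch_ratio=max_mismatch_ratio,
        phred_cutoff=phred_cutoff,
        min_len=min_len,
    )
    derep = dereplicate((m.pair_id, m.consensus_seq) for m in prep.merged)
    queries = [(e.representative, seq) for seq, e in derep.entries.items()]
    hits = search_hits(queries, references)
    mf = build_match_file(
        hits, guide,
        min_identity=min_identity, min_coverage=min_coverage,
        bitscore_fraction=bitscore_fraction, uncultured_patterns=uncultured_patterns,
    )

    by_pair: dict[str, Assignment] = {}
    for seq, entry in derep.entries.items():
        taxids = mf.taxid_set(entry.representative)
        node = assign_query(taxids, guide, q) if taxids else None
        rank = _display_rank(taxonomy, node) if node is not None else None
        status = ASSIGNED if node is not None else UNASSIGNED
        for member in entry.members:
            by_pair[member] = Assignment(member, node, rank, status, 1)
    for pair in prep.unmerged:
        by_pair[pair.pair_id] = Assignment(pair.pair_id, None, None, UNASSIGNED, 1)
    for pid in prep.dropped_ids:
        by_pair[pid] = Assignment(pid, None, None, UNASSIGNED, 1)

    assignments = [by_pair[p.pair_id] for p in pairs]
    return PipelineResult(assignments, prep, derep, mf, guide)


@dataclass
class SyntheticDataset:
    """A complete truth-labeled benchmark dataset."""

    taxonomy: Taxonomy
    species_pool: list[tuple[int, int]]
    community: list[int]
    references: list[tuple[str, str]]
    ref_to_taxid: dict[str, int]
    pairs: list[ReadPair]
    truth: dict[str, int]


def _subseeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(0 if seed is None else seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def build_synthetic_dataset(
    seed: int = 0,
    *,
    n_genera: int = 10,
    species_per_genus: int = 3,
    pairs_per_species: int = 100,
    substitution_rate: float = 0.0,
    n_refs_per_species: int = 3,
    marker_len_range: tuple[int, int] = V5V6_CORE_LEN,
    primers: PrimerPair = V5V6_PRIMERS,
    read_len: int = DEFAULT_READ_LEN,
    community_size: int | None = None,
    min_cogeneric: int = 0,
) -> SyntheticDataset:
    """Simulate taxonomy, reference database, community and reads in one go.

    Reads for each community species are spread round-robin over the
    amplicons extracted from that species' references.  Deterministic under
    ``seed``; all derived seeds stay below 2**31.
    """
    s_db, s_comm, s_reads = _subseeds(seed, 3)
    taxonomy, pool = simulate_taxonomy(n_genera, species_per_genus)
    references, ref_to_taxid = simulate_reference_db(
        taxonomy, n_refs_per_species, marker_len_range, seed=s_db, primers=primers
    )
    community = sample_community(
        pool, community_size or len(pool), min_cogeneric, seed=s_comm
    )

    amplicons_by_species: dict[int, list] = {}
    for rid, seq in references:
        taxid = ref_to_taxid[rid]
        amplicons_by_species.setdefault(taxid, []).extend(
            extract_amplicons(rid, seq, taxid, primers)
        )

    pairs: list[ReadPair] = []
    truth: dict[str, int] = {}
    read_seeds = _subseeds(s_reads, len(community) * n_refs_per_species * 2)
    seed_iter = iter(read_seeds)
    for sp in community:
        amps = amplicons_by_species.get(sp, [])
        if not amps:
            raise RuntimeError(f"no amplicon recovered for species {sp}")
        share = [pairs_per_species // len(amps)] * len(amps)
        for i in range(pairs_per_species % len(amps)):
            share[i] += 1
        for amp, n in zip(amps, share):
            if n == 0:
                continue
            for sim in simulate_paired_reads(
                amp, n, read_len, substitution_rate, seed=next(seed_iter)
            ):
                pairs.append(
                    ReadPair(
                        sim.pair_id, sim.read1_seq, sim.read2_seq,
                        sim.read1_quals, sim.read2_quals,
                    )
                )
                truth[sim.pair_id] = sim.true_taxid
    return SyntheticDataset(
        taxonomy, pool, community, references, ref_to_taxid, pairs, truth
    )
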