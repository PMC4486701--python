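"""Synthetic benchmark construction: in-silico PCR, communities, reads.

Reproduces the construction of truth-labeled amplicon collections used to
benchmark the classifier: degenerate-primer pattern matching against marker
sequences, community sampling that forces co-generic species pairs (the
hardest discrimination problem for a marker), and MiSeq-like 250x2
paired-read simulation with a substitution-only error model.

The universal primer pairs for the 16S rRNA V5-V6 region and the fungal
ITS1 spacer are provided as constants.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import count
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .taxonomy import TaxNode, Taxonomy, rank_ancestor

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
DNA_BASES = "ACGT"

DEFAULT_READ_LEN = 250
DEFAULT_PAIRS_PER_SPECIES = 5000
DEFAULT_MAX_AMPLICON_LEN = 2000

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(DNA_BASES):
    _BASE_INDEX[ord(_b)] = _i
_BASE_BYTES = np.frombuffer(DNA_BASES.encode(), dtype=np.uint8)


def _check_iupac(seq: str, what: str = "sequence") -> None:
    bad = set(seq.upper()) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"non-IUPAC characters in {what}: {sorted(bad)}")


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate PCR primer pair, both given 5'->3' (PCR convention:
    the reverse primer anneals to the plus strand, so its reverse
    complement is what appears on the amplicon's plus strand)."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            _check_iupac(seq, f"{name} primer")
            if len(seq) < 10:
                raise ValueError(f"{name} primer shorter than 10 nt")


#: Universal 16S V5-V6 primer pair (bacteria).
V5V6_PRIMERS = PrimerPair("TTAGATACCCYGGTAGTCC", "ACGAGCTGACGACARCCATG")
#: Universal ITS1 primer pair (fungi).
ITS1_PRIMERS = PrimerPair("GAACCWGCGGARGGATCA", "GCTGCGTTCTTCATCGATGC")

#: Marker-core length ranges; ITS1 is deliberately far more length-variable
#: than V5-V6, mirroring the two loci's real behaviour.
V5V6_CORE_LEN = (280, 320)
ITS1_CORE_LEN = (120, 480)


@dataclass(frozen=True)
class AmpliconRecord:
    """One in-silico PCR product, with half-open source coordinates.

    ``sequence`` is always the amplicon plus strand: for ``strand == "-"``
    it equals the reverse complement of ``source[start:end]``.
    """

    amplicon_id: str
    source_id: str
    taxid: int
    sequence: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class SimReadPair:
    """A truth-labeled simulated read pair (field-compatible with ReadPair)."""

    pair_id: str
    read1_seq: str
    read2_seq: str
    read1_quals: tuple[int, ...]
    read2_quals: tuple[int, ...]
    true_taxid: int
    amplicon_id: str


def iupac_match_positions(pattern: str, sequence: str, max_mismatches: int = 0) -> list[int]:
    """All 0-based starts where ``pattern`` matches under IUPAC degeneracy.

    A pattern column matches when the sequence base belongs to the code's
    base set; up to ``max_mismatches`` non-matching columns are tolerated
    (default 0: exact degenerate matching).
    """
    if not pattern:
        raise ValueError("empty primer pattern")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    _check_iupac(pattern, "pattern")
    pat = [IUPAC_CODES[c] for c in pattern.upper()]
    seq = sequence.upper()
    m = len(pat)
    hits: list[int] = []
    for i in range(len(seq) - m + 1):
        mismatches = 0
        ok = True
        for j, allowed in enumerate(pat):
            if seq[i + j] not in allowed:
                mismatches += 1
                if mismatches > max_mismatches:
                    ok = False
                    break
        if ok:
            hits.append(i)
    return hits


def _pair_sites(
    seq: str, forward: str, reverse_rc: str, max_amplicon_len: int, max_mismatches: int
) -> list[tuple[int, int]]:
    """Leftmost-first, non-nested pairing of forward sites with the nearest
    downstream reverse site; each reverse site is consumed at most once."""
    f_sites = iupac_match_positions(forward, seq, max_mismatches)
    r_sites = iupac_match_positions(reverse_rc, seq, max_mismatches)
    flen, rlen = len(forward), len(reverse_rc)
    pairs: list[tuple[int, int]] = []
    ri = 0
    for f in f_sites:
        while ri < len(r_sites) and r_sites[ri] < f + flen:
            ri += 1
        if ri == len(r_sites):
            break
        end = r_sites[ri] + rlen
        if end - f <= max_amplicon_len:
            pairs.append((f, end))
            ri += 1
    return pairs


def extract_amplicons(
    source_id: str,
    sequence: str,
    taxid: int,
    primers: PrimerPair,
    max_amplicon_len: int = DEFAULT_MAX_AMPLICON_LEN,
    *,
    max_mismatches: int = 0,
    trim_primers: bool = False,
) -> list[AmpliconRecord]:
    """In-silico PCR: emit every primer-delimited amplicon on both strands.

    Amplicons include both primer annealing sites unless ``trim_primers``;
    minus-strand products are reported reverse-complemented to the amplicon
    plus strand with coordinates still on the source.
    """
    seq = sequence.upper()
    fwd = primers.forward.upper()
    rev_rc = reverse_complement(primers.reverse.upper())
    flen, rlen = len(fwd), len(rev_rc)
    out: list[AmpliconRecord] = []
    n = len(seq)
    ids = count(1)

    for s, e in _pair_sites(seq, fwd, rev_rc, max_amplicon_len, max_mismatches):
        if trim_primers:
            s, e = s + flen, e - rlen
        out.append(
            AmpliconRecord(
                f"{source_id}|amp{next(ids)}", source_id, taxid, seq[s:e], s, e, "+"
            )
        )
    rc = reverse_complement(seq)
    for s, e in _pair_sites(rc, fwd, rev_rc, max_amplicon_len, max_mismatches):
        if trim_primers:
            s, e = s + flen, e - rlen
        out.append(
            AmpliconRecord(
                f"{source_id}|amp{next(ids)}", source_id, taxid,
                rc[s:e], n - e, n - s, "-",
            )
        )
    return out


def _max_cogeneric(genus_sizes: Sequence[int], n_species: int) -> int:
    """Greedy upper bound on achievable co-generic species for a sample size."""
    budget = n_species
    total = 0
    for size in sorted((s for s in genus_sizes if s >= 2), reverse=True):
        if budget < 2:
            break
        take = min(size, budget)
        if take >= 2:
            total += take
            budget -= take
    return total


def sample_community(
    species_pool: Sequence[tuple[int, int]],
    n_species: int,
    min_cogeneric: int = 0,
    seed: int | None = None,
) -> list[int]:
    """Sample ``n_species`` distinct taxids, forcing co-generic structure.

    ``species_pool`` is a list of (species taxid, genus id).  At least
    ``min_cogeneric`` of the returned species belong to genera contributing
    two or more selected species.  Deterministic under ``seed``.
    """
    pool = sorted(set(species_pool))
    if n_species > len(pool):
        raise ValueError(f"n_species={n_species} exceeds pool size {len(pool)}")
    by_genus: dict[int, list[int]] = defaultdict(list)
    for taxid, genus in pool:
        by_genus[genus].append(taxid)
    feasible = _max_cogeneric([len(v) for v in by_genus.values()], n_species)
    if min_cogeneric > feasible:
        raise ValueError(
            f"min_cogeneric={min_cogeneric} infeasible: at most {feasible} "
            f"co-generic species achievable with this pool and n_species={n_species}"
        )
    rng = np.random.default_rng(seed)
    selected: set[int] = set()
    picked_per_genus: dict[int, int] = defaultdict(int)

    if min_cogeneric > 0:
        multi = sorted(g for g, sp in by_genus.items() if len(sp) >= 2)
        order = [multi[i] for i in rng.permutation(len(multi))]
        cogeneric = 0
        for g in order:  # two species per genus, spreading across genera
            if cogeneric >= min_cogeneric or len(selected) + 2 > n_species:
                break
            picks = rng.choice(by_genus[g], size=2, replace=False)
            selected.update(int(t) for t in picks)
            picked_per_genus[g] = 2
            cogeneric += 2
        # top up within already-used genera if genera ran out
        progress = True
        while cogeneric < min_cogeneric and len(selected) < n_species and progress:
            progress = False
            for g in order:
                if cogeneric >= min_cogeneric or len(selected) >= n_species:
                    break
                remaining = [t for t in by_genus[g] if t not in selected]
                if remaining and picked_per_genus[g] >= 2:
                    pick = int(rng.choice(remaining))
                    selected.add(pick)
                    picked_per_genus[g] += 1
                    cogeneric += 1
                    progress = True

    leftovers = [t for t, _ in pool if t not in selected]
    n_fill = n_species - len(selected)
    if n_fill:
        fill = rng.choice(leftovers, size=n_fill, replace=False)
        selected.update(int(t) for t in fill)
    return sorted(selected)


def _mutate_array(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases i.i.d. at ``rate``, each to a uniform different base."""
    out = arr.copy()
    if rate <= 0:
        return out
    mask = rng.random(arr.size) < rate
    k = int(mask.sum())
    if k:
        idx = _BASE_INDEX[out[mask]]
        shift = rng.integers(1, 4, size=k)
        out[mask] = _BASE_BYTES[(idx + shift) % 4]
    return out


def _mutate_str(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _mutate_array(rng, arr, rate).tobytes().decode()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=int(length)))


def simulate_paired_reads(
    amplicon: AmpliconRecord,
    n_pairs: int,
    read_len: int = DEFAULT_READ_LEN,
    substitution_rate: float = 0.001,
    qual_model: tuple[float, float] = (36.0, 3.0),
    seed: int | None = None,
) -> list[SimReadPair]:
    """MiSeq-like paired reads from one amplicon, truth fields attached.

    Read 1 covers the amplicon 5' end, read 2 is the reverse complement of
    its 3' end; amplicons shorter than ``read_len`` yield reads at amplicon
    length (adapter read-through is assumed trimmed, not padded).
    Substitutions are i.i.d. per base; Phred scores are drawn from a normal
    ``qual_model=(mean, sd)`` clipped to [2, 41].
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if not 0 <= substitution_rate < 1:
        raise ValueError("substitution_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seq = amplicon.sequence.upper()
    tmpl1 = np.frombuffer(seq[:read_len].encode(), dtype=np.uint8)
    tmpl2 = np.frombuffer(reverse_complement(seq)[:read_len].encode(), dtype=np.uint8)
    mean, sd = qual_model
    out: list[SimReadPair] = []
    for i in range(n_pairs):
        r1 = _mutate_array(rng, tmpl1, substitution_rate)
        r2 = _mutate_array(rng, tmpl2, substitution_rate)
        q1 = np.clip(np.rint(rng.normal(mean, sd, r1.size)), 2, 41).astype(int)
        q2 = np.clip(np.rint(rng.normal(mean, sd, r2.size)), 2, 41).astype(int)
        out.append(
            SimReadPair(
                pair_id=f"{amplicon.amplicon_id}:{i}",
                read1_seq=r1.tobytes().decode(),
                read2_seq=r2.tobytes().decode(),
                read1_quals=tuple(int(q) for q in q1),
                read2_quals=tuple(int(q) for q in q2),
                true_taxid=amplicon.taxid,
                amplicon_id=amplicon.amplicon_id,
            )
        )
    return out


def simulate_taxonomy(
    n_genera: int = 10,
    species_per_genus: int = 3,
    n_phyla: int = 2,
    n_families: int = 4,
) -> tuple[Taxonomy, list[tuple[int, int]]]:
    """A complete seven-rank synthetic taxonomy plus its species pool.

    Returns the taxonomy and a list of (species taxid, genus taxid) suitable
    for :func:`sample_community`.
    """
    next_id = count(1)
    nodes: dict[int, TaxNode] = {}

    def add(parent: int | None, rank: str, name: str) -> int:
        nid = next(next_id)
        nodes[nid] = TaxNode(nid, nid if parent is None else parent, rank, name)
        return nid

    root = add(None, "kingdom", "Synthetica")
    phyla = [add(root, "phylum", f"Phylum{i + 1}") for i in range(n_phyla)]
    classes = [add(p, "class", f"Class{i + 1}") for i, p in enumerate(phyla)]
    orders = [add(c, "order", f"Order{i + 1}") for i, c in enumerate(classes)]
    families = [
        add(orders[i % len(orders)], "family", f"Family{i + 1}") for i in range(n_families)
    ]
    pool: list[tuple[int, int]] = []
    for gi in range(n_genera):
        genus = add(families[gi % n_families], "genus", f"Genus{gi + 1}")
        for si in range(species_per_genus):
            sp = add(genus, "species", f"Genus{gi + 1} species{si + 1}")
            pool.append((sp, genus))
    return Taxonomy(nodes), pool


def _resolve_iupac(rng: np.random.Generator, pattern: str) -> str:
    """One concrete realization of a degenerate primer."""
    return "".join(
        c if c in DNA_BASES else IUPAC_CODES[c][int(rng.integers(len(IUPAC_CODES[c])))]
        for c in pattern.upper()
    )


def simulate_reference_db(
    taxonomy: Taxonomy,
    n_refs_per_species: int = 3,
    marker_len_range: tuple[int, int] = V5V6_CORE_LEN,
    seed: int | None = None,
    *,
    primers: PrimerPair = V5V6_PRIMERS,
    within_species_rate: float = 0.005,
    between_species_divergence: float = 0.08,
    flank_len_range: tuple[int, int] = (25, 60),
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Synthetic marker reference database with hierarchical divergence.

    Each genus gets an independent random marker core (between-genus
    identity is at background level); each species derives from its genus
    core at ``between_species_divergence``; each reference from its species
    core at ``within_species_rate``.  Primer annealing sites flank the core
    exactly, so in-silico PCR recovers one amplicon per reference.  Within-
    species identity therefore exceeds between-genus identity by
    construction.  Byte-identical output under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    species = sorted(
        nid for nid, node in taxonomy.nodes.items() if node.rank == "species"
    )
    if not species:
        raise ValueError("taxonomy has no species-rank nodes")
    fwd_site = _resolve_iupac(rng, primers.forward)
    rev_site = reverse_complement(_resolve_iupac(rng, primers.reverse))
    lo, hi = marker_len_range
    genus_core: dict[int, str] = {}
    records: list[tuple[str, str]] = []
    ref_to_taxid: dict[str, int] = {}
    for sp in species:
        genus = rank_ancestor(taxonomy, sp, "genus") or sp
        if genus not in genus_core:
            genus_core[genus] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        sp_core = _mutate_str(rng, genus_core[genus], between_species_divergence)
        for r in range(n_refs_per_species):
            core = _mutate_str(rng, sp_core, within_species_rate)
            flank5 = _random_seq(rng, int(rng.integers(*flank_len_range)))
            flank3 = _random_seq(rng, int(rng.integers(*flank_len_range)))
            rid = f"ref{sp}_{r + 1}"
            records.append((rid, flank5 + fwd_site + core + rev_site + flank3))
            ref_to_taxid[rid] = sp
    return records, ref_to_taxid


# ---------------------------------------------------------------------------
# output helpers

def write_fasta(records: Iterable[tuple[str, str]], handle_or_path) -> None:
    recs = (SeqRecord(Seq(s), id=i, description="") for i, s in records)
    SeqIO.write(recs, handle_or_path, "fasta")


def write_paired_fastq(pairs: Iterable[SimReadPair], fq1_path, fq2_path) -> None:
    """Phred+33 paired FASTQ output, mate order preserved."""
    pairs = list(pairs)

    def _rec(pid: str, seq: str, quals, mate: int) -> SeqRecord:
        rec = SeqRecord(Seq(seq), id=f"{pid}/{mate}", description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        return rec

    SeqIO.write((_rec(p.pair_id, p.read1_seq, p.read1_quals, 1) for p in pairs), fq1_path, "fastq")
    SeqIO.write((_rec(p.pair_id, p.read2_seq, p.read2_quals, 2) for p in pairs), fq2_path, "fastq")


def write_truth_tsv(pairs: Iterable[SimReadPair], handle_or_path) -> None:
    def _write(fh):
        for p in pairs:
            fh.write(f"{p.pair_id}\t{p.true_taxid}\t{p.amplicon_id}\n")

    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "wt") as fh:
            _write(fh)
    else:
        _write(handle_or_path)


def read_truth_tsv(handle_or_path) -> dict[str, int]:
    def _read(fh) -> dict[str, int]:
        out: dict[str, int] = {}
        for line in fh:
            if line.strip():
                fields = line.rstrip("\n").split("\t")
                out[fields[0]] = int(fields[1])
        return out

    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "rt") as fh:
            return _read(fh)
    return _read(handle_or_path)
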