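"""Paired-read preparation: overlap merging, quality trimming, dereplication.

The first computational stage of the Illumina pipeline.  Overlapping mates
are merged into a single consensus; pairs that fail to merge are instead
3'-quality-trimmed and length-filtered and travel through the rest of the
pipeline as pairs; surviving consensus sequences are dereplicated into
unique sequences with abundance counts.

Every input pair lands in exactly one of {merged, kept-unmerged, dropped}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import reverse_complement

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_RATIO = 0.25
DEFAULT_PHRED_CUTOFF = 25
DEFAULT_MIN_LEN = 50


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    read1_seq: str
    read2_seq: str
    read1_quals: tuple[int, ...]
    read2_quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.read1_seq) != len(self.read1_quals) or len(self.read2_seq) != len(
            self.read2_quals
        ):
            raise ValueError(f"quality/base length mismatch in pair {self.pair_id}")


@dataclass(frozen=True)
class MergedRead:
    pair_id: str
    consensus_seq: str
    consensus_quals: tuple[int, ...]
    overlap_len: int
    mismatches_in_overlap: int


@dataclass(frozen=True)
class DerepEntry:
    representative: str          # first-seen sequence id
    abundance: int
    members: tuple[str, ...]     # all ids collapsed into this entry


@dataclass
class DereplicatedSet:
    """Unique (case-folded) sequences with abundances; Σ abundance == total_input."""

    entries: dict[str, DerepEntry]
    total_input: int


@dataclass
class PrepResult:
    merged: list[MergedRead] = field(default_factory=list)
    unmerged: list[ReadPair] = field(default_factory=list)
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        n_m, n_u, n_d = len(self.merged), len(self.unmerged), len(self.dropped_ids)
        return {
            "n_input": n_m + n_u + n_d,
            "n_merged": n_m,
            "n_unmerged": n_u,
            "n_dropped": n_d,
        }


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
) -> MergedRead | None:
    """Merge a pair into one consensus if the mates overlap acceptably.

    All suffix(read1)/prefix(revcomp(read2)) overlaps of length >=
    ``min_overlap`` are scored; the overlap minimizing mismatch ratio wins
    (ties go to the longest overlap).  Merging is rejected when the best
    ratio exceeds ``max_mismatch_ratio``.  At a mismatching column the base
    with the higher Phred score is kept (tie: read 1); the consensus quality
    is the max of the two at agreement and their absolute difference at
    disagreement.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    r1 = pair.read1_seq.upper()
    r2rc = reverse_complement(pair.read2_seq.upper())
    a = np.frombuffer(r1.encode(), dtype=np.uint8)
    b = np.frombuffer(r2rc.encode(), dtype=np.uint8)
    q1 = np.asarray(pair.read1_quals, dtype=np.int32)
    q2 = np.asarray(pair.read2_quals, dtype=np.int32)[::-1]
    n1, n2 = a.size, b.size
    if min(n1, n2) < min_overlap:
        return None

    best: tuple[float, int, int] | None = None  # (ratio, overlap, mismatches)
    for o in range(min_overlap, min(n1, n2) + 1):
        mm = int(np.count_nonzero(a[n1 - o:] != b[:o]))
        ratio = mm / o
        if best is None or ratio <= best[0]:  # ascending o: equal ratio -> longer wins
            best = (ratio, o, mm)
    ratio, o, mm = best
    if ratio > max_mismatch_ratio:
        return None

    ov_a, ov_b = a[n1 - o:], b[:o]
    qa, qb = q1[n1 - o:], q2[:o]
    agree = ov_a == ov_b
    consensus_ov = np.where(~agree & (qb > qa), ov_b, ov_a)
    quals_ov = np.where(agree, np.maximum(qa, qb), np.abs(qa - qb))
    consensus = r1[: n1 - o] + consensus_ov.tobytes().decode() + r2rc[o:]
    quals = tuple(int(x) for x in np.concatenate([q1[: n1 - o], quals_ov, q2[o:]]))
    return MergedRead(pair.pair_id, consensus, quals, o, mm)


def quality_trim(
    seq: str, quals: Sequence[int], phred_cutoff: int = DEFAULT_PHRED_CUTOFF
) -> tuple[str, tuple[int, ...]]:
    """Remove the low-quality 3' region by partial-sum minimization.

    Walking from the 3' end, accumulate ``q - cutoff`` and cut at the
    position where the running sum is lowest; bases at exactly the cutoff
    count as low-quality.  A fully low-quality read trims to empty.
    """
    running = 0
    lowest = 0
    cut = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        running += quals[i] - phred_cutoff
        if running <= lowest:
            lowest = running
            cut = i
    return seq[:cut], tuple(quals[:cut])


def length_filter(pair: ReadPair, min_len: int = DEFAULT_MIN_LEN) -> bool:
    """Keep a (trimmed) pair only if both mates are at least ``min_len`` nt."""
    return len(pair.read1_seq) >= min_len and len(pair.read2_seq) >= min_len


def dereplicate(sequences: Iterable[tuple[str, str]]) -> DereplicatedSet:
    """Collapse exact (case-insensitive) duplicate sequences.

    The representative is the first-seen id; abundance is the group size.
    """
    groups: dict[str, list[str]] = {}
    total = 0
    for seq_id, seq in sequences:
        total += 1
        groups.setdefault(seq.upper(), []).append(seq_id)
    entries = {
        seq: DerepEntry(ids[0], len(ids), tuple(ids)) for seq, ids in groups.items()
    }
    return DereplicatedSet(entries=entries, total_input=total)


def prep_pairs(
    pairs: Iterable[ReadPair],
    *,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
    phred_cutoff: int = DEFAULT_PHRED_CUTOFF,
    min_len: int = DEFAULT_MIN_LEN,
) -> PrepResult:
    """Run the full preparation stage, partitioning the input pairs.

    Merged reads pass through untrimmed; only pairs that fail to merge are
    quality-trimmed and then length-filtered.
    """
    result = PrepResult()
    for pair in pairs:
        merged = merge_pair(pair, min_overlap, max_mismatch_ratio)
        if merged is not None:
            result.merged.append(merged)
            continue
        s1, t1 = quality_trim(pair.read1_seq, pair.read1_quals, phred_cutoff)
        s2, t2 = quality_trim(pair.read2_seq, pair.read2_quals, phred_cutoff)
        trimmed = ReadPair(pair.pair_id, s1, s2, t1, t2)
        if length_filter(trimmed, min_len):
            result.unmerged.append(trimmed)
        else:
            result.dropped_ids.append(pair.pair_id)
    return result


# ---------------------------------------------------------------------------
# FASTQ I/O

def _strip_mate_suffix(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def read_paired_fastq(fq1_path, fq2_path) -> list[ReadPair]:
    """Load mate-synchronized Phred+33 FASTQ files."""
    pairs: list[ReadPair] = []
    it1 = SeqIO.parse(fq1_path, "fastq")
    it2 = SeqIO.parse(fq2_path, "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        pid1, pid2 = _strip_mate_suffix(rec1.id), _strip_mate_suffix(rec2.id)
        if pid1 != pid2:
            raise ValueError(f"mate id mismatch: {rec1.id} vs {rec2.id}")
        pairs.append(
            ReadPair(
                pid1,
                str(rec1.seq),
                str(rec2.seq),
                tuple(rec1.letter_annotations["phred_quality"]),
                tuple(rec2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def write_derep_fasta(derep: DereplicatedSet, handle_or_path) -> None:
    """Dereplicated sequences with ``;size=N`` abundance annotations."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = (
        SeqRecord(Seq(seq), id=f"{e.representative};size={e.abundance}", description="")
        for seq, e in derep.entries.items()
    )
    SeqIO.write(recs, handle_or_path, "fasta")


def write_abundance_tsv(derep: DereplicatedSet, handle_or_path) -> None:
    def _write(fh):
        for seq, e in derep.entries.items():
            fh.write(f"{e.representative}\t{e.abundance}\t{seq}\n")

    if isinstance(handle_or_path, (str,)) or hasattr(handle_or_path, "__fspath__"):
        with open(handle_or_path, "wt") as fh:
            _write(fh)
    else:
        _write(handle_or_path)
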