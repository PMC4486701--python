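"""Alignment-hit parsing and the staged retention rules ("match file").

External aligner output (BLAST outfmt-6 tabular or SAM) is parsed into
:class:`HitRecord` objects and reduced, per query, by three staged rules:

1. numeric thresholds — identity >= 97 % and query coverage >= 70 %
   (both inclusive);
2. score tolerance — keep hits whose score is at least 95 % of the best
   surviving score (the "not lower than 5 % of the best match" rule, read
   fractionally);
3. completeness priority — if any survivor maps to a reference with a
   complete, informative taxonomic path, survivors mapping to incomplete
   references (e.g. "uncultured bacterium") are discarded.

The stage order is fixed: thresholds, then score tolerance, then
completeness.  The surviving (reference, taxon) candidates per query form
the match file consumed by assignment.
"""

from __future__ import annotations

import logging
import re
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .taxonomy import DEFAULT_UNCULTURED_PATTERNS, GuideTree, is_complete_path

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 97.0
DEFAULT_MIN_COVERAGE = 70.0
DEFAULT_BITSCORE_FRACTION = 0.95

BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class ParseError(ValueError):
    """Malformed alignment input."""


@dataclass(frozen=True)
class HitRecord:
    """One parsed alignment hit (or one merged proper pair for SAM input).

    ``bitscore`` holds the BLAST bit score, or the aligner's alignment
    score for SAM input; ``aligned_query_span`` is 0-based half-open on
    the query.
    """

    query_id: str
    ref_id: str
    identity_pct: float
    query_coverage_pct: float
    bitscore: float
    aligned_query_span: tuple[int, int] = (0, 0)
    paired: bool = False
    qlen: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity out of range: {self.identity_pct}")
        if not 0.0 <= self.query_coverage_pct <= 100.0 + 1e-9:
            raise ValueError(f"coverage out of range: {self.query_coverage_pct}")
        if self.bitscore < 0:
            raise ValueError(f"negative score: {self.bitscore}")


@dataclass
class MatchFile:
    """Per-query retained candidates: ordered (ref_id, taxid) lists."""

    entries: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    complete_path_only: dict[str, bool] = field(default_factory=dict)

    def taxid_view(self) -> dict[str, list[int]]:
        return {q: [t for _, t in hits] for q, hits in self.entries.items()}

    def taxid_set(self, query_id: str) -> set[int]:
        return {t for _, t in self.entries.get(query_id, [])}


# ---------------------------------------------------------------------------
# BLAST tabular

def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            yield from fh
    elif hasattr(source, "read"):
        yield from source
    else:
        yield from source


def parse_blast_tabular(
    source, qlen: Mapping[str, int] | None = None
) -> list[HitRecord]:
    """Parse BLAST outfmt-6 rows (12 standard columns, optional 13th qlen).

    Query coverage is ``100 * (qend - qstart + 1) / qlen``; the query
    length must come from the 13th column or the ``qlen`` mapping,
    otherwise coverage is uncomputable and a :class:`ParseError` is raised.
    """
    hits: list[HitRecord] = []
    for lineno, line in enumerate(_iter_lines(source), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (12, 13):
            raise ParseError(
                f"line {lineno}: expected 12 or 13 tab-separated columns, got {len(fields)}"
            )
        try:
            pident = float(fields[2])
            qstart, qend = int(fields[6]), int(fields[7])
            bitscore = float(fields[11])
            ql = int(fields[12]) if len(fields) == 13 else None
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if ql is None:
            if qlen is not None and fields[0] in qlen:
                ql = int(qlen[fields[0]])
            else:
                raise ParseError(
                    f"line {lineno}: query length unavailable for {fields[0]!r}; "
                    "supply a 13th qlen column or a qlen mapping"
                )
        coverage = 100.0 * (qend - qstart + 1) / ql
        hits.append(
            HitRecord(
                fields[0], fields[1], pident, coverage, bitscore,
                (qstart - 1, qend), qlen=ql,
            )
        )
    return hits


def write_blast_tabular(hits: Iterable[HitRecord], handle_or_path) -> None:
    """Emit hits as 13-column outfmt-6 rows (placeholder mismatch/gap/evalue).

    ``parse_blast_tabular`` is the inverse on the fields a
    :class:`HitRecord` carries.
    """

    def _write(fh):
        for h in hits:
            qstart, qend = h.aligned_query_span
            ql = h.qlen if h.qlen is not None else max(qend, 1)
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.ref_id, f"{h.identity_pct:g}",
                        str(qend - qstart), "0", "0",
                        str(qstart + 1), str(qend), "1", str(qend - qstart),
                        "0.0", f"{h.bitscore:g}", str(ql),
                    ]
                )
                + "\n"
            )

    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "wt") as fh:
            _write(fh)
    else:
        _write(handle_or_path)


# ---------------------------------------------------------------------------
# SAM

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _nm_from_md(md: str, n_ins: int, n_del: int) -> int:
    """Edit count from an MD tag plus CIGAR indel lengths (NM semantics)."""
    mismatches = 0
    for match in _MD_TOKEN.finditer(md):
        if match.group(3):
            mismatches += 1
    return mismatches + n_ins + n_del


def _as_sam_path(source, stack: list) -> str:
    if isinstance(source, (str, Path)):
        return str(source)
    text = source.read() if hasattr(source, "read") else "".join(source)
    tmp = tempfile.NamedTemporaryFile("wt", suffix=".sam", delete=False)
    stack.append(tmp.name)
    tmp.write(text)
    tmp.close()
    return tmp.name


def parse_sam(source, ref_to_taxid: Mapping[str, int] | None = None) -> list[HitRecord]:
    """Parse SAM alignments (secondary included) into hit records.

    Identity is ``100 * (aligned_len - NM) / aligned_len`` over CIGAR
    M/=/X columns, with NM taken from the NM tag or reconstructed from MD;
    records with neither are skipped (count logged).  Coverage is the
    aligned query fraction of the full read length including soft clips.
    Proper pairs collapse to a single record with mate-averaged identity
    and coverage and summed alignment score.
    """
    import os

    import pysam

    tmp_files: list = []
    path = _as_sam_path(source, tmp_files)
    singles: list[HitRecord] = []
    mates: dict[tuple[str, str], list[HitRecord]] = defaultdict(list)
    skipped = 0
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped or aln.is_supplementary:
                    continue
                cig = aln.cigartuples or []
                aligned_len = sum(n for op, n in cig if op in (0, 7, 8))
                if aligned_len == 0:
                    continue
                n_ins = sum(n for op, n in cig if op == 1)
                n_del = sum(n for op, n in cig if op == 2)
                if aln.has_tag("NM"):
                    nm = int(aln.get_tag("NM"))
                elif aln.has_tag("MD"):
                    nm = _nm_from_md(str(aln.get_tag("MD")), n_ins, n_del)
                else:
                    skipped += 1
                    continue
                identity = 100.0 * max(aligned_len - nm, 0) / aligned_len
                read_len = aln.infer_read_length() or len(aln.query_sequence or "")
                qal = aln.query_alignment_length  # excludes soft clips
                coverage = 100.0 * qal / read_len if read_len else 0.0
                score = float(aln.get_tag("AS")) if aln.has_tag("AS") else float(
                    max(aligned_len - nm, 0)
                )
                ref = aln.reference_name
                if ref_to_taxid is not None and ref not in ref_to_taxid:
                    logger.warning("SAM hit to unmapped reference %s kept as-is", ref)
                rec = HitRecord(
                    aln.query_name, ref, identity, min(coverage, 100.0), score,
                    (aln.query_alignment_start, aln.query_alignment_end),
                    qlen=read_len or None,
                )
                if aln.is_paired and aln.is_proper_pair and not aln.is_secondary:
                    mates[(aln.query_name, ref)].append(rec)
                else:
                    singles.append(rec)
    finally:
        for f in tmp_files:
            os.unlink(f)
    if skipped:
        logger.warning("skipped %d SAM records lacking both NM and MD tags", skipped)

    out = list(singles)
    for (qname, ref), recs in mates.items():
        if len(recs) == 2:
            out.append(
                HitRecord(
                    qname, ref,
                    (recs[0].identity_pct + recs[1].identity_pct) / 2,
                    (recs[0].query_coverage_pct + recs[1].query_coverage_pct) / 2,
                    recs[0].bitscore + recs[1].bitscore,
                    (0, 0), paired=True,
                )
            )
        else:
            out.extend(recs)
    return out


# ---------------------------------------------------------------------------
# filtering

def filter_hits(
    hits: Iterable[HitRecord],
    guide: GuideTree,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    bitscore_fraction: float = DEFAULT_BITSCORE_FRACTION,
    uncultured_patterns: Iterable[str] = DEFAULT_UNCULTURED_PATTERNS,
) -> list[HitRecord]:
    """Apply the three retention stages to one query's hits.

    Hits to references absent from the guide tree carry no taxonomic
    information and are dropped with the numeric thresholds.  Returns a
    possibly-empty list preserving input order; a query with no survivors
    is simply recorded as unassigned downstream.
    """
    hits = list(hits)
    if not hits:
        return []
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("filter_hits expects hits for a single query")

    stage1 = [
        h
        for h in hits
        if h.identity_pct >= min_identity
        and h.query_coverage_pct >= min_coverage
        and h.ref_id in guide.ref_to_leaf
    ]
    if not stage1:
        return []
    best = max(h.bitscore for h in stage1)
    stage2 = [h for h in stage1 if h.bitscore >= bitscore_fraction * best]
    patterns = tuple(uncultured_patterns)
    complete = {
        h.ref_id: is_complete_path(guide.taxonomy, guide.ref_to_leaf[h.ref_id], patterns)
        for h in stage2
    }
    if any(complete.values()):
        return [h for h in stage2 if complete[h.ref_id]]
    return stage2


def build_match_file(
    hits: Iterable[HitRecord],
    guide: GuideTree,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    bitscore_fraction: float = DEFAULT_BITSCORE_FRACTION,
    uncultured_patterns: Iterable[str] = DEFAULT_UNCULTURED_PATTERNS,
) -> MatchFile:
    """Group hits by query, filter each group, keep non-empty survivors."""
    by_query: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    mf = MatchFile()
    for qid in sorted(by_query):
        kept = filter_hits(
            by_query[qid], guide, min_identity, min_coverage,
            bitscore_fraction, uncultured_patterns,
        )
        if kept:
            mf.entries[qid] = [(h.ref_id, guide.ref_to_leaf[h.ref_id]) for h in kept]
            mf.complete_path_only[qid] = all(
                is_complete_path(guide.taxonomy, guide.ref_to_leaf[h.ref_id],
                                 tuple(uncultured_patterns))
                for h in kept
            )
    return mf


def write_match_file(matches: MatchFile, handle_or_path) -> None:
    """TSV: query_id, tab, comma-separated taxids; sorted by query id."""

    def _write(fh):
        for qid in sorted(matches.entries):
            taxids = ",".join(str(t) for _, t in matches.entries[qid])
            fh.write(f"{qid}\t{taxids}\n")

    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "wt") as fh:
            _write(fh)
    else:
        _write(handle_or_path)


def read_match_file(source) -> MatchFile:
    """Inverse of :func:`write_match_file` (ref ids are not round-tripped)."""
    mf = MatchFile()
    for lineno, line in enumerate(_iter_lines(source), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ParseError(f"line {lineno}: expected 2 columns")
        mf.entries[fields[0]] = [("", int(t)) for t in fields[1].split(",") if t]
    return mf
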