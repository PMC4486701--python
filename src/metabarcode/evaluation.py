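"""Benchmark harness: per-taxon confusion counts, macro-averaged per-rank
rates, assigned/correct tallies and the reference-depletion experiment.

For each canonical rank, every read's true taxon and called taxon are
projected to that rank; for a taxon *i* at the rank,

* TP_i — reads belonging to *i* and assigned to *i*;
* FN_i — reads belonging to *i* but not assigned to *i* (unassigned reads
  and reads assigned above the rank count here);
* FP_i — reads belonging to some *j* != *i* but assigned to *i*;
* TN_i — reads belonging to *j* != *i* and assigned to their own *j*.

Per-taxon rates are TPR = TP/(TP+FN), TNR = TN/(TN+FP), FPR = FP/(TN+FP),
FNR = FN/(TP+FN), expressed as percentages; the rank value is the
unweighted (macro) mean over taxa, excluding taxa with a zero denominator
for that rate.  TPR+FNR = 100 and TNR+FPR = 100 hold exactly per taxon and
per rank mean.  A rank with no defined denominator (e.g. a single-taxon
kingdom level has no negatives) stores the rate as undefined rather than
zero; table output may render it as 0.00 for compatibility with the usual
benchmark-table convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .tax_assign import Assignment
from .taxonomy import CANONICAL_RANKS, RANK_DEPTH, Taxonomy, rank_ancestor


@dataclass
class TaxonCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0


@dataclass(frozen=True)
class RankEntry:
    """Macro-averaged rates (percent) at one rank; None marks undefined."""

    tpr: float | None
    tnr: float | None
    fpr: float | None
    fnr: float | None
    n_taxa: int


@dataclass(frozen=True)
class DepletionReport:
    """Outcome of re-classifying after removing a fraction of genera.

    The three buckets partition the reads whose true genus was removed:
    ``wrong`` (called off the true lineage), ``unassigned``, and
    ``recovered_family_or_above`` (called on the true lineage at family
    rank or higher).
    """

    removed_genera: tuple[int, ...]
    n_affected: int
    n_wrong: int
    n_unassigned: int
    n_recovered_family_or_above: int

    def fractions(self) -> dict[str, float]:
        n = max(self.n_affected, 1)
        return {
            "wrong": self.n_wrong / n,
            "unassigned": self.n_unassigned / n,
            "recovered_family_or_above": self.n_recovered_family_or_above / n,
        }


def _project(taxonomy: Taxonomy, node_id: int | None, rank: str) -> int | None:
    if node_id is None:
        return None
    return rank_ancestor(taxonomy, node_id, rank)


def confusion_at_rank(
    assignments: Iterable[Assignment],
    truth: Mapping[str, int],
    taxonomy: Taxonomy,
    rank: str,
) -> dict[int, TaxonCounts]:
    """Per-taxon confusion counts at one canonical rank.

    Reads whose true lineage lacks the rank are not evaluable and are
    skipped.  Taxa appearing only in calls (never in truth) still
    accumulate FP against themselves.  Counts are abundance-weighted.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"rank must be canonical, got {rank!r}")
    counts: dict[int, TaxonCounts] = {}
    correct_total = 0
    for a in assignments:
        if a.query_id not in truth:
            continue
        t = _project(taxonomy, truth[a.query_id], rank)
        if t is None:
            continue
        c = _project(taxonomy, a.node_id, rank)
        w = a.abundance
        counts.setdefault(t, TaxonCounts())
        if c == t:
            counts[t].tp += w
            correct_total += w
        else:
            counts[t].fn += w
            if c is not None:
                counts.setdefault(c, TaxonCounts())
                counts[c].fp += w
    for taxon, tc in counts.items():
        tc.tn = correct_total - tc.tp
    return counts


def rank_metrics(counts: Mapping[int, TaxonCounts]) -> RankEntry:
    """Macro-average the four per-taxon rates; undefined rates stay None."""
    tprs, fnrs, tnrs, fprs = [], [], [], []
    n_taxa = 0
    for tc in counts.values():
        pos = tc.tp + tc.fn
        neg = tc.tn + tc.fp
        if pos > 0:
            n_taxa += 1
            tprs.append(100.0 * tc.tp / pos)
            fnrs.append(100.0 * tc.fn / pos)
        if neg > 0:
            tnrs.append(100.0 * tc.tn / neg)
            fprs.append(100.0 * tc.fp / neg)
    if n_taxa == 0:
        raise ValueError("no evaluable taxa (no positives at this rank)")
    mean = lambda xs: float(np.mean(xs)) if xs else None  # noqa: E731
    return RankEntry(mean(tprs), mean(tnrs), mean(fprs), mean(fnrs), n_taxa)


def evaluate_ranks(
    assignments: Sequence[Assignment],
    truth: Mapping[str, int],
    taxonomy: Taxonomy,
    ranks: Sequence[str] = CANONICAL_RANKS,
) -> dict[str, RankEntry]:
    return {
        rank: rank_metrics(confusion_at_rank(assignments, truth, taxonomy, rank))
        for rank in ranks
    }


def assigned_correct_counts(
    assignments: Iterable[Assignment],
    truth: Mapping[str, int],
    taxonomy: Taxonomy,
    rank: str,
) -> tuple[int, int]:
    """Reads whose call projects to the rank, and how many match the truth.

    A deeper call projects up to the rank (a species call counts at genus
    level); a call above the rank projects to nothing and is not counted
    as assigned at that rank.
    """
    n_assigned = 0
    n_correct = 0
    for a in assignments:
        c = _project(taxonomy, a.node_id, rank)
        if c is None:
            continue
        n_assigned += a.abundance
        t = _project(taxonomy, truth.get(a.query_id), rank) if a.query_id in truth else None
        if t is not None and c == t:
            n_correct += a.abundance
    return n_assigned, n_correct


def depletion_experiment(
    references: Sequence[tuple[str, str]],
    ref_to_taxid: Mapping[str, int],
    taxonomy: Taxonomy,
    truth: Mapping[str, int],
    runner: Callable[[Sequence[tuple[str, str]], dict[str, int]], Sequence[Assignment]],
    fraction: float = 0.5,
    seed: int | None = None,
) -> DepletionReport:
    """Remove a random fraction of genera from the reference and re-classify.

    ``runner(depleted_records, depleted_map)`` must re-run the pipeline
    against the depleted reference and return per-read assignments.  Reads
    whose true genus was removed are partitioned into wrong / unassigned /
    recovered-at-family-or-above (see :class:`DepletionReport`).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")

    def genus_of(taxid: int) -> int | None:
        return rank_ancestor(taxonomy, taxid, "genus")

    genera = sorted({g for t in ref_to_taxid.values() if (g := genus_of(t)) is not None})
    if len(genera) < 2:
        raise ValueError("depletion requires at least 2 genera in the reference")
    rng = np.random.default_rng(seed)
    n_remove = int(round(fraction * len(genera)))
    removed: set[int] = (
        set(int(g) for g in rng.choice(genera, size=n_remove, replace=False))
        if n_remove
        else set()
    )

    kept_records = [
        (rid, seq) for rid, seq in references if genus_of(ref_to_taxid[rid]) not in removed
    ]
    kept_map = {rid: ref_to_taxid[rid] for rid, _ in kept_records}
    assignments = {a.query_id: a for a in runner(kept_records, kept_map)}

    affected = [qid for qid, t in truth.items() if genus_of(t) in removed]
    family_depth = RANK_DEPTH["family"]
    n_wrong = n_unassigned = n_recovered = 0
    for qid in affected:
        a = assignments.get(qid)
        if a is None or a.node_id is None:
            n_unassigned += 1
            continue
        lineage = set(taxonomy.path_to_root(truth[qid]))
        on_lineage = a.node_id in lineage
        call_rank = a.assigned_rank
        if on_lineage and call_rank is not None and RANK_DEPTH[call_rank] <= family_depth:
            n_recovered += 1
        else:
            n_wrong += 1
    return DepletionReport(
        removed_genera=tuple(sorted(removed)),
        n_affected=len(affected),
        n_wrong=n_wrong,
        n_unassigned=n_unassigned,
        n_recovered_family_or_above=n_recovered,
    )


# ---------------------------------------------------------------------------
# report I/O

def write_benchmark_report(
    metrics: Mapping[str, RankEntry],
    handle_or_path,
    *,
    undefined_display: str = "0.00",
) -> None:
    """One CSV row per rank with TPR/TNR/FPR/FNR to two decimals.

    ``undefined_display`` controls how undefined rates are rendered; the
    default "0.00" matches the usual benchmark-table convention at ranks
    with no negatives, while "NA" keeps undefinedness explicit.
    """

    def _fmt(v: float | None) -> str:
        return undefined_display if v is None else f"{v:.2f}"

    def _write(fh):
        w = csv.writer(fh)
        w.writerow(["rank", "TPR", "TNR", "FPR", "FNR"])
        for rank in CANONICAL_RANKS:
            if rank in metrics:
                e = metrics[rank]
                w.writerow([rank, _fmt(e.tpr), _fmt(e.tnr), _fmt(e.fpr), _fmt(e.fnr)])

    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "wt", newline="") as fh:
            _write(fh)
    else:
        _write(handle_or_path)


def read_benchmark_report(source) -> dict[str, dict[str, float | None]]:
    """Parse a report CSV back into rate dictionaries ("NA" -> None)."""

    def _read(fh):
        out: dict[str, dict[str, float | None]] = {}
        reader = csv.reader(fh)
        header = next(reader)
        for row in reader:
            if not row:
                continue
            out[row[0]] = {
                col: (None if val == "NA" else float(val))
                for col, val in zip(header[1:], row[1:])
            }
        return out

    if isinstance(source, (str, Path)):
        with open(source, "rt", newline="") as fh:
            return _read(fh)
    return _read(source)
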