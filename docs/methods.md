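# Methods

## Scope and model

`metabarcode` implements the bespoke computational stages of an
amplicon meta-barcoding classification workflow for Illumina paired-end
data, plus the machinery needed to benchmark it end to end without any
external downloads:

1. **read preparation** — merge overlapping mates into a consensus,
   quality-trim and length-filter pairs that do not merge, dereplicate;
2. **hit filtering** — reduce external-aligner output (BLAST tabular or
   SAM) to a per-query candidate taxon list by staged rules;
3. **taxonomic assignment** — map each candidate set to a single node of a
   ranked reference taxonomy via penalized score minimization on a guide
   tree, with the classical lowest-common-ancestor (LCA) mapping as an
   exact special case;
4. **evaluation** — per-taxon confusion counts projected to each of the
   seven canonical ranks (kingdom … species), macro-averaged
   TPR/TNR/FPR/FNR, assigned/correct tallies and a reference-depletion
   experiment;
5. **synthetic data** — degenerate-primer in-silico PCR, co-generic
   community sampling and MiSeq-like 250×2 read simulation that together
   produce truth-labeled benchmark datasets.

## Read preparation

Merging scans every suffix/prefix overlap of length ≥ `min_overlap`
(default 10) between read 1 and the reverse complement of read 2 and keeps
the overlap with the lowest mismatch ratio, ties going to the longest
overlap; the merge is rejected if the best ratio exceeds
`max_mismatch_ratio` (default 0.25). These defaults follow the published
defaults of the overlap-merging tools commonly wrapped in such pipelines
and are exposed as parameters. At a disagreeing column the base with the
higher Phred score wins (ties keep read 1); consensus quality is the
maximum of the two scores at agreement and their absolute difference at
disagreement.

Only pairs that fail to merge are quality-trimmed, mirroring the workflow
this package models. Trimming removes the 3' region by partial-sum
minimization: walking from the 3' end, accumulate `q − cutoff` and cut
where the running sum is lowest. A base exactly at the cutoff (default
Phred 25) counts as low quality, so a trailing run at the cutoff is
removed. Pairs with a mate shorter than 50 nt after trimming are dropped
("shorter than" is strict: 50/50 survives). Dereplication is exact,
case-insensitive full-length grouping; the representative is the
first-seen id.

Every input pair lands in exactly one of {merged, kept-unmerged, dropped};
this partition is asserted in the tests.

## Hit filtering

Per query, three stages in a fixed order:

1. numeric thresholds — identity ≥ 97 % and query coverage ≥ 70 %, both
   inclusive; hits to references absent from the guide tree are dropped
   here too (they carry no taxonomic information);
2. score tolerance — keep hits scoring at least 95 % of the best surviving
   score (the "within 5 % of the best match" rule read fractionally, not
   as an absolute offset);
3. completeness priority — if any survivor maps to a reference whose
   lineage populates all seven ranks with informative names, survivors
   mapping to incomplete references (missing ranks, or names containing
   "uncultured", "environmental sample", "unidentified" — configurable
   patterns) are discarded.

The stage order matters (completeness-first would change results) and is
fixed deliberately: thresholds define candidacy, the score tolerance
defines the competitive set, and completeness only arbitrates among
already-competitive hits. For SAM input the aligner's alignment score (AS
tag) plays the bit score's role; proper pairs collapse to one record with
mate-averaged identity/coverage and summed score.

## Assignment

Given a query's matched taxa `S` on a guide tree with `R` mapped
references, every taxonomy node `n` is scored

    score(n) = q · FN(n) + (1 − q) · FP(n)

with FN(n) = matched references outside the subtree of `n` and FP(n) =
unmatched references inside it. The minimizing node wins; ties prefer the
deepest node, then the smallest node id, making runs reproducible. The
scan covers *every* node (O(nodes) per query using subtree reference
counts precomputed on the guide tree), not just ancestors of the LCA — a
node off the LCA path can be optimal when `q` is small, and restricting
candidates would silently miss it.

Matched taxa are weighted by their reference multiplicity, with a floor of
one for matched taxa that have no directly mapped reference; this floor is
what makes `q = 1` reduce *exactly* to the LCA of the matched taxa for all
inputs. The default `q = 0.5` penalizes false negatives and false
positives symmetrically; `q = 1` recovers classical LCA behaviour for
users who want it.

Profiles are cumulative: an assignment at a species increments that
species and every ancestor, so per-rank tables read off node counts at
each rank and counts never increase toward the leaves. Reads assigned at
no-rank nodes report the nearest ranked ancestor's rank in rank-indexed
tables.

## Evaluation

Truth and call are projected to the evaluated rank via ranked-ancestor
lookup. Calls above the rank project to nothing and count in FN of the
read's true taxon (they are "not assigned to i"); reads whose truth lacks
the rank are not evaluable there. TN_i is computed as (reads whose call
equals their own truth) − TP_i, which is algebraically identical to the
per-read definition. Taxa appearing only in calls accrue FP but are
excluded from the TPR/FNR means (no positives exist, avoiding 0/0);
rates with empty denominators are stored as undefined (`None`) and only
rendered as "0.00" in the compatibility output mode, since a single-taxon
rank genuinely has no negatives.

The depletion experiment removes every reference of a uniformly sampled
fraction of genera (deterministic under seed), re-runs filtering and
assignment, and partitions reads of removed genera into: **wrong** (call
off the true lineage), **unassigned**, and **recovered** (call on the true
lineage at family rank or above). A call on the true lineage below family
cannot occur when whole genera are removed, so the three buckets always
partition the affected reads.

## Synthetic data generator

The generator emulates the construction of a truth-labeled mock dataset:

* **taxonomy** — a complete seven-rank tree (default 10 genera × 3
  species across 4 families, 2 phyla), so lineage-completeness checks and
  rank projection are exercised end to end;
* **reference markers** — each genus gets an independent random core
  sequence; species cores diverge from the genus core at 8 %
  substitutions; references diverge from their species core at 0.5 %.
  Within-species identity (~99 %) therefore exceeds within-genus
  cross-species identity (~85 %), which in turn exceeds between-genus
  identity (background), giving the classifier a realistic hierarchy of
  similarity. Exact primer annealing sites (one concrete realization of
  the degenerate universal primers) flank each core, so in-silico PCR
  recovers exactly one amplicon per reference;
* **in-silico PCR** — exact degenerate IUPAC matching (0 mismatches by
  default, a tolerance knob exists), both strands scanned, leftmost-first
  non-nested site pairing, products capped at 2,000 nt (unbounded pairing
  is biologically meaningless);
* **communities** — sampling without replacement that forces a minimum
  number of co-generic species (species sharing a genus with another
  selected species), the hardest case for a marker; infeasible constraints
  report the achievable maximum;
* **reads** — 250×2 pairs from the amplicon ends, substitution-only
  errors (default 0.1 %, benchmark fixtures use 0 % and 0.5 %), Phred
  scores from a normal (36, 3) clipped to [2, 41], Phred+33 on disk.
  Amplicons shorter than the read length yield reads at amplicon length
  (adapter read-through is assumed trimmed, never padded). The 16S V5-V6
  length profile is narrow (280–320 nt cores); the ITS1 profile is wide
  (120–480 nt), reproducing that locus's marked length variability.

What the generator does **not** emulate: indels and homopolymer errors,
chimeras, PCR amplification bias, 454 flowgram noise, incomplete or
mislabeled reference annotations, and the sheer taxonomic breadth of real
reference collections. Consequences worth knowing: because genus cores are
independent, reads of a genus removed from the reference have no
family-level similarity to fall back on — the depletion experiment on the
default fixture yields (correctly) ~100 % unassigned and an empty
family-recovery bucket, whereas real references show partial family-level
recovery. Passing benchmarks here demonstrate the correctness of the
machinery under controlled conditions, not field performance on real
communities.

## Self-contained similarity search

Production runs consume alignments from an external aligner. For
benchmarks that must run with no external inputs, `pipeline.search_hits`
aligns every consensus inside every reference with a banded semi-global
edit-distance search (edlib): identity is the matched fraction of
alignment columns, coverage is 100 (the whole query aligns in infix
mode), and the hit score — standing in for the bit score in the 5 %
rule — is the count of matched columns. Alignments whose edit distance
exceeds 12 % of the query length are pruned early; hits below 90 %
identity are not reported, so the ≥97 % filter still does real work.

## Numerical choices and degenerate inputs

* Thresholds 97.0 / 70.0 are inclusive; the score tolerance is
  fractional (≥ 0.95 × best).
* Merge tie-break: equal mismatch ratio → longest overlap; consensus
  base tie (equal Phred) → read 1.
* Assignment tie-break: lowest score → deepest → smallest node id.
* Empty match set → unassigned, never an error; zero-survivor queries are
  unassigned downstream.
* Undefined rates are `None` internally; rendering is a display decision.
* All randomness flows through `numpy.random.Generator`; composite
  simulations derive child seeds from a `SeedSequence`, kept below 2³¹.

## Problem sizes

End-to-end fixtures use 30 species in 10 genera with 100 pairs per
species (3,000 pairs), with a complete 90-reference synthetic database —
large enough that every rank has multiple taxa and co-generic
discrimination is exercised, small enough to run interactively. Oracle
checks use 10,000 random hit tables, 1,000 random guide trees × three
values of `q`, and 1,000 error-free merge pairs. The full test suite runs
in ~10 s and the acceptance script in ~7 s on one CPU.

## Known limitations

* Dereplication is exact-match only (no prefix clustering or abundance
  sorting beyond first-seen representatives).
* The assignment objective is a principled stand-in for penalized
  guide-tree mapping with an exact LCA special case; it does not claim
  bit-compatibility with any particular external implementation.
* BLAST XML is not parsed (tabular only); aligners are never executed by
  the pipeline itself.
* The paired-coverage semantics for SAM input (mate averaging) are one
  defensible reading of an under-specified convention and are fixed here.
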