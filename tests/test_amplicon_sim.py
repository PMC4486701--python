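"""In-silico PCR, community sampling and read simulation."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from metabarcode.amplicon_sim import (
    ITS1_CORE_LEN,
    V5V6_CORE_LEN,
    V5V6_PRIMERS,
    extract_amplicons,
    iupac_match_positions,
    sample_community,
    simulate_paired_reads,
    simulate_reference_db,
    simulate_taxonomy,
)


class TestIupacMatching:
    def test_ambiguity_code_matches_member_base(self):
        assert iupac_match_positions("AY", "ACG") == [0]

    def test_n_matches_every_window(self):
        assert iupac_match_positions("NNN", "ACGT") == [0, 1]

    def test_printed_forward_primer_matches_planted_site(self):
        # Y in the degenerate primer must accept the planted T realization
        site = "TTAGATACCCTGGTAGTCC"
        seq = "GGGG" + site + "AAAA"
        assert iupac_match_positions(V5V6_PRIMERS.forward, seq) == [4]

    def test_mismatch_budget(self):
        assert iupac_match_positions("AAAA", "AAAT", max_mismatches=0) == []
        assert iupac_match_positions("AAAA", "AAAT", max_mismatches=1) == [0]

    def test_non_iupac_character_rejected(self):
        with pytest.raises(ValueError):
            iupac_match_positions("AXG", "ACGT")


def _brute_force_pairing(seq, fwd, rev_rc, max_len):
    """Independent re-statement of the pairing rule: leftmost-first, each
    forward site takes the nearest downstream unconsumed reverse site."""
    f_sites = iupac_match_positions(fwd, seq)
    r_sites = iupac_match_positions(rev_rc, seq)
    used = set()
    out = []
    for f in f_sites:
        candidates = [r for r in r_sites if r not in used and r >= f + len(fwd)]
        if not candidates:
            continue
        r = min(candidates)
        if r + len(rev_rc) - f <= max_len:
            out.append((f, r + len(rev_rc)))
            used.add(r)
    return out


class TestExtractAmplicons:
    FWD = "ACGTACGTACGT"
    REV = "TTGGCCAATTGG"  # given 5'->3' on the opposite strand

    def test_constructed_amplicon_length(self):
        insert = "A" * 20
        seq = self.FWD + insert + reverse_complement(self.REV)
        amps = extract_amplicons("s", seq, 1, type(V5V6_PRIMERS)(self.FWD, self.REV))
        plus = [a for a in amps if a.strand == "+"]
        assert len(plus) == 1
        assert len(plus[0].sequence) == len(self.FWD) + 20 + len(self.REV)
        assert plus[0].sequence == seq

    def test_forward_site_only_yields_nothing(self):
        seq = "C" * 30 + self.FWD + "C" * 30
        primers = type(V5V6_PRIMERS)(self.FWD, self.REV)
        assert extract_amplicons("s", seq, 1, primers) == []

    def test_minus_strand_amplicon_reported_on_plus(self):
        insert = "ACGGTTACCGGATCCAAGGT"
        plus_amp = self.FWD + insert + reverse_complement(self.REV)
        source = "GG" + reverse_complement(plus_amp) + "TT"
        primers = type(V5V6_PRIMERS)(self.FWD, self.REV)
        amps = extract_amplicons("s", source, 1, primers)
        minus = [a for a in amps if a.strand == "-"]
        assert len(minus) == 1
        assert minus[0].sequence == plus_amp
        assert reverse_complement(source[minus[0].start:minus[0].end]) == plus_amp

    def test_coordinates_always_slice_the_source(self):
        rng = np.random.default_rng(5)
        primers = type(V5V6_PRIMERS)(self.FWD, self.REV)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
            # plant a site pair
            pos = int(rng.integers(0, 300))
            seq = seq[:pos] + self.FWD + seq[pos:pos + 60] + reverse_complement(self.REV) + seq[pos + 60:]
            for a in extract_amplicons("s", seq, 1, primers):
                sliced = seq[a.start:a.end]
                expected = sliced if a.strand == "+" else reverse_complement(sliced)
                assert a.sequence == expected

    def test_matches_bruteforce_pairing_on_planted_sites(self):
        """Planted multi-site sequences agree with an exhaustive pairing oracle."""
        rng = np.random.default_rng(11)
        primers = type(V5V6_PRIMERS)(self.FWD, self.REV)
        for rep in range(10):
            chunks = []
            for _ in range(3):
                chunks.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=1500)))
                chunks.append(self.FWD)
                chunks.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=200)))
                chunks.append(reverse_complement(self.REV))
            chunks.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=1500)))
            seq = "".join(chunks)
            got = [
                (a.start, a.end) for a in extract_amplicons("s", seq, 1, primers, 2000)
                if a.strand == "+"
            ]
            expected = _brute_force_pairing(
                seq, self.FWD, reverse_complement(self.REV), 2000
            )
            assert got == expected

    def test_trim_primers_removes_annealing_sites(self):
        insert = "ACGGTTACCGGATCCAAGGT"
        seq = self.FWD + insert + reverse_complement(self.REV)
        primers = type(V5V6_PRIMERS)(self.FWD, self.REV)
        amps = extract_amplicons("s", seq, 1, primers, trim_primers=True)
        assert amps[0].sequence == insert


class TestSampleCommunity:
    def _pool(self, n_genera=40, per_genus=3):
        _, pool = simulate_taxonomy(n_genera, per_genus)
        return pool

    def _cogeneric_count(self, selected, pool):
        genus_of = dict(pool)
        from collections import Counter

        per_genus = Counter(genus_of[t] for t in selected)
        return sum(c for c in per_genus.values() if c >= 2)

    def test_benchmark_sizing_with_forced_cogenerics(self):
        pool = self._pool()
        sel = sample_community(pool, 102, min_cogeneric=58, seed=3)
        assert len(sel) == len(set(sel)) == 102
        assert self._cogeneric_count(sel, pool) >= 58

    def test_zero_constraint_is_plain_sampling(self):
        pool = self._pool(5, 2)
        sel = sample_community(pool, 4, min_cogeneric=0, seed=1)
        assert len(sel) == 4
        assert set(sel) <= {t for t, _ in pool}

    def test_infeasible_constraint_reports_maximum(self):
        pool = [(i, i) for i in range(1, 6)]  # 5 genera x 1 species
        with pytest.raises(ValueError, match="at most 0"):
            sample_community(pool, 4, min_cogeneric=2, seed=0)

    def test_deterministic_under_seed(self):
        pool = self._pool()
        assert sample_community(pool, 20, 10, seed=9) == sample_community(pool, 20, 10, seed=9)


class TestSimulateReads:
    def _amplicon(self, length=300, seed=0):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        from metabarcode.amplicon_sim import AmpliconRecord

        return AmpliconRecord("amp1", "src", 7, seq, 0, length)

    def test_error_free_reads_are_exact_slices(self):
        amp = self._amplicon(300)
        (pair,) = simulate_paired_reads(amp, 1, read_len=250, substitution_rate=0.0, seed=1)
        assert pair.read1_seq == amp.sequence[:250]
        assert pair.read2_seq == reverse_complement(amp.sequence[50:300])
        assert len(pair.read1_quals) == len(pair.read1_seq)

    def test_short_amplicon_reads_at_amplicon_length(self):
        amp = self._amplicon(180)
        (pair,) = simulate_paired_reads(amp, 1, read_len=250, substitution_rate=0.0, seed=1)
        assert len(pair.read1_seq) == len(pair.read2_seq) == 180

    def test_substitution_rate_within_binomial_error(self):
        amp = self._amplicon(300, seed=2)
        rate = 0.01
        pairs = simulate_paired_reads(amp, 2000, 250, rate, seed=4)
        tmpl1 = amp.sequence[:250]
        mism = sum(
            sum(a != b for a, b in zip(p.read1_seq, tmpl1)) for p in pairs
        )
        n = 2000 * 250
        se = (rate * (1 - rate) / n) ** 0.5
        assert abs(mism / n - rate) < 3 * se

    def test_quals_clipped_to_phred_range(self):
        amp = self._amplicon(300)
        pairs = simulate_paired_reads(amp, 5, 250, 0.0, qual_model=(10, 30), seed=3)
        allq = [q for p in pairs for q in p.read1_quals + p.read2_quals]
        assert min(allq) >= 2 and max(allq) <= 41

    def test_deterministic_under_seed(self):
        amp = self._amplicon(300)
        a = simulate_paired_reads(amp, 10, 250, 0.01, seed=5)
        b = simulate_paired_reads(amp, 10, 250, 0.01, seed=5)
        assert a == b


class TestReferenceDb:
    def test_single_species_single_ref(self):
        tax, _ = simulate_taxonomy(1, 1)
        records, ref_map = simulate_reference_db(tax, 1, seed=0)
        assert len(records) == len(ref_map) == 1

    def test_within_species_identity_exceeds_between_genus(self):
        import edlib

        tax, _ = simulate_taxonomy(5, 2)
        records, ref_map = simulate_reference_db(tax, 2, seed=1)
        from metabarcode.taxonomy import rank_ancestor

        def identity(a, b):
            d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
            return 1 - d / max(len(a), len(b))

        within, between = [], []
        for i, (rid_i, seq_i) in enumerate(records):
            for rid_j, seq_j in records[i + 1:]:
                sp_i, sp_j = ref_map[rid_i], ref_map[rid_j]
                g_i = rank_ancestor(tax, sp_i, "genus")
                g_j = rank_ancestor(tax, sp_j, "genus")
                if sp_i == sp_j:
                    within.append(identity(seq_i, seq_j))
                elif g_i != g_j:
                    between.append(identity(seq_i, seq_j))
        assert min(within) > max(between)

    def test_byte_identical_under_seed(self):
        tax, _ = simulate_taxonomy(3, 2)
        assert simulate_reference_db(tax, 2, seed=7) == simulate_reference_db(tax, 2, seed=7)

    def test_its1_length_variability_exceeds_v5v6(self):
        """The ITS1 profile is far more length-variable than V5-V6."""
        from metabarcode.amplicon_sim import ITS1_PRIMERS, extract_amplicons

        tax, _ = simulate_taxonomy(10, 2)
        lengths = {}
        for name, (primers, core) in {
            "v5v6": (V5V6_PRIMERS, V5V6_CORE_LEN),
            "its1": (ITS1_PRIMERS, ITS1_CORE_LEN),
        }.items():
            records, ref_map = simulate_reference_db(
                tax, 1, core, seed=13, primers=primers
            )
            ls = []
            for rid, seq in records:
                for a in extract_amplicons(rid, seq, ref_map[rid], primers):
                    ls.append(len(a.sequence))
            lengths[name] = np.std(ls)
        assert lengths["its1"] > lengths["v5v6"]
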