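"""Trimming, the micro-mapper (vs. an exhaustive alignment oracle),
pileups and terminus calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosmallrna.model import GenomeRecord, MappedRead, Read, revcomp
from nanosmallrna.reads import (
    MapConfig,
    MicroMapper,
    ReadPileup,
    TrimConfig,
    build_pileup,
    call_termini,
    map_reads,
    screen_intergenic,
    trim_reads,
)

from .oracles import exhaustive_alignment_cost


def _mk_reads(seqs, q=40):
    return [Read(f"r{i}", s, [q] * len(s)) for i, s in enumerate(seqs)]


class TestTrim:
    def test_short_read_discarded(self):
        kept, log = trim_reads(_mk_reads(["ACGTACGTACGTAC"]))  # 14 nt
        assert kept == [] and log["too_short"] == 1

    def test_clean_high_quality_read_unchanged(self):
        read = Read("r", "ACGTACGTACGTACGTACGT", [40] * 20)
        kept, _ = trim_reads([read])
        assert kept[0].sequence == read.sequence

    def test_polya_tail_removed_matches_suffix_scan(self, rng):
        body = "ACGTCGTACGTCGTACG"
        for run in (6, 8, 10):
            seq = body + "A" * run
            kept, _ = trim_reads(_mk_reads([seq]), TrimConfig(polyA_min_run=6))
            # direct suffix-scan oracle
            n = len(seq)
            while n > 0 and seq[n - 1] == "A":
                n -= 1
            assert kept[0].sequence == seq[:n]

    def test_polya_below_min_run_kept(self):
        seq = "ACGTCGTACGTCGTACG" + "AAAA"
        kept, _ = trim_reads(_mk_reads([seq]), TrimConfig(polyA_min_run=6))
        assert kept[0].sequence == seq

    def test_adapter_suffix_removed(self):
        adapter = "AGATCGGAAGAGC"
        insert = "TTGACCGTAGGCTAACG"
        kept, _ = trim_reads(_mk_reads([insert + adapter]))
        assert kept[0].sequence == insert

    def test_low_quality_tail_trimmed(self):
        seq = "ACGTACGTACGTACGTACGT" + "GGGGGGGGGG"
        quals = [40] * 20 + [2] * 10
        kept, _ = trim_reads([Read("r", seq, quals)])
        assert kept[0].sequence == seq[:20]


class TestMapper:
    def test_exact_substring_maps_cost_zero(self, rng):
        from .conftest import random_seq

        genome = GenomeRecord("g", random_seq(rng, 2000))
        read = Read("r", genome.sequence[700:730])
        hits = MicroMapper(genome).map_read(read)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand, hits[0].edit_cost) == (
            700, 730, "+", 0.0,
        )

    def test_reverse_complement_strand_symmetry(self, rng):
        from .conftest import random_seq

        genome = GenomeRecord("g", random_seq(rng, 2000))
        read = Read("r", revcomp(genome.sequence[700:730]))
        hits = MicroMapper(genome).map_read(read)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (700, 730, "-")

    def test_mismatch_plus_deletion_costs_five(self, rng):
        from .conftest import random_seq

        genome = GenomeRecord("g", random_seq(rng, 1500))
        locus = genome.sequence[500:530]
        # one substitution at position 5 and one deleted base at position 20
        read_seq = locus[:5] + ("T" if locus[5] != "T" else "G") + locus[6:20] + locus[21:]
        hits = MicroMapper(genome).map_read(Read("r", read_seq))
        assert hits, "read with 1 mismatch + 1 deletion should map"
        assert hits[0].edit_cost == 5.0  # 2 (mismatch) + 3 (deletion)
        oracle_cost, _ = exhaustive_alignment_cost(read_seq, genome.sequence)
        assert hits[0].edit_cost == oracle_cost

    def test_agrees_with_exhaustive_oracle(self, rng):
        """Accepted placements and costs equal full-matrix DP over all
        positions and strands, for reads with a unique optimum."""
        from .conftest import random_seq

        genome = GenomeRecord("g", random_seq(rng, 600))
        mapper = MicroMapper(genome)
        checked = 0
        for _ in range(25):
            start = int(rng.integers(0, 560))
            length = int(rng.integers(20, 41))
            seq = list(genome.sequence[start : start + length])
            n_edits = int(rng.integers(0, 3))
            for _ in range(n_edits):
                op = rng.integers(3)
                pos = int(rng.integers(1, len(seq) - 1))
                if op == 0:
                    seq[pos] = "ACGT"[int(rng.integers(4))]
                elif op == 1 and len(seq) > 20:
                    del seq[pos]
                else:
                    seq.insert(pos, "ACGT"[int(rng.integers(4))])
            read_seq = "".join(seq)
            if int(rng.integers(2)):
                read_seq = revcomp(read_seq)
            cost, ends = exhaustive_alignment_cost(read_seq, genome.sequence)
            hits = mapper.map_read(Read("r", read_seq))
            if not hits:
                continue  # rejected by identity threshold; oracle has no filter
            assert hits[0].edit_cost == cost
            if len(ends) == 1:
                (end, strand) = next(iter(ends))
                assert hits[0].is_unique
                assert (hits[0].end, hits[0].strand) == (end, strand)
            checked += 1
        assert checked >= 15

    def test_multimap_policies(self, rng):
        genome = GenomeRecord("g", "ACGTACGGTTCAGGACTGA" + "CCCTTAGGCAAGTCA" * 2)
        repeat_read = Read("r", "CCCTTAGGCAAGTCA")
        for policy, expected in (("report_all", 2), ("discard", 0)):
            mapped, _ = map_reads(
                [repeat_read], genome, MapConfig(multimap_policy=policy), seed=0
            )
            assert len(mapped) == expected
        placed, _ = map_reads([repeat_read], genome, MapConfig(), seed=0)
        assert len(placed) == 1 and not placed[0].is_unique
        again, _ = map_reads([repeat_read], genome, MapConfig(), seed=0)
        assert placed[0].start == again[0].start  # seeded determinism


class TestPileup:
    def test_single_read_depth_and_ends(self):
        genome = GenomeRecord("g", "A" * 100)
        pileup = build_pileup([MappedRead("r", "g", 10, 40, "+")], genome)
        assert pileup.depth["+"][10:40].sum() == 30
        assert pileup.five_prime_ends["+"][10] == 1
        assert pileup.three_prime_ends["+"][39] == 1

    def test_linearity_in_read_multiplicity(self):
        genome = GenomeRecord("g", "A" * 50)
        reads = [MappedRead(f"r{i}", "g", 5, 25, "-") for i in range(7)]
        pileup = build_pileup(reads, genome)
        assert pileup.depth["-"][5:25].tolist() == [7] * 20
        assert pileup.five_prime_ends["-"][24] == 7
        assert pileup.three_prime_ends["-"][5] == 7

    @given(
        st.lists(
            st.tuples(st.integers(0, 180), st.integers(1, 20), st.sampled_from("+-")),
            min_size=0,
            max_size=30,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_end_count_conservation_and_depth_mass(self, intervals):
        genome = GenomeRecord("g", "A" * 200)
        reads = [
            MappedRead(f"r{i}", "g", s, s + ln, strand)
            for i, (s, ln, strand) in enumerate(intervals)
        ]
        pileup = build_pileup(reads, genome)  # .check() runs inside
        for strand in "+-":
            sub = [r for r in reads if r.strand == strand]
            assert pileup.five_prime_ends[strand].sum() == len(sub)
            assert pileup.three_prime_ends[strand].sum() == len(sub)
            assert pileup.depth[strand].sum() == sum(r.end - r.start for r in sub)

    def test_out_of_bounds_read_rejected(self):
        genome = GenomeRecord("g", "A" * 20)
        with pytest.raises(ValueError):
            build_pileup([MappedRead("r", "g", 10, 25, "+")], genome)


class TestTermini:
    def _pileup_with_ends(self, positions_counts, side="5p", strand="+"):
        genome = GenomeRecord("g", "A" * 200)
        pileup = ReadPileup(genome)
        arr = (
            pileup.five_prime_ends if side == "5p" else pileup.three_prime_ends
        )[strand]
        for pos, count in positions_counts.items():
            arr[pos] = count
        return pileup

    def test_single_shared_end_fraction_one(self):
        pileup = self._pileup_with_ends({50: 20})
        calls = call_termini(pileup, (0, 200), "+", "5p", min_support=2)
        assert len(calls) == 1
        assert (calls[0].position, calls[0].local_fraction, calls[0].is_hotspot) == (
            50, 1.0, False,
        )

    def test_secondary_maximum_flagged_as_hotspot(self):
        pileup = self._pileup_with_ends({50: 60, 52: 40}, side="3p")
        calls = call_termini(pileup, (0, 200), "+", "3p", min_support=2, window=10)
        assert calls[0].position == 50 and not calls[0].is_hotspot
        hot = [c for c in calls if c.is_hotspot]
        assert [c.position for c in hot] == [52]
        assert hot[0].local_fraction == pytest.approx(0.4)

    def test_min_support_filters_noise(self):
        pileup = self._pileup_with_ends({50: 10, 80: 1})
        calls = call_termini(pileup, (0, 200), "+", "5p", min_support=2)
        assert [c.position for c in calls] == [50]

    def test_empty_region_returns_empty(self):
        pileup = self._pileup_with_ends({})
        assert call_termini(pileup, (0, 200), "+", "5p") == []


class TestIntergenicScreen:
    def test_no_reads_empty(self):
        genome = GenomeRecord("g", "A" * 100)
        assert screen_intergenic(ReadPileup(genome), [], min_coverage=10) == []

    def test_planted_expressed_region_found_and_threshold_inclusive(self):
        from nanosmallrna.model import Feature

        genome = GenomeRecord("g", "A" * 300)
        pileup = ReadPileup(genome)
        pileup.depth["+"][100:150] = 1000  # exactly at threshold: included
        pileup.depth["+"][160:170] = 999
        features = [Feature("gene", "g", 0, 50, "+", "gene")]
        regions = screen_intergenic(pileup, features, min_coverage=1000)
        assert regions == [(100, 150, "+")]

    def test_gap_merging(self):
        genome = GenomeRecord("g", "A" * 300)
        pileup = ReadPileup(genome)
        pileup.depth["-"][100:120] = 50
        pileup.depth["-"][125:140] = 50  # 5-nt gap, merged
        pileup.depth["-"][180:190] = 50  # 40-nt gap, separate
        regions = screen_intergenic(pileup, [], min_coverage=50, merge_gap=10)
        assert regions == [(100, 140, "-"), (180, 190, "-")]
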