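"""CRISPR array detection, orientation, maturation and promoter analysis."""

import numpy as np
import pytest

from nanosmallrna.crispr import (
    CrisprArray,
    CrisprParams,
    call_tss,
    compare_leaders,
    detect_arrays,
    find_boxA,
    infer_maturation,
    orient_array,
)
from nanosmallrna.model import GenomeRecord, MappedRead, revcomp
from nanosmallrna.reads import ReadPileup, build_pileup

from .conftest import random_seq


def _build_array_genome(rng, n_spacers=4, repeat=None, leader=None, pad=2000,
                        spacer_len=38):
    repeat = repeat or (random_seq(rng, 20) + "ATTGAAAG")
    leader = leader if leader is not None else random_seq(rng, 300)
    spacers = [random_seq(rng, spacer_len) for _ in range(n_spacers)]
    parts = [random_seq(rng, pad), leader]
    first_repeat = sum(len(p) for p in parts)
    body = repeat + "".join(s + repeat for s in spacers)
    parts.append(body)
    parts.append(random_seq(rng, pad))
    genome = GenomeRecord("toy", "".join(parts))
    return genome, repeat, spacers, first_repeat


class TestDetection:
    def test_planted_array_recovered_by_construction(self, rng):
        genome, repeat, spacers, first = _build_array_genome(rng)
        arrays = detect_arrays(genome)
        assert len(arrays) == 1
        arr = arrays[0]
        assert len(arr.spacers) == 4
        assert arr.repeat_consensus == repeat
        assert arr.repeats[0] == (first, first + 28)
        assert arr.spacer_seqs == spacers

    def test_uniform_random_sequence_yields_no_arrays(self):
        rng = np.random.default_rng(7)
        genome = GenomeRecord("rand", random_seq(rng, 10_000))
        assert detect_arrays(genome) == []

    def test_overlong_spacer_flagged_but_chain_unbroken(self, rng):
        repeat = random_seq(rng, 20) + "ATTGAAAG"
        spacers = [random_seq(rng, 38) for _ in range(4)]
        spacers[1] = random_seq(rng, 60)  # > spacer_len_max, within soft bound
        body = repeat + "".join(s + repeat for s in spacers)
        genome = GenomeRecord("toy", random_seq(rng, 1000) + body + random_seq(rng, 1000))
        (arr,) = detect_arrays(genome)
        assert len(arr.spacers) == 4
        assert arr.flags.get("long_spacer") == [1]

    def test_too_few_repeats_rejected(self, rng):
        repeat = random_seq(rng, 28)
        body = repeat + random_seq(rng, 38) + repeat  # only 2 copies
        genome = GenomeRecord("toy", random_seq(rng, 1000) + body + random_seq(rng, 1000))
        assert detect_arrays(genome) == []


class TestOrientation:
    def _pileup_over(self, genome, start, end, strand, n=20):
        reads = [
            MappedRead(f"r{i}", genome.contig_id, start + i, start + i + 30, strand)
            for i in range(n)
            if start + i + 30 <= end
        ]
        return build_pileup(reads, genome)

    def test_read_majority_sets_strand(self, rng):
        genome, *_ = _build_array_genome(rng)
        (arr,) = detect_arrays(genome)
        pileup = self._pileup_over(genome, arr.start, arr.end, "-")
        orient_array(arr, pileup, genome)
        assert arr.strand == "-"
        assert arr.orientation_method == "reads"

    def test_genome_only_fallback_uses_at_rich_leader(self, rng):
        at_leader = "".join("AT"[int(b)] for b in rng.integers(0, 2, 200))
        genome, *_ = _build_array_genome(rng, leader=at_leader)
        (arr,) = detect_arrays(genome)
        orient_array(arr, None, genome)
        assert arr.orientation_method == "sequence"
        assert arr.strand == "+"
        assert arr.leader is not None and arr.leader[1] == arr.repeats[0][0]


class TestMaturation:
    def _simulate_crrnas(self, genome, arr, strand, tag_len=8, counts=None):
        reads = []
        counts = counts or [30] * len(arr.spacers)
        order = arr.spacer_order()
        for rank, idx in enumerate(order):
            a, b = arr.spacers[idx]
            for i in range(counts[rank]):
                if strand == "+":
                    reads.append(
                        MappedRead(f"c{idx}_{i}", genome.contig_id, a - tag_len, b + 10, "+")
                    )
                else:
                    reads.append(
                        MappedRead(f"c{idx}_{i}", genome.contig_id, a - 10, b + tag_len, "-")
                    )
        return build_pileup(reads, genome)

    def test_planted_tag_length_recovered(self, rng):
        genome, repeat, _, _ = _build_array_genome(rng)
        (arr,) = detect_arrays(genome)
        pileup = self._simulate_crrnas(genome, arr, "+")
        orient_array(arr, pileup, genome)
        profile = infer_maturation(arr, pileup)
        assert profile.five_tag_length == 8
        assert profile.five_tag_sequence == "ATTGAAAG"
        assert profile.per_spacer_tag_length == [8, 8, 8, 8]

    def test_tag_sequence_is_repeat_consensus_suffix(self, rng):
        genome, repeat, _, _ = _build_array_genome(rng)
        (arr,) = detect_arrays(genome)
        pileup = self._simulate_crrnas(genome, arr, "+")
        orient_array(arr, pileup, genome)
        profile = infer_maturation(arr, pileup)
        assert arr.repeat_consensus.endswith(profile.five_tag_sequence)

    def test_abundances_normalised_and_ordered(self, rng):
        genome, *_ = _build_array_genome(rng)
        (arr,) = detect_arrays(genome)
        counts = [40, 20, 10, 5]
        pileup = self._simulate_crrnas(genome, arr, "+", counts=counts)
        orient_array(arr, pileup, genome)
        profile = infer_maturation(arr, pileup)
        assert sum(profile.relative_abundance) == pytest.approx(1.0, abs=1e-9)
        assert profile.read_counts == counts

    def test_minus_strand_array_maturation(self, rng):
        genome, repeat, _, _ = _build_array_genome(rng)
        (arr,) = detect_arrays(genome)
        pileup = self._simulate_crrnas(genome, arr, "-")
        orient_array(arr, pileup, genome)
        assert arr.strand == "-"
        profile = infer_maturation(arr, pileup)
        assert profile.five_tag_length == 8
        assert profile.five_tag_sequence == revcomp(repeat)[-8:]

    def test_zero_read_spacer_flagged(self, rng):
        genome, *_ = _build_array_genome(rng)
        (arr,) = detect_arrays(genome)
        counts = [30, 30, 0, 30]
        pileup = self._simulate_crrnas(genome, arr, "+", counts=counts)
        orient_array(arr, pileup, genome)
        profile = infer_maturation(arr, pileup)
        assert profile.zero_read_spacers == [2]
        assert profile.per_spacer_tag_length[2] is None


class TestLeaders:
    def _two_arrays(self, rng, shared_len=130):
        shared = random_seq(rng, shared_len)
        repeat = random_seq(rng, 20) + "ATTGAAAG"
        parts = []
        firsts = []
        for i in range(2):
            private = random_seq(rng, 150)
            parts.append(random_seq(rng, 800))
            parts.append(private[:-1] + ("A" if private[-1] != "A" else "C"))
            if i == 1:
                # differ from array 0 immediately before the shared stretch
                parts[-1] = parts[-1][:-1] + (
                    "G" if parts[1][-1] != "G" else "T"
                )
            parts.append(shared)
            firsts.append(sum(len(p) for p in parts))
            parts.append(repeat + random_seq(rng, 38) + repeat + random_seq(rng, 38) + repeat)
        genome = GenomeRecord("toy", "".join(parts) + random_seq(rng, 500))
        arrays = detect_arrays(genome)
        for arr in arrays:
            arr.strand = "+"
        return genome, arrays

    def test_identical_leader_length_exact(self, rng):
        genome, arrays = self._two_arrays(rng, shared_len=130)
        assert len(arrays) == 2
        res = compare_leaders(arrays[0], arrays[1], genome)
        assert res.identical_prefix_length == 130

    def test_independent_leaders_match_character_walk(self, rng):
        genome, arrays = self._two_arrays(rng, shared_len=0)
        res = compare_leaders(arrays[0], arrays[1], genome)
        # character-walk oracle
        a = arrays[0].repeats[0][0]
        b = arrays[1].repeats[0][0]
        n = 0
        while genome.sequence[a - 1 - n] == genome.sequence[b - 1 - n]:
            n += 1
        assert res.identical_prefix_length == n


class TestTssAndBoxA:
    def _array_with_tss_reads(self, rng, offset=33):
        genome, repeat, _, first = _build_array_genome(rng)
        (arr,) = detect_arrays(genome)
        tss = first - offset
        reads = [
            MappedRead(f"t{i}", genome.contig_id, tss, tss + 55, "+") for i in range(25)
        ] + [
            MappedRead(f"s{i}", genome.contig_id, arr.spacers[0][0] - 8,
                       arr.spacers[0][1], "+")
            for i in range(40)
        ]
        pileup = build_pileup(reads, genome)
        orient_array(arr, pileup, genome)
        return genome, arr, pileup, tss

    def test_planted_tss_recovered_with_offset(self, rng):
        genome, arr, pileup, tss = self._array_with_tss_reads(rng)
        res = call_tss(arr, pileup, genome)
        assert res.tss_position == tss
        assert res.tss_offset_to_first_repeat == 33
        assert res.tss_base == genome.sequence[tss]

    def test_tied_modes_pick_upstream_most(self, rng):
        genome, repeat, _, first = _build_array_genome(rng)
        (arr,) = detect_arrays(genome)
        arr.strand = "+"
        reads = [
            MappedRead(f"a{i}", genome.contig_id, first - 40, first, "+")
            for i in range(10)
        ] + [
            MappedRead(f"b{i}", genome.contig_id, first - 20, first, "+")
            for i in range(10)
        ]
        pileup = build_pileup(reads, genome)
        res = call_tss(arr, pileup, genome)
        assert res.tss_position == first - 40
        assert res.tss_tied

    def test_no_leader_reads_flagged_undefined(self, rng):
        genome, *_ = _build_array_genome(rng)
        (arr,) = detect_arrays(genome)
        arr.strand = "+"
        pileup = build_pileup([], genome)
        res = call_tss(arr, pileup, genome)
        assert res.tss_position is None

    def test_boxa_planted_at_minus_27(self, rng):
        seq = random_seq(rng, 400)
        tss = 300
        seq = seq[: tss - 27] + "TTTAAA" + seq[tss - 21 :]
        genome = GenomeRecord("toy", seq)
        res = find_boxA(genome, tss, "+")
        assert (res.boxA_offset, res.boxA_mismatches) == (27, 0)
        assert res.boxA_sequence == "TTTAAA"

    def test_no_near_hexamer_reports_absent(self):
        genome = GenomeRecord("toy", "GC" * 200)
        res = find_boxA(genome, 300, "+")
        assert res.boxA_offset is None

    def test_tie_breaks_towards_canonical_spacing(self, rng):
        seq = list(random_seq(rng, 400))
        tss = 300
        # two perfect, non-overlapping hexamers inside the scan window
        seq[tss - 27 : tss - 21] = "TTTAAA"
        seq[tss - 20 : tss - 14] = "TTTAAA"
        genome = GenomeRecord("toy", "".join(seq))
        res = find_boxA(genome, tss, "+")
        assert res.boxA_offset == 27  # |27-26| < |20-26|
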