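"""Box motif scanning (vs. regex enumeration), C/D and H/ACA discovery,
circularity, context classification and guide-target prediction."""

import numpy as np
import pytest

from nanosmallrna.boxsrna import (
    CdParams,
    check_terminal_pairing,
    classify_context,
    detect_circular,
    find_haca,
    find_motif,
    predict_2ome_targets,
    predict_psi_targets,
    scan_cd,
)
from nanosmallrna.fold import can_pair, nussinov
from nanosmallrna.model import Feature, GenomeRecord, Read, revcomp
from nanosmallrna.synthetic import _make_cd_locus, make_haca_sequence

from .conftest import random_seq
from .oracles import brute_force_max_pairs, regex_motif_positions


class TestMotifScan:
    @pytest.mark.parametrize(
        "pattern,max_mm,exact",
        [
            ("CTGA", 0, ()),
            ("CTGA", 1, ()),
            ("RTGATGA", 1, (2, 3, 4)),
            ("RTGATGA", 2, (2, 3, 4)),
        ],
    )
    def test_equals_regex_enumeration_on_random_sequence(self, pattern, max_mm, exact):
        rng = np.random.default_rng(99)
        seq = random_seq(rng, 5000)
        assert find_motif(seq, pattern, max_mm, exact) == regex_motif_positions(
            seq, pattern, max_mm, exact
        )

    def test_box_c_variant_with_t_to_g_mutation_passes(self):
        # the naturally occurring intronic box C variant: T->G outside the core
        assert find_motif("AGGATGA", "RTGATGA", 1, (2, 3, 4)) == [(0, 1)]

    def test_core_mutations_always_rejected(self):
        for pos in (2, 3, 4):
            variant = list("ATGATGA")
            variant[pos] = "C"
            assert find_motif("".join(variant), "RTGATGA", 2, (2, 3, 4)) == []


class TestCdScan:
    def _plant(self, rng, permuted=False, strand="+", seed=3):
        cd = _make_cd_locus(np.random.default_rng(seed), permuted=permuted)
        locus = cd["locus"] if strand == "+" else revcomp(cd["locus"])
        left = random_seq(rng, 900)
        genome = GenomeRecord("toy", left + locus + random_seq(rng, 900))
        if strand == "+":
            iv = (900 + cd["interval"][0], 900 + cd["interval"][1])
        else:
            n = len(cd["locus"])
            iv = (900 + n - cd["interval"][1], 900 + n - cd["interval"][0])
        return genome, iv, cd

    def test_planted_canonical_detected_at_exact_interval(self, rng):
        genome, iv, _ = self._plant(rng)
        hits = [s for s in scan_cd(genome) if not s.shadowed]
        assert [(s.start, s.end, s.arrangement) for s in hits] == [
            (iv[0], iv[1], "canonical")
        ]

    def test_planted_minus_strand_detected(self, rng):
        genome, iv, _ = self._plant(rng, strand="-")
        hits = [s for s in scan_cd(genome) if not s.shadowed]
        assert [(s.start, s.end, s.strand) for s in hits] == [(iv[0], iv[1], "-")]

    def test_planted_permuted_reported_as_permuted(self, rng):
        genome, iv, _ = self._plant(rng, permuted=True)
        hits = [s for s in scan_cd(genome) if not s.shadowed]
        assert [(s.start, s.end, s.arrangement) for s in hits] == [
            (iv[0], iv[1], "permuted")
        ]
        # box D genomically upstream of box C
        assert hits[0].boxD.start < hits[0].boxC.start

    def test_guide_regions_have_legal_lengths(self, rng):
        genome, _, _ = self._plant(rng)
        (hit,) = [s for s in scan_cd(genome) if not s.shadowed]
        assert set(hit.guide_seqs) == {"D", "Dp"}
        for g in hit.guide_seqs.values():
            assert 10 <= len(g) <= 21

    def test_circular_genome_wrap_scan_finds_origin_spanning_locus(self, rng):
        cd = _make_cd_locus(np.random.default_rng(11))
        locus = cd["locus"]
        cut = len(locus) // 2
        seq = locus[cut:] + random_seq(rng, 3000) + locus[:cut]
        genome = GenomeRecord("toy", seq, is_circular=True)
        hits = [s for s in scan_cd(genome) if not s.shadowed and s.wraps_origin]
        assert len(hits) == 1
        assert hits[0].end > genome.length  # unwrapped coordinates


class TestTerminalPairing:
    def test_unpaired_ends_score_low(self):
        seq = "AAAAAA" + "G" * 40 + "AAAAAA"
        assert check_terminal_pairing(seq) == 0

    def test_designed_terminal_stem_counted(self):
        stem = "GGCGC"
        seq = stem + "A" + "T" * 30 + "A" + revcomp(stem)
        assert check_terminal_pairing(seq) >= 5

    def test_unpaired_classification_contract(self):
        srna = _make_cd_locus(np.random.default_rng(3))
        from nanosmallrna.boxsrna import CdBoxSrna  # count via the property

        n = check_terminal_pairing(srna["locus"])
        assert (n <= 1) == (n in (0, 1))


class TestCircularity:
    def _junction_reads(self, locus, n=50, rng=None):
        rng = rng or np.random.default_rng(0)
        reads = []
        for i in range(n):
            tail = int(rng.integers(14, 22))
            total = int(rng.integers(32, 42))
            reads.append(Read(f"j{i}", locus[-tail:] + locus[: total - tail]))
        return reads

    def test_simulated_circle_supported(self, rng):
        genome, iv, cd = TestCdScan()._plant(rng)
        (hit,) = [s for s in scan_cd(genome) if not s.shadowed]
        reads = self._junction_reads(hit.sequence)
        detect_circular(hit, reads)
        assert hit.circular
        assert hit.junction_read_support == 50
        assert hit.circle_length == len(hit.sequence)

    def test_linear_reads_give_zero_support(self, rng):
        genome, iv, cd = TestCdScan()._plant(rng)
        (hit,) = [s for s in scan_cd(genome) if not s.shadowed]
        linear = [Read(f"l{i}", hit.sequence[5:45]) for i in range(20)]
        detect_circular(hit, linear)
        assert hit.junction_read_support == 0 and not hit.circular

    def test_permuted_with_junctions_becomes_circular_permuted(self, rng):
        genome, iv, cd = TestCdScan()._plant(rng, permuted=True)
        (hit,) = [s for s in scan_cd(genome) if not s.shadowed]
        detect_circular(hit, self._junction_reads(hit.sequence))
        assert hit.arrangement == "circular_permuted"
        # the circular reading restores C before D
        rot = hit.sequence[hit.boxC.start - hit.start :] + hit.sequence[: hit.boxC.start - hit.start]
        c_local = rot.find(hit.boxC.sequence)
        d_local = rot.find(hit.boxD.sequence, c_local)
        assert 0 <= c_local < d_local

    def test_support_below_threshold_not_circular(self, rng):
        genome, iv, cd = TestCdScan()._plant(rng)
        (hit,) = [s for s in scan_cd(genome) if not s.shadowed]
        detect_circular(hit, self._junction_reads(hit.sequence, n=3))
        assert hit.junction_read_support == 3 and not hit.circular


class TestContext:
    def _srna(self, start, end, strand="+"):
        from nanosmallrna.boxsrna import BoxHit, CdBoxSrna

        box = BoxHit(start, start + 4, "CTGA", 0)
        return CdBoxSrna(
            "s", "toy", start, end, strand, box, box, None, None, "canonical"
        )

    def test_dicistronic_immediately_downstream_of_trna(self):
        feats = [Feature("trna", "toy", 1000, 1072, "+", "tRNA")]
        assert classify_context(self._srna(1074, 1130), feats) == "tRNA_dicistronic"

    def test_split_gene_flank_within_100nt(self):
        feats = [
            Feature("gyr", "toy", 2000, 2500, "+", "gene", {"split_part": "N_terminal"})
        ]
        assert classify_context(self._srna(1850, 1910), feats) == "split_gene_flank"

    def test_intronic_beats_other_contexts(self):
        feats = [
            Feature("met", "toy", 100, 240, "+", "tRNA"),
            Feature("intron", "toy", 130, 196, "+", "tRNA_intron"),
        ]
        assert classify_context(self._srna(140, 190), feats) == "tRNA_intronic"

    def test_overlap_with_gene_is_mrna_overlap(self):
        feats = [Feature("g", "toy", 100, 700, "-", "gene")]
        assert classify_context(self._srna(300, 360), feats) == "mRNA_overlap"

    def test_isolated_is_standalone(self):
        assert classify_context(self._srna(5000, 5060), []) == "standalone"


class TestOmeTargets:
    def _hit_with_guide(self, guide):
        from nanosmallrna.boxsrna import BoxHit, CdBoxSrna

        box = BoxHit(0, 4, "CTGA", 0)
        s = CdBoxSrna("s", "toy", 0, 60, "+", box, box, None, None, "canonical")
        s.guide_seqs["D"] = guide
        return s

    def test_perfect_antisense_guide_targets_d_plus_five_base(self, rng):
        r = random_seq(rng, 300)
        rrna = GenomeRecord("rrna", r)
        guide = revcomp(r[100:115])  # 15-nt guide, ends adjacent to box D
        preds = predict_2ome_targets(self._hit_with_guide(guide), [rrna])
        assert preds
        # hand-computed: g[-5] pairs r[100 + 4]
        assert preds[0].target_position == 104
        assert preds[0].duplex_len == 15

    def test_d_plus_five_rule_holds_for_every_prediction(self, rng):
        r = random_seq(rng, 400)
        rrna = GenomeRecord("rrna", r)
        guide = revcomp(r[50:64])
        for p in predict_2ome_targets(self._hit_with_guide(guide), [rrna]):
            g = guide
            anchor = len(g) - 5
            # the reported base must pair the D+5 guide nucleotide
            t = p.target_position
            assert can_pair(g[anchor], r[t])

    def test_short_duplex_yields_nothing(self, rng):
        rrna = GenomeRecord("rrna", random_seq(rng, 200))
        guide = "ACGTACGTACGTACG"
        rng2 = np.random.default_rng(17)
        # overwhelmingly unlikely to find 10 contiguous pairs by chance in 200 nt
        preds = predict_2ome_targets(self._hit_with_guide(guide), [rrna], min_duplex=14)
        assert preds == []

    def test_reverse_complement_symmetry(self, rng):
        """A locus on the minus strand predicts the identical target set."""
        cd = _make_cd_locus(np.random.default_rng(21))
        left, right = random_seq(rng, 500), random_seq(rng, 500)
        fwd = GenomeRecord("toy", left + cd["locus"] + right)
        rev = GenomeRecord("toy", revcomp(left + cd["locus"] + right))
        rrna = GenomeRecord("rrna", random_seq(rng, 400))
        (hit_f,) = [s for s in scan_cd(fwd) if not s.shadowed]
        (hit_r,) = [s for s in scan_cd(rev) if not s.shadowed]
        assert hit_f.sequence == hit_r.sequence
        pf = predict_2ome_targets(hit_f, [rrna], min_duplex=6)
        pr = predict_2ome_targets(hit_r, [rrna], min_duplex=6)
        assert [
            (p.guide_source, p.target_rna, p.target_position, p.duplex_len)
            for p in pf
        ] == [
            (p.guide_source, p.target_rna, p.target_position, p.duplex_len)
            for p in pr
        ]


class TestFolder:
    def test_equals_bruteforce_pair_maximisation_up_to_40nt(self):
        rng = np.random.default_rng(13)
        for length in (10, 18, 25, 33, 40):
            for _ in range(4):
                seq = random_seq(rng, length)
                assert len(nussinov(seq)) == brute_force_max_pairs(seq)

    def test_hairpin_sequence_folds_into_single_stem(self):
        stem = "GGCGCGC"
        seq = stem + "AAAA" + revcomp(stem)
        pairs = nussinov(seq)
        assert (0, len(seq) - 1) in pairs
        assert len(pairs) == len(stem)


class TestHaca:
    def test_designed_two_hairpin_molecule_detected(self):
        seq = make_haca_sequence()
        genome = GenomeRecord("toy", seq)
        (h,) = find_haca([(0, len(seq), "+")], genome)
        assert len(h.hairpins) == 2
        assert h.h_domain_status == "ACA_only"
        assert h.hinge_aca is not None
        assert h.kturn_flags == [True, True]
        assert all(p is not None for p in h.pockets)

    def test_single_hairpin_rejected(self):
        stem = "GGCGCGCGG"
        seq = "AAA" + stem + "AAAA" + revcomp(stem) + "ACA"
        genome = GenomeRecord("toy", seq)
        assert find_haca([(0, len(seq), "+")], genome) == []

    def test_missing_aca_rejected(self):
        seq = make_haca_sequence().replace("ACA", "AAA")
        genome = GenomeRecord("toy", seq)
        assert find_haca([(0, len(seq), "+")], genome) == []

    def test_psi_target_at_planted_u(self, rng):
        seq = make_haca_sequence()
        genome = GenomeRecord("toy", seq)
        (h,) = find_haca([(0, len(seq), "+")], genome)
        r = random_seq(rng, 300)
        r = r[:195] + "TTTTT" + "T" + r[201] + "TTTTT" + r[207:]
        preds = predict_psi_targets(h, [GenomeRecord("rrna", r)])
        assert {p.target_position for p in preds} == {200}
        assert {p.guide_source for p in preds} == {"pocket1", "pocket2"}

    def test_empty_rrna_set_gives_no_predictions(self):
        seq = make_haca_sequence()
        genome = GenomeRecord("toy", seq)
        (h,) = find_haca([(0, len(seq), "+")], genome)
        assert predict_psi_targets(h, []) == []
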