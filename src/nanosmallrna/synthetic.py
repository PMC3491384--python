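"""Synthetic genome and small-RNA-seq scenario generator with ground truth.

The generator emulates the architecture of a minimal archaeal genome: two
CRISPR arrays sharing an identical leader (TSS on an adenosine 33 nt
upstream of the first repeat, TTTAAA box A at -27, repeats ending in the
ATTGAAAG tag), trans-spliced tRNA-half genes with GC-rich
reverse-complementary clamps and T-stretch terminators, leaderless tRNA
genes (including a G-1 extended tyrosine tRNA and an intron-bearing
elongator methionine tRNA whose 66-nt intron carries a C/D box sRNA),
canonical / permuted / dicistronic / intronic C/D box sRNAs, one
two-hairpin H/ACA sRNA, and an rRNA with planted methylation and
pseudouridylation target sites.

Read simulation reflects the processing model: endonucleolytic crRNA
cleavage leaving a fixed 5' repeat tag, geometric 3' exonucleolytic
trimming, abundance decay along the array, leaderless tRNA starts,
reverse-transcriptase drop-off on structured tRNAs (depressing their read
counts), and junction-spanning reads from circular sRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .model import Feature, GenomeRecord, Read, revcomp

BASES = "ACGT"


@dataclass
class Scenario:
    seed: int = 42
    genome_length: int = 50_000
    n_arrays: int = 2
    repeat_seq: str | None = None  # random 20-mer + tag when None
    tag: str = "ATTGAAAG"
    spacers_per_array: tuple[int, ...] = (21, 20)
    leader_identity_len: int = 130
    tss_offset: int = 33
    boxA_offset: int = 27
    tag_len: int = 8
    trim_geometric_p: float = 0.25
    abundance_decay: float = 0.8
    n_trna_pairs: int = 6
    clamp_len: int = 12
    n_cd: dict[str, int] = field(
        default_factory=lambda: {
            "standalone": 2,
            "mRNA_overlap": 1,
            "tRNA_dicistronic": 1,
            "split_gene_flank": 2,  # one canonical + one permuted/circular
        }
    )
    haca: bool = True
    read_depth: float = 100.0
    cd_depth_multiplier: float = 10.0
    leader_reads: int = 50
    junction_reads: int = 50
    error_rate: float = 0.001
    rt_dropoff: float = 0.02
    n_plain_trnas: int = 3
    n_genes: int = 5

    def __post_init__(self) -> None:
        for p in (self.trim_geometric_p, self.abundance_decay, self.error_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0,1]")
        if self.repeat_seq is not None and not self.repeat_seq.endswith(self.tag):
            raise ValueError("repeat_seq must end with the configured tag")


@dataclass
class SyntheticTruth:
    arrays: list[dict] = field(default_factory=list)
    trna_pairs: list[dict] = field(default_factory=list)
    trna_genes: list[dict] = field(default_factory=list)
    cd_srnas: list[dict] = field(default_factory=list)
    haca: dict | None = None
    rrna: dict | None = None
    expected_counts: dict[str, float] = field(default_factory=dict)
    realized_counts: dict[str, int] = field(default_factory=dict)
    scenario: Scenario | None = None


class ScenarioError(RuntimeError):
    pass


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _rand_gc_rich(rng: np.random.Generator, n: int) -> str:
    """GC-rich sequence (~80% G/C); the A/T admixture keeps independently
    drawn clamps from sharing long complementary runs by chance."""
    return "".join(rng.choice(list("GCAT"), size=n, p=[0.4, 0.4, 0.1, 0.1]))


def _max_duplex_run(a: str, b: str) -> int:
    """Longest contiguous antiparallel WC/GU run between two sequences."""
    pairable = {
        ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
    }
    other = b[::-1]
    best = 0
    for shift in range(-(len(other) - 1), len(a)):
        run = 0
        for i in range(max(0, shift), min(len(a), shift + len(other))):
            if (a[i], other[i - shift]) in pairable:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


class _Builder:
    """Sequential genome assembly with random padding between cassettes."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.parts: list[str] = []
        self.cursor = 0

    def pad(self, lo: int = 250, hi: int = 600) -> None:
        n = int(self.rng.integers(lo, hi))
        self.parts.append(_rand_seq(self.rng, n))
        self.cursor += n

    def place(self, seq: str) -> int:
        start = self.cursor
        self.parts.append(seq)
        self.cursor += len(seq)
        return start

    def sequence(self) -> str:
        return "".join(self.parts)


# ---------------------------------------------------------------------------
# C/D box sRNA cassette construction

_BOXC = "ATGATGA"
_BOXD = "CTGA"
_BOXDP = "CTGG"  # internal D' carries one mismatch, as real sRNAs commonly do
_GUIDE_LEN = 15
_CD_FLANK5 = 4
_CD_FLANK3 = 2


def _clean_guide(rng: np.random.Generator, n: int, seq: str | None = None) -> str:
    """A guide segment free of box-D-like (<=1 mm) and box-C-like 7-mers."""
    from .boxsrna import find_motif

    for _ in range(1000):
        g = seq if seq is not None else _rand_seq(rng, n)
        if (
            not find_motif(g, "CTGA", 1)
            and not find_motif(g, "RTGATGA", 2, (2, 3, 4))
            and "TTTTT" not in g
        ):
            return g
        if seq is not None:
            raise ScenarioError("requested guide sequence fails sanitisation")
    raise ScenarioError("could not sanitise a guide segment in 1000 attempts")


def _make_cd_core(
    rng: np.random.Generator, guide2: str | None = None
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Canonical C/D core: boxC - guide1 - boxD' - boxC' - guide2 - boxD.

    The degenerate D' (one mismatch) keeps the canonical and permuted
    readings distinguishable: only the true box D matches the exact outer
    pattern.  Construction is rejection-sampled until the candidate
    enumeration reports exactly the planted geometry and nothing else.
    """
    from .boxsrna import CdParams, _canonical_candidates

    params = CdParams()
    for _ in range(1000):
        g1 = _clean_guide(rng, _GUIDE_LEN)
        g2 = _clean_guide(rng, _GUIDE_LEN, guide2)
        core = _BOXC + g1 + _BOXDP + _BOXC + g2 + _BOXD
        coords = {
            "C": (0, 7),
            "Dp": (7 + len(g1), 11 + len(g1)),
            "Cp": (11 + len(g1), 18 + len(g1)),
            "D": (len(core) - 4, len(core)),
        }
        cands = _canonical_candidates(core, params, True)
        if len(cands) == 1 and (
            cands[0]["c"][0] == 0
            and cands[0]["d"][0] == coords["D"][0]
            and cands[0]["dp"][0] == coords["Dp"][0]
            and cands[0]["cp"][0] == coords["Cp"][0]
        ):
            return core, coords
    raise ScenarioError("could not build a clean C/D core in 1000 attempts")


def _make_cd_locus(
    rng: np.random.Generator, permuted: bool = False, guide2: str | None = None
) -> dict[str, Any]:
    """A planted C/D locus: core plus short flanks; optionally permuted.

    The permuted locus is the circular rotation of the canonical molecule
    cut between box D' and box C' so the genomic order becomes
    C' - guide2 - D - flanks - C - guide1 - D'; the truth interval spans
    box C' through box D'.
    """
    from .boxsrna import CdParams, _canonical_candidates, _permuted_candidates

    params = CdParams()
    for _ in range(100):
        core, coords = _make_cd_core(rng, guide2)
        f5 = _clean_guide(rng, _CD_FLANK5)
        f3 = _clean_guide(rng, _CD_FLANK3)
        if not permuted:
            locus = f5 + core + f3
            cands = _canonical_candidates(locus, params, True)
            if len(cands) != 1 or cands[0]["start"] != len(f5):
                continue
            return {
                "locus": locus,
                "interval": (len(f5), len(f5) + len(core)),
                "arrangement": "canonical",
                "core": core,
                "transcript": (len(f5), len(f5) + len(core)),
            }
        cut = coords["Cp"][0]
        rotated = core[cut:] + f3 + f5 + core[:cut]
        # genomic order: C' g2 D | f3 f5 | C g1 D'
        perms = _permuted_candidates(rotated, params)
        if (
            len(perms) == 1
            and perms[0]["start"] == 0
            and perms[0]["end"] == len(rotated)
            and not _canonical_candidates(rotated, params, True)
        ):
            return {
                "locus": rotated,
                "interval": (0, len(rotated)),
                "arrangement": "permuted",
                "core": core,
                "transcript": (0, len(rotated)),
            }
    raise ScenarioError("could not build an unambiguous C/D locus")


# ---------------------------------------------------------------------------
# H/ACA cassette (fixed design; stems verified by the fold-based caller)

# The molecule is T-free with pure-A pockets, loops and spacers, so the only
# possible pairs are the designed G-C stems.  The two hairpins carry opposite
# arm polarity (hairpin 1: G-rich 5' arms; hairpin 2: C-rich 5' arms), which
# makes cross-hairpin stem pairing impossible (G-G / C-C); every remaining
# alternative pairing either crosses designed stem pairs (losing more than it
# gains) or ties, and ties resolve to the stacked designed helices.
_H1 = {
    "lower": "GGCGCG", "upper": "GCGGC", "apex": "GGCG",
    "pocket_l": "AAAAA", "pocket_r": "AAAAA", "loop": "AAAA",
}
_H2 = {
    "lower": "CCGCCG", "upper": "CCGCC", "apex": "CCGC",
    "pocket_l": "AAAAA", "pocket_r": "AAAAA", "loop": "AAAA",
}


def _haca_hairpin(d: dict[str, str]) -> str:
    return (
        d["lower"] + "GA" + d["upper"] + d["pocket_l"] + d["apex"] + d["loop"]
        + revcomp(d["apex"]) + d["pocket_r"] + revcomp(d["upper"]) + "AG"
        + revcomp(d["lower"])
    )


def make_haca_sequence() -> str:
    """The planted two-hairpin H/ACA sRNA: hinge ACA, terminal ACA, k-turns."""
    return "AAA" + _haca_hairpin(_H1) + "ACA" + _haca_hairpin(_H2) + "ACAAAA"


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(
    scenario: Scenario,
) -> tuple[GenomeRecord, list[Feature], SyntheticTruth]:
    """Build the toy genome, its annotation and the planted truth."""
    rng = np.random.default_rng(scenario.seed)
    b = _Builder(rng)
    truth = SyntheticTruth(scenario=scenario)
    features: list[Feature] = []
    b.pad(400, 700)

    # --- CRISPR arrays -----------------------------------------------------
    repeat = scenario.repeat_seq or (_rand_seq(rng, 20) + scenario.tag)
    shared = _shared_leader(rng, scenario)
    spacer_pool = _distinct_spacers(rng, scenario, repeat)
    pool_iter = iter(spacer_pool)
    for a_idx in range(scenario.n_arrays):
        n_spacers = scenario.spacers_per_array[a_idx]
        private = _rand_seq(rng, 70)
        # force divergence immediately upstream of the shared leader stretch
        if a_idx > 0:
            prev_private = truth.arrays[0]["private_leader"]
            if private[-1] == prev_private[-1]:
                alt = [x for x in BASES if x != prev_private[-1]]
                private = private[:-1] + alt[int(rng.integers(len(alt)))]
        b.pad()
        leader_start = b.place(private + shared)
        first_repeat = b.cursor
        repeats = []
        spacers = []
        for s_idx in range(n_spacers):
            repeats.append((b.place(repeat), b.cursor))
            spacer = next(pool_iter)
            spacers.append((b.place(spacer), b.cursor))
        repeats.append((b.place(repeat), b.cursor))
        tss = first_repeat - scenario.tss_offset
        boxa_start = tss - scenario.boxA_offset
        truth.arrays.append(
            {
                "array_id": f"true_array_{a_idx + 1}",
                "strand": "+",
                "repeats": repeats,
                "spacers": spacers,
                "repeat_seq": repeat,
                "leader_interval": (leader_start, first_repeat),
                "private_leader": private,
                "tss": tss,
                "tss_base": "A",
                "boxA": (boxa_start, boxa_start + 6),
                "tag_len": scenario.tag_len,
                "tag_seq": repeat[-scenario.tag_len :],
            }
        )
        features.append(
            Feature(
                f"true_array_{a_idx + 1}",
                "synthetic",
                repeats[0][0],
                repeats[-1][1],
                "+",
                "CRISPR_array",
            )
        )

    # --- tRNA half pairs ---------------------------------------------------
    clamps = _distinct_clamps(rng, scenario)
    ext_plan = ["GC", "A", "-A"] + [""] * max(0, scenario.n_trna_pairs - 3)
    for p_idx in range(scenario.n_trna_pairs):
        strand = "-" if p_idx == scenario.n_trna_pairs - 1 else "+"
        clamp5 = clamps[p_idx]
        clamp3 = revcomp(clamp5)
        body5 = "G" + _clean_guide(rng, 34)
        body3 = _clean_guide(rng, 39) + "A"
        ext = ext_plan[p_idx]
        shortened = ext.startswith("-")
        ext_seq = "" if shortened else ext

        b.pad()
        # 5' half cassette: body + clamp + T-stretch terminator
        cas5 = body5 + clamp5 + "TTTTT"
        start5 = _place_cassette(b, cas5, strand)
        body5_iv = _sense_to_genomic(start5, len(cas5), (0, len(body5)), strand)
        f5 = Feature(
            f"trna_half_{p_idx + 1}_5p",
            "synthetic",
            *body5_iv,
            strand,
            "tRNA_half",
            {"half_side": "five_prime", "clamp_len": str(len(clamp5))},
        )
        b.pad(120, 250)
        # 3' half cassette: T-stretch (upstream terminator of the neighbour),
        # spacer, optional templated extension, clamp, body
        gap = _clean_guide(rng, 6)
        cas3 = "TTTTT" + gap + ext_seq + clamp3 + body3
        start3 = _place_cassette(b, cas3, strand)
        body3_lo = len(cas3) - len(body3)
        body3_iv = _sense_to_genomic(start3, len(cas3), (body3_lo, len(cas3)), strand)
        f3 = Feature(
            f"trna_half_{p_idx + 1}_3p",
            "synthetic",
            *body3_iv,
            strand,
            "tRNA_half",
            {"half_side": "three_prime", "clamp_len": str(len(clamp3))},
        )
        features.extend([f5, f3])
        clamp3_local = (body3_lo - len(clamp3), body3_lo)
        clamp3_iv = _sense_to_genomic(start3, len(cas3), clamp3_local, strand)
        clamp5_local = (len(body5), len(body5) + len(clamp5))
        clamp5_iv = _sense_to_genomic(start5, len(cas5), clamp5_local, strand)
        offset = -1 if shortened else len(ext_seq)
        truth.trna_pairs.append(
            {
                "pair_id": f"trna_pair_{p_idx + 1}",
                "five_id": f5.feature_id,
                "three_id": f3.feature_id,
                "strand": strand,
                "clamp5": clamp5,
                "clamp3": clamp3,
                "mature_seq": body5 + body3,
                "clamp5_iv": clamp5_iv,
                "clamp3_iv": clamp3_iv,
                "three_ext_offset": offset,
                "body5_iv": body5_iv,
                "body3_iv": body3_iv,
            }
        )

    # --- plain tRNA genes, tRNA-Tyr (G-1), tRNA-Met (66-nt intron) --------
    for t_idx in range(scenario.n_plain_trnas):
        b.pad()
        body = "G" + _clean_guide(rng, 71)
        start = b.place(body + "TTTTT")
        features.append(
            Feature(f"trna_plain_{t_idx + 1}", "synthetic", start, start + 72, "+", "tRNA")
        )
        truth.trna_genes.append(
            {"gene_id": f"trna_plain_{t_idx + 1}", "start": start, "end": start + 72,
             "strand": "+", "minus1_fraction": 0.0, "start_base": "G"}
        )
    b.pad()
    tyr_body = "C" + _clean_guide(rng, 71)
    start = b.place("G" + tyr_body + "TTTTT") + 1  # templated G at -1
    features.append(Feature("trna_tyr", "synthetic", start, start + 72, "+", "tRNA"))
    truth.trna_genes.append(
        {"gene_id": "trna_tyr", "start": start, "end": start + 72, "strand": "+",
         "minus1_fraction": 0.9, "start_base": "C", "minus1_base": "G"}
    )

    b.pad()
    intron, intron_cd_local = _met_intron(rng)
    exon1 = "A" + _clean_guide(rng, 29)
    exon2 = _clean_guide(rng, 30)
    met_start = b.place(exon1 + intron + exon2 + "TTTTT")
    intron_start = met_start + len(exon1)
    features.append(
        Feature("trna_met", "synthetic", met_start, met_start + 60 + len(intron), "+", "tRNA")
    )
    features.append(
        Feature(
            "trna_met_intron", "synthetic", intron_start,
            intron_start + len(intron), "+", "tRNA_intron",
        )
    )
    truth.trna_genes.append(
        {"gene_id": "trna_met", "start": met_start,
         "end": met_start + 60 + len(intron), "strand": "+",
         "minus1_fraction": 0.0, "start_base": "A"}
    )
    truth.cd_srnas.append(
        {
            "srna_id": "true_cd_intronic",
            "start": intron_start + intron_cd_local[0],
            "end": intron_start + intron_cd_local[1],
            "strand": "+",
            "arrangement": "canonical",
            "context": "tRNA_intronic",
            "circular": False,
            "transcript": (intron_start, intron_start + len(intron)),
        }
    )

    # --- rRNA with planted target sites ------------------------------------
    b.pad()
    rrna_seq = _rand_seq(rng, 300)
    # pseudouridylation site at u = 200 matched to the H/ACA pocket design
    # (pure-A pockets pair runs of T flanking the unpaired UN dinucleotide)
    rrna_seq = (
        rrna_seq[:195] + "TTTTT" + "T" + rrna_seq[201] + "TTTTT" + rrna_seq[207:]
    )
    ome_guide = None
    for shift in range(0, 100, 5):
        segment = rrna_seq[100 + shift : 115 + shift]
        candidate = revcomp(segment)
        try:
            _make_cd_core(np.random.default_rng(int(rng.integers(2**31))), candidate)
        except ScenarioError:
            continue
        ome_guide = candidate
        # D+5 rule: guide base g[-5] pairs target position a+4 for a perfect
        # antiparallel duplex over r[a:a+15]
        ome_target = 100 + shift + 4
        break
    if ome_guide is None:
        raise ScenarioError("no clean antisense guide segment found in the rRNA")
    rrna_start = b.place(rrna_seq)
    features.append(
        Feature("rrna_16s", "synthetic", rrna_start, rrna_start + 300, "+", "rRNA")
    )
    truth.rrna = {
        "rrna_id": "rrna_16s",
        "sequence": rrna_seq,
        "ome_target": ome_target,
        "psi_target": 200,
    }

    # --- protein genes, incl. a split gene pair ----------------------------
    gene_ivs = []
    for g_idx in range(scenario.n_genes):
        b.pad()
        length = int(rng.integers(400, 800))
        start = b.place(_rand_seq(rng, length))
        strand = "+" if g_idx % 2 == 0 else "-"
        features.append(
            Feature(f"gene_{g_idx + 1}", "synthetic", start, start + length, strand, "gene")
        )
        gene_ivs.append((start, start + length, strand))
    b.pad()
    split_n_len = int(rng.integers(400, 600))
    # permuted sRNA upstream, canonical sRNA downstream flank the N-terminal part
    perm = _make_cd_locus(rng, permuted=True)
    b.pad()
    perm_start = b.place(perm["locus"])
    gap1 = b.place(_rand_seq(rng, int(rng.integers(20, 80))))
    split_n_start = b.place(_rand_seq(rng, split_n_len))
    gap2 = b.place(_rand_seq(rng, int(rng.integers(20, 80))))
    flank_cd = _make_cd_locus(rng)
    flank_start = b.place(flank_cd["locus"])
    features.append(
        Feature(
            "gene_split_N", "synthetic", split_n_start, split_n_start + split_n_len,
            "+", "gene", {"split_part": "N_terminal"},
        )
    )
    b.pad()
    split_c_len = int(rng.integers(400, 600))
    split_c_start = b.place(_rand_seq(rng, split_c_len))
    features.append(
        Feature(
            "gene_split_C", "synthetic", split_c_start, split_c_start + split_c_len,
            "-", "gene", {"split_part": "C_terminal"},
        )
    )
    truth.cd_srnas.append(
        {
            "srna_id": "true_cd_permuted",
            "start": perm_start + perm["interval"][0],
            "end": perm_start + perm["interval"][1],
            "strand": "+",
            "arrangement": "permuted",
            "context": "split_gene_flank",
            "circular": True,
            "transcript": (
                perm_start + perm["transcript"][0],
                perm_start + perm["transcript"][1],
            ),
        }
    )
    truth.cd_srnas.append(
        {
            "srna_id": "true_cd_split_flank",
            "start": flank_start + flank_cd["interval"][0],
            "end": flank_start + flank_cd["interval"][1],
            "strand": "+",
            "arrangement": "canonical",
            "context": "split_gene_flank",
            "circular": False,
            "transcript": (
                flank_start + flank_cd["transcript"][0],
                flank_start + flank_cd["transcript"][1],
            ),
        }
    )

    # --- remaining C/D sRNAs by context ------------------------------------
    for c_idx in range(scenario.n_cd.get("standalone", 0)):
        strand = "-" if c_idx == 1 else "+"
        guide2 = ome_guide if c_idx == 0 else None
        cd = _make_cd_locus(rng, guide2=guide2)
        b.pad()
        start = _place_cassette(b, cd["locus"], strand)
        iv = _sense_to_genomic(start, len(cd["locus"]), cd["interval"], strand)
        tx = _sense_to_genomic(start, len(cd["locus"]), cd["transcript"], strand)
        truth.cd_srnas.append(
            {
                "srna_id": f"true_cd_standalone_{c_idx + 1}",
                "start": iv[0],
                "end": iv[1],
                "strand": strand,
                "arrangement": "canonical",
                "context": "standalone",
                "circular": c_idx == 1,  # one linear-circular sRNA (sRNA23-like)
                "transcript": tx,
                "ome_guide": guide2,
            }
        )
    if scenario.n_cd.get("mRNA_overlap", 0):
        cd = _make_cd_locus(rng)
        b.pad()
        host_len = int(rng.integers(400, 600))
        host_start = b.place(_rand_seq(rng, 150))
        cd_start = b.place(cd["locus"])
        b.place(_rand_seq(rng, host_len - 150 - len(cd["locus"])))
        features.append(
            Feature(
                "gene_host", "synthetic", host_start, host_start + host_len, "+", "gene"
            )
        )
        iv = (cd_start + cd["interval"][0], cd_start + cd["interval"][1])
        truth.cd_srnas.append(
            {
                "srna_id": "true_cd_mrna_overlap",
                "start": iv[0],
                "end": iv[1],
                "strand": "+",
                "arrangement": "canonical",
                "context": "mRNA_overlap",
                "circular": False,
                "transcript": (
                    cd_start + cd["transcript"][0], cd_start + cd["transcript"][1]
                ),
            }
        )
    if scenario.n_cd.get("tRNA_dicistronic", 0):
        b.pad()
        val_body = "G" + _clean_guide(rng, 71)
        val_start = b.place(val_body)
        features.append(
            Feature("trna_val", "synthetic", val_start, val_start + 72, "+", "tRNA")
        )
        truth.trna_genes.append(
            {"gene_id": "trna_val", "start": val_start, "end": val_start + 72,
             "strand": "+", "minus1_fraction": 0.0, "start_base": "G"}
        )
        # RNase Z cleavage at the tRNA 3' end directly releases the sRNA 5'
        # leader, so the locus abuts the tRNA gene
        cd = _make_cd_locus(rng)
        cd_start = b.place(cd["locus"])
        b.place("TTTTT")
        iv = (cd_start + cd["interval"][0], cd_start + cd["interval"][1])
        truth.cd_srnas.append(
            {
                "srna_id": "true_cd_dicistronic",
                "start": iv[0],
                "end": iv[1],
                "strand": "+",
                "arrangement": "canonical",
                "context": "tRNA_dicistronic",
                "circular": False,
                "transcript": (
                    cd_start + cd["transcript"][0], cd_start + cd["transcript"][1]
                ),
            }
        )

    # --- H/ACA sRNA ---------------------------------------------------------
    if scenario.haca:
        b.pad()
        haca_seq = make_haca_sequence()
        start = b.place(haca_seq)
        b.place("TTTTT")
        truth.haca = {
            "srna_id": "true_haca",
            "start": start,
            "end": start + len(haca_seq),
            "strand": "+",
            "sequence": haca_seq,
        }

    # --- final padding -----------------------------------------------------
    if b.cursor > scenario.genome_length:
        raise ScenarioError(
            f"planted features need {b.cursor} nt > genome_length "
            f"{scenario.genome_length}"
        )
    b.place(_rand_seq(rng, scenario.genome_length - b.cursor))
    genome = GenomeRecord("synthetic", b.sequence(), is_circular=False)
    for f in features:
        if f.end > genome.length:
            raise ScenarioError("feature outside genome bounds")
    features.sort(key=lambda f: (f.start, f.end))
    return genome, features, truth


def _place_cassette(b: _Builder, sense_seq: str, strand: str) -> int:
    return b.place(revcomp(sense_seq) if strand == "-" else sense_seq)


def _sense_to_genomic(
    start: int, cassette_len: int, local: tuple[int, int], strand: str
) -> tuple[int, int]:
    if strand == "+":
        return start + local[0], start + local[1]
    return start + cassette_len - local[1], start + cassette_len - local[0]


def _shared_leader(rng: np.random.Generator, sc: Scenario) -> str:
    """The leader stretch identical between arrays, with TSS 'A' and box A."""
    n = sc.leader_identity_len
    tss_idx = n - sc.tss_offset
    boxa_idx = tss_idx - sc.boxA_offset
    if boxa_idx < 0:
        raise ScenarioError("leader too short for the box A placement")
    for _ in range(1000):
        s = list(_rand_seq(rng, n))
        s[tss_idx] = "A"
        s[boxa_idx : boxa_idx + 6] = "TTTAAA"
        seq = "".join(s)
        # no competing near-perfect box A hexamer in the promoter scan window
        ok = True
        for off in range(20, 36):
            if off == sc.boxA_offset:
                continue
            cand_start = tss_idx - off
            if cand_start < 0:
                continue
            cand = seq[cand_start : cand_start + 6]
            mm = sum(1 for a, bch in zip(cand, "TTTAAA") if a != bch)
            if mm <= 1:
                ok = False
                break
        if ok and "TTTTT" not in seq:
            return seq
    raise ScenarioError("could not sanitise the shared leader in 1000 attempts")


def _distinct_spacers(
    rng: np.random.Generator, sc: Scenario, repeat: str
) -> list[str]:
    total = sum(sc.spacers_per_array[: sc.n_arrays])
    spacers: list[str] = []
    seen: set[str] = set()
    long_idx = 3  # one considerably longer spacer, as real arrays show
    attempts = 0
    while len(spacers) < total:
        attempts += 1
        if attempts > 10_000:
            raise ScenarioError("could not draw distinct spacers")
        n = 60 if len(spacers) == long_idx else int(rng.integers(35, 45))
        s = _rand_seq(rng, n)
        if s in seen or repeat[:12] in s or "TTTTT" in s:
            continue
        seen.add(s)
        spacers.append(s)
    return spacers


def _distinct_clamps(rng: np.random.Generator, sc: Scenario) -> list[str]:
    """GC-rich clamps whose cross-pair duplex runs stay short (< 6)."""
    clamps: list[str] = []
    attempts = 0
    while len(clamps) < sc.n_trna_pairs:
        attempts += 1
        if attempts > 5000:
            raise ScenarioError("could not draw mutually distinct clamps")
        c = _rand_gc_rich(rng, sc.clamp_len)
        if "TTTTT" in c:
            continue
        ok = True
        for prev in clamps:
            if (
                _max_duplex_run(c, revcomp(prev)) >= 6
                or _max_duplex_run(prev, revcomp(c)) >= 6
            ):
                ok = False
                break
        if ok and _max_duplex_run(c, c) < 6:
            clamps.append(c)
    return clamps


def _met_intron(rng: np.random.Generator) -> tuple[str, tuple[int, int]]:
    """A 66-nt tRNA intron carrying a C/D sRNA with a mutated box C.

    The box C carries a single T-to-G substitution outside the central GAU
    core (the budget the scanner's box C pattern must admit) and the
    internal region contains a stable hairpin of six consecutive GC pairs.
    """
    boxc_mut = "AGGATGA"  # RTGATGA with T2G
    stem = "GGCGCC"
    hairpin = stem + "GAAA" + revcomp(stem)
    filler = _clean_guide(rng, 40 - len(hairpin) - 4)
    internal = _clean_guide(rng, 2) + hairpin + filler + _clean_guide(rng, 2)
    internal = internal[:40]
    core = boxc_mut + internal + _BOXD
    pad5 = _clean_guide(rng, 8)
    pad3 = _clean_guide(rng, 66 - len(core) - 8)
    intron = pad5 + core + pad3
    assert len(intron) == 66
    return intron, (len(pad5), len(pad5) + len(core))


# ---------------------------------------------------------------------------
# read simulation


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    s = list(seq)
    for pos in rng.integers(0, len(seq), n_err):
        alt = [x for x in BASES if x != s[pos]]
        s[pos] = alt[int(rng.integers(3))]
    return "".join(s)


def simulate_reads(
    genome: GenomeRecord,
    truth: SyntheticTruth,
    scenario: Scenario | None = None,
    seed_offset: int = 1,
) -> list[Read]:
    """Draw a processed small-RNA-seq library from the planted truth.

    Per-transcript read counts are Poisson around the class abundance model;
    crRNA reads carry the repeat-derived 5' tag and geometric 3' trimming;
    tRNA-class transcripts are depressed by RT drop-off on structured RNA;
    circular sRNAs additionally emit junction-spanning reads.
    """
    sc = scenario or truth.scenario
    if sc is None:
        raise ValueError("scenario required")
    rng = np.random.default_rng(sc.seed + seed_offset)
    reads: list[Read] = []
    expected = truth.expected_counts
    realized = truth.realized_counts

    def emit(name: str, start: int, end: int, strand: str) -> None:
        if start < 0 or end > genome.length or end <= start:
            return
        seq = genome.sequence[start:end]
        if strand == "-":
            seq = revcomp(seq)
        seq = _mutate(rng, seq, sc.error_rate)
        reads.append(Read(f"{name}_{len(reads)}", seq, [30] * len(seq)))

    # crRNAs: 5' tag + spacer + geometrically trimmed 3' repeat tail
    for arr in truth.arrays:
        rep_len = len(arr["repeat_seq"])
        tail = rep_len - sc.tag_len
        for rank, (s_start, s_end) in enumerate(arr["spacers"]):
            lam = sc.read_depth * (sc.abundance_decay**rank)
            n = int(rng.poisson(lam))
            expected[f"{arr['array_id']}_spacer_{rank + 1}"] = lam
            realized[f"{arr['array_id']}_spacer_{rank + 1}"] = n
            for _ in range(n):
                trim = int(rng.geometric(sc.trim_geometric_p)) - 1
                end3 = s_end + max(0, tail - trim)
                if end3 - (s_start - sc.tag_len) < 15:
                    end3 = s_start - sc.tag_len + 15
                emit(f"crRNA_{arr['array_id']}_{rank}", s_start - sc.tag_len, end3, "+")
        # pre-crRNA 5' leader reads pinpointing the TSS
        for _ in range(sc.leader_reads):
            length = int(rng.integers(45, 70))
            emit(f"precrRNA_{arr['array_id']}", arr["tss"], arr["tss"] + length, "+")
        expected[f"{arr['array_id']}_leader"] = sc.leader_reads

    # tRNA half precursors: defined 5' ends, slightly dispersed 3' ends
    for pair in truth.trna_pairs:
        strand = pair["strand"]
        for side in ("5", "3"):
            if side == "5":
                body = pair["body5_iv"]
                clamp = pair["clamp5_iv"]
                if strand == "+":
                    tx = (body[0], clamp[1])
                else:
                    tx = (clamp[0], body[1])
            else:
                body = pair["body3_iv"]
                clamp = pair["clamp3_iv"]
                off = pair["three_ext_offset"]
                if strand == "+":
                    tx = (clamp[0] - off, body[1])
                else:
                    tx = (body[0], clamp[1] + off)
            length = tx[1] - tx[0]
            lam = sc.read_depth * float(np.exp(-sc.rt_dropoff * length))
            n = int(rng.poisson(lam))
            key = pair["five_id"] if side == "5" else pair["three_id"]
            expected[key] = lam
            realized[key] = n
            for _ in range(n):
                jitter = int(rng.geometric(0.5)) - 1
                if strand == "+":
                    emit(f"half_{key}", tx[0], max(tx[0] + 15, tx[1] - jitter), strand)
                else:
                    emit(f"half_{key}", min(tx[1] - 15, tx[0] + jitter), tx[1], strand)

    # mature/unspliced tRNA gene reads (leaderless starts; G-1 for Tyr)
    for gene in truth.trna_genes:
        length = gene["end"] - gene["start"]
        lam = sc.read_depth * float(np.exp(-sc.rt_dropoff * length))
        n = int(rng.poisson(lam))
        expected[gene["gene_id"]] = lam
        realized[gene["gene_id"]] = n
        for _ in range(n):
            minus1 = rng.random() < gene.get("minus1_fraction", 0.0)
            jitter = int(rng.geometric(0.5)) - 1
            if gene["strand"] == "+":
                start = gene["start"] - (1 if minus1 else 0)
                emit(f"trna_{gene['gene_id']}", start, gene["end"] - jitter, "+")
            else:
                end = gene["end"] + (1 if minus1 else 0)
                emit(f"trna_{gene['gene_id']}", gene["start"] + jitter, end, "-")

    # C/D box sRNAs: abundant, near-full-length reads; circles add junctions
    for cd in truth.cd_srnas:
        lam = sc.cd_depth_multiplier * sc.read_depth
        n = int(rng.poisson(lam))
        expected[cd["srna_id"]] = lam
        realized[cd["srna_id"]] = n
        tx = cd["transcript"]
        for _ in range(n):
            j3 = int(rng.integers(0, 3))
            if cd["strand"] == "+":
                emit(f"cd_{cd['srna_id']}", tx[0], tx[1] - j3, "+")
            else:
                emit(f"cd_{cd['srna_id']}", tx[0] + j3, tx[1], "-")
        if cd.get("circular"):
            locus = genome.sequence[tx[0] : tx[1]]
            if cd["strand"] == "-":
                locus = revcomp(locus)
            for _ in range(sc.junction_reads):
                tail = int(rng.integers(15, 26))
                total = int(rng.integers(34, 46))
                seq = locus[-tail:] + locus[: total - tail]
                seq = _mutate(rng, seq, sc.error_rate)
                reads.append(
                    Read(f"junction_{cd['srna_id']}_{len(reads)}", seq, [30] * len(seq))
                )
            expected[f"{cd['srna_id']}_junction"] = sc.junction_reads

    # H/ACA sRNA
    if truth.haca:
        lam = 3 * sc.read_depth
        n = int(rng.poisson(lam))
        expected[truth.haca["srna_id"]] = lam
        realized[truth.haca["srna_id"]] = n
        for _ in range(n):
            j3 = int(rng.integers(0, 3))
            emit("haca", truth.haca["start"], truth.haca["end"] - j3, "+")

    # rRNA background (kept modest) and fragmented mRNA reads
    if truth.rrna is not None:
        rr = truth.rrna
        rr_start = genome.sequence.find(rr["sequence"])
        n = int(rng.poisson(sc.read_depth))
        expected[rr["rrna_id"]] = float(sc.read_depth)
        for _ in range(n):
            a = int(rng.integers(0, 240))
            emit("rrna", rr_start + a, rr_start + a + 60, "+")
    return reads
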