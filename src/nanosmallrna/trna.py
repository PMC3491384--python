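"""Trans-spliced tRNA-half pairing, assembly, and RNase-P-absence diagnostics.

Split tRNA genes in *Nanoarchaeum*-like genomes carry GC-rich
reverse-complementary "clamp" sequences on the intron-side end of each half;
the clamp duplex identifies the matching partner.  Pairing is solved as a
maximum-weight bipartite assignment over all 5'x3' clamp duplex scores.
Leaderless transcription (no RNase P) is checked by the fraction of read 5'
ends exactly at the mature tRNA start, the purine-start rule, and templated
-1 extensions (the G-1 case of tRNA-Tyr).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import Feature, GenomeRecord, is_purine, revcomp
from .reads import ReadPileup, call_termini


@dataclass
class TrnaHalfGene:
    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    half_side: str  # 'five_prime' or 'three_prime'
    body_seq: str = ""
    clamp_interval: tuple[int, int] | None = None
    clamp_seq: str = ""
    low_gc_clamp: bool = False
    clamp_truncated: bool = False
    anticodon: str = "NNN"

    @classmethod
    def from_feature(cls, f: Feature, genome: GenomeRecord) -> "TrnaHalfGene":
        side = f.attributes.get("half_side")
        if side not in ("five_prime", "three_prime"):
            raise ValueError(f"{f.feature_id}: missing/invalid half_side attribute")
        return cls(
            feature_id=f.feature_id,
            contig_id=f.contig_id,
            start=f.start,
            end=f.end,
            strand=f.strand,
            half_side=side,
            body_seq=f.sequence(genome),
            anticodon=f.attributes.get("anticodon", "NNN"),
        )


@dataclass
class TrnaHalfPair:
    five_half: TrnaHalfGene
    three_half: TrnaHalfGene
    duplex_len: int
    duplex_score: float
    gc_fraction_of_duplex: float
    mature_seq: str = ""
    junction: int = 0
    ambiguous: bool = False
    length_flag: bool = False


@dataclass
class LeaderlessRow:
    gene_id: str
    mature_start_fraction: float
    start_base: str
    purine_start: bool
    minus1_fraction: float
    minus1_base: str
    n_reads: int


# ---------------------------------------------------------------------------
# clamps


def extract_clamps(
    halves: list[TrnaHalfGene],
    genome: GenomeRecord,
    flank_len: int = 40,
    t_stretch: int = 5,
    gc_floor: float = 0.5,
) -> list[TrnaHalfGene]:
    """Attach clamp sequences: the intron-side flank of each half gene.

    The flank lies downstream of a 5' half and upstream of a 3' half (in the
    transcript sense) and is trimmed at the first run of >= ``t_stretch`` T
    (the polypyrimidine terminator).  Clamps with GC fraction below
    ``gc_floor`` are flagged rather than rejected.
    """
    for h in halves:
        if (h.half_side == "five_prime") == (h.strand == "+"):
            lo, hi = h.end, min(genome.length, h.end + flank_len)
        else:
            lo, hi = max(0, h.start - flank_len), h.start
        h.clamp_truncated = (hi - lo) < flank_len
        raw = genome.sequence[lo:hi]
        sense = revcomp(raw) if h.strand == "-" else raw
        if h.half_side == "three_prime":
            # clamp read towards the body: keep the portion nearest the gene
            sense = sense[::-1]
        tpos = sense.find("T" * t_stretch)
        if tpos != -1:
            sense = sense[:tpos]
        if h.half_side == "three_prime":
            sense = sense[::-1]
        h.clamp_seq = sense
        if h.strand == "+":
            if h.half_side == "five_prime":
                h.clamp_interval = (lo, lo + len(sense))
            else:
                h.clamp_interval = (hi - len(sense), hi)
        else:
            if h.half_side == "five_prime":
                h.clamp_interval = (hi - len(sense), hi)
            else:
                h.clamp_interval = (lo, lo + len(sense))
        gc = (sense.count("G") + sense.count("C")) / len(sense) if sense else 0.0
        h.low_gc_clamp = gc < gc_floor
    return halves


# ---------------------------------------------------------------------------
# pairing


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def duplex_score(
    clamp5: str, clamp3: str, gu_weight: float = 0.5
) -> tuple[float, int, float]:
    """Best ungapped antiparallel duplex between two clamp sequences.

    Slides ``clamp5`` along ``revcomp-orientation`` of ``clamp3`` and scores
    the best contiguous paired run (Watson-Crick = 1, GU wobble =
    ``gu_weight``).  Returns (score, run length, GC fraction of the run).
    """
    other = clamp3[::-1]  # antiparallel orientation; compare base vs base
    best = (0.0, 0, 0.0)
    n5, n3 = len(clamp5), len(other)
    for shift in range(-(n3 - 1), n5):
        score = 0.0
        run = 0
        gc = 0
        cur = (0.0, 0, 0)
        for i in range(max(0, shift), min(n5, shift + n3)):
            a, b = clamp5[i], other[i - shift]
            if (a, b) in _WC:
                score += 1.0
                run += 1
                gc += 1 if a in "GC" else 0
            elif (a, b) in _GU:
                score += gu_weight
                run += 1
                gc += 1 if a in "GC" else 0
            else:
                if score > cur[0]:
                    cur = (score, run, gc)
                score, run, gc = 0.0, 0, 0
            if score > cur[0]:
                cur = (score, run, gc)
        if cur[0] > best[0]:
            best = (cur[0], cur[1], cur[2] / cur[1] if cur[1] else 0.0)
    return best


def pair_halves(
    halves: list[TrnaHalfGene],
    min_duplex_len: int = 8,
    gu_weight: float = 0.5,
    tie_tol: float = 1e-9,
) -> list[TrnaHalfPair]:
    """One-to-one pairing of 5' and 3' halves by maximum total duplex score.

    The assignment is solved exactly (Hungarian algorithm); pairs whose best
    duplex run is shorter than ``min_duplex_len`` are rejected.  A pair is
    flagged ambiguous when some other partner reaches the same pair score.
    """
    fives = [h for h in halves if h.half_side == "five_prime"]
    threes = [h for h in halves if h.half_side == "three_prime"]
    if not fives or not threes:
        return []
    scores = np.zeros((len(fives), len(threes)))
    details = {}
    for i, f in enumerate(fives):
        for j, t in enumerate(threes):
            s, length, gc = duplex_score(f.clamp_seq, t.clamp_seq, gu_weight)
            scores[i, j] = s
            details[(i, j)] = (s, length, gc)
    rows, cols = linear_sum_assignment(scores, maximize=True)
    pairs = []
    for i, j in zip(rows, cols):
        s, length, gc = details[(i, j)]
        if length < min_duplex_len:
            continue
        ambiguous = bool(
            np.any(np.abs(np.delete(scores[i, :], j) - s) <= tie_tol)
            or np.any(np.abs(np.delete(scores[:, j], i) - s) <= tie_tol)
        )
        pair = TrnaHalfPair(
            five_half=fives[i],
            three_half=threes[j],
            duplex_len=length,
            duplex_score=s,
            gc_fraction_of_duplex=gc,
            ambiguous=ambiguous,
        )
        assemble_mature(pair)
        pairs.append(pair)
    return pairs


def assemble_mature(
    pair: TrnaHalfPair, length_bounds: tuple[int, int] = (70, 100)
) -> TrnaHalfPair:
    """Join the two body sequences into the mature trans-spliced tRNA."""
    if not pair.five_half.body_seq or not pair.three_half.body_seq:
        raise ValueError("cannot assemble a mature tRNA from an empty half body")
    pair.mature_seq = pair.five_half.body_seq + pair.three_half.body_seq
    pair.junction = len(pair.five_half.body_seq)
    n = len(pair.mature_seq)
    if not (length_bounds[0] <= n <= length_bounds[1]):
        pair.length_flag = True
    return pair


# ---------------------------------------------------------------------------
# precursor termini


@dataclass
class PrecursorTerminusRow:
    feature_id: str
    half_side: str
    five_position: int | None
    three_position: int | None
    five_offset_body: int | None
    three_offset_body: int | None
    clamp_side_offset: int | None
    purine_start: bool | None
    five_dispersion: float
    three_dispersion: float
    read_through: bool
    absent: bool


def _dispersion(arr: np.ndarray, lo: int, hi: int) -> float:
    window = arr[lo:hi].astype(float)
    total = window.sum()
    if total == 0:
        return 0.0
    pos = np.arange(lo, hi, dtype=float)
    mean = (pos * window).sum() / total
    return float(np.sqrt(((pos - mean) ** 2 * window).sum() / total))


def annotate_precursor_termini(
    halves: list[TrnaHalfGene],
    pileup: ReadPileup,
    genome: GenomeRecord,
    features: list[Feature] | None = None,
    margin: int = 15,
) -> list[PrecursorTerminusRow]:
    """Modal precursor termini per half gene with offsets to the annotated
    boundaries.

    ``clamp_side_offset`` is signed on the transcript strand: +2 means the
    precursor extends two templated bases beyond the clamp boundary (the
    tRNA-Met 3' half case), -1 means it stops one base short.  Read-through
    into an annotated adjacent gene is flagged.
    """
    rows = []
    for h in halves:
        clamp = h.clamp_interval or (h.end, h.end)
        span_lo = min(h.start, clamp[0]) - margin
        span_hi = max(h.end, clamp[1]) + margin
        region = (max(0, span_lo), min(pileup.length, span_hi))
        five_calls = call_termini(pileup, region, h.strand, "5p", min_support=2)
        three_calls = call_termini(pileup, region, h.strand, "3p", min_support=2)
        if not five_calls and not three_calls:
            rows.append(
                PrecursorTerminusRow(
                    h.feature_id, h.half_side, None, None, None, None, None,
                    None, 0.0, 0.0, False, True,
                )
            )
            continue
        five_pos = five_calls[0].position if five_calls else None
        three_pos = three_calls[0].position if three_calls else None

        def sense_offset(pos: int, anchor: int) -> int:
            return (pos - anchor) if h.strand == "+" else (anchor - pos)

        body_start = h.start if h.strand == "+" else h.end - 1
        body_end = h.end - 1 if h.strand == "+" else h.start
        five_off = sense_offset(five_pos, body_start) if five_pos is not None else None
        three_off = sense_offset(three_pos, body_end) if three_pos is not None else None
        # clamp-side terminus: 3' end of a 5' half, 5' end of a 3' half
        clamp_off = None
        if h.half_side == "five_prime" and three_pos is not None:
            clamp_outer = clamp[1] - 1 if h.strand == "+" else clamp[0]
            clamp_off = sense_offset(three_pos, clamp_outer)
        elif h.half_side == "three_prime" and five_pos is not None:
            clamp_outer = clamp[0] if h.strand == "+" else clamp[1] - 1
            clamp_off = -sense_offset(five_pos, clamp_outer)
        purine = None
        if five_pos is not None:
            base = genome.sequence[five_pos]
            if h.strand == "-":
                base = revcomp(base)
            purine = is_purine(base)
        read_through = False
        if features and three_pos is not None:
            for f in features:
                if f.feature_id == h.feature_id:
                    continue
                if f.overlaps(three_pos, three_pos + 1):
                    read_through = True
        rows.append(
            PrecursorTerminusRow(
                h.feature_id,
                h.half_side,
                five_pos,
                three_pos,
                five_off,
                three_off,
                clamp_off,
                purine,
                _dispersion(pileup.five_prime_ends[h.strand], *region),
                _dispersion(pileup.three_prime_ends[h.strand], *region),
                read_through,
                False,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# leaderless transcription


def leaderless_report(
    trna_genes: list[Feature],
    pileup: ReadPileup,
    genome: GenomeRecord,
) -> list[LeaderlessRow]:
    """Per tRNA gene: fraction of 5' read ends exactly at the mature start,
    the start base and purine flag, and the templated -1 extension test."""
    rows = []
    for gene in trna_genes:
        strand = gene.strand
        five = pileup.five_prime_ends[strand]
        if strand == "+":
            start = gene.start
            minus1 = start - 1
        else:
            start = gene.end - 1
            minus1 = start + 1
        lo = max(0, min(start, minus1) - 20)
        hi = min(pileup.length, max(start, minus1) + 21)
        n = int(five[lo:hi].sum())
        at_start = int(five[start]) if 0 <= start < pileup.length else 0
        at_minus1 = int(five[minus1]) if 0 <= minus1 < pileup.length else 0
        base = genome.sequence[start]
        m1_base = genome.sequence[minus1] if 0 <= minus1 < genome.length else "N"
        if strand == "-":
            base, m1_base = revcomp(base), revcomp(m1_base)
        rows.append(
            LeaderlessRow(
                gene_id=gene.feature_id,
                mature_start_fraction=at_start / n if n else 0.0,
                start_base=base,
                purine_start=is_purine(base),
                minus1_fraction=at_minus1 / n if n else 0.0,
                minus1_base=m1_base,
                n_reads=n,
            )
        )
    return rows
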