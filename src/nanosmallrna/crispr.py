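"""De novo CRISPR array detection and crRNA maturation profiling.

Arrays are found as chains of >= 3 near-identical repeats (20-50 nt,
pairwise identity >= 0.9) separated by 17-50 nt spacers, seeded by exact
k-mer self-matches.  Read pile-ups then yield the maturation model: the
repeat-derived 5' tag left by endonucleolytic cleavage within the repeat,
per-spacer abundances, the 3'-trimming profile, leader identity between
arrays, the transcription start site and the box A promoter element.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import Feature, GenomeRecord, revcomp
from .reads import ReadPileup, call_termini


@dataclass
class CrisprParams:
    min_repeats: int = 3
    repeat_len_min: int = 20
    repeat_len_max: int = 50
    spacer_len_min: int = 17
    spacer_len_max: int = 50
    spacer_soft_factor: float = 1.5  # long spacers up to factor*max are kept, flagged
    identity: float = 0.9
    seed_k: int = 12


@dataclass
class CrisprArray:
    array_id: str
    contig_id: str
    strand: str  # '.' until oriented
    repeats: list[tuple[int, int]]
    spacers: list[tuple[int, int]]
    spacer_seqs: list[str]
    repeat_consensus: str
    leader: tuple[int, int] | None = None
    orientation_method: str | None = None
    flags: dict[str, list[int]] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.repeats[0][0]

    @property
    def end(self) -> int:
        return self.repeats[-1][1]

    def spacer_order(self) -> list[int]:
        """Spacer indices in transcription (array) order."""
        order = list(range(len(self.spacers)))
        return order[::-1] if self.strand == "-" else order

    def first_repeat(self) -> tuple[int, int]:
        """The leader-proximal repeat on the array strand."""
        return self.repeats[-1] if self.strand == "-" else self.repeats[0]


@dataclass
class CrRnaProfile:
    array_id: str
    read_counts: list[int]
    relative_abundance: list[float]
    five_tag_length: int | None
    five_tag_sequence: str | None
    per_spacer_tag_length: list[int | None]
    three_end_distribution: list[dict[int, int]]
    trimming_hotspots: list[list[int]]
    zero_read_spacers: list[int]


@dataclass
class LeaderAnalysis:
    identical_prefix_length: int | None = None
    truncated: bool = False
    tss_position: int | None = None
    tss_base: str | None = None
    tss_offset_to_first_repeat: int | None = None
    tss_tied: bool = False
    boxA_interval: tuple[int, int] | None = None
    boxA_sequence: str | None = None
    boxA_offset: int | None = None
    boxA_mismatches: int | None = None


# ---------------------------------------------------------------------------
# detection


def _column_consensus(seqs: list[str]) -> tuple[str, float]:
    """Majority consensus and mean per-column majority fraction."""
    length = min(len(s) for s in seqs)
    cons = []
    fracs = []
    for col in range(length):
        counts = Counter(s[col] for s in seqs)
        base, n = counts.most_common(1)[0]
        cons.append(base)
        fracs.append(n / len(seqs))
    return "".join(cons), sum(fracs) / length if length else 0.0


def _majority_frac(genome_seq: str, positions: list[int], offset: int) -> float:
    bases = []
    for p in positions:
        q = p + offset
        if 0 <= q < len(genome_seq):
            bases.append(genome_seq[q])
    if len(bases) < 2:
        return 0.0
    _, n = Counter(bases).most_common(1)[0]
    return n / len(bases)


def detect_arrays(
    genome: GenomeRecord, params: CrisprParams | None = None
) -> list[CrisprArray]:
    """Find CRISPR arrays by k-mer seeded self-match chaining.

    Repeat boundaries are refined column-wise: a flanking column belongs to
    the repeat while >= ``identity`` of the copies agree on the majority
    base.  Orientation is left unset ('.').
    """
    params = params or CrisprParams()
    seq = genome.sequence
    k = params.seed_k
    min_gap = params.repeat_len_min + params.spacer_len_min
    max_gap = params.repeat_len_max + int(
        params.spacer_len_max * params.spacer_soft_factor
    )

    kmer_pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer_pos.setdefault(seq[i : i + k], []).append(i)

    candidates: list[CrisprArray] = []
    seen_chains: set[tuple[int, ...]] = set()

    for i in range(len(seq) - k + 1):
        positions = kmer_pos[seq[i : i + k]]
        if len(positions) < params.min_repeats:
            continue
        chain = [p for p in positions if p >= i]
        if chain[0] != i:
            continue
        # greedy chaining with plausible repeat periods
        kept = [chain[0]]
        for p in chain[1:]:
            gap = p - kept[-1]
            if min_gap <= gap <= max_gap:
                kept.append(p)
            elif gap > max_gap:
                break
        if len(kept) < params.min_repeats:
            continue
        signature = tuple(kept)
        if signature in seen_chains:
            continue
        seen_chains.add(signature)
        # column-wise boundary refinement around the seed
        left = 0
        while (
            left < params.repeat_len_max - k
            and kept[0] - (left + 1) >= 0
            and _majority_frac(seq, kept, -(left + 1)) >= params.identity
        ):
            left += 1
        right = k
        while (
            right - (-left) < params.repeat_len_max
            and kept[-1] + right < len(seq)
            and _majority_frac(seq, kept, right) >= params.identity
        ):
            right += 1
        rep_len = left + right
        if not (params.repeat_len_min <= rep_len <= params.repeat_len_max):
            continue
        starts = [p - left for p in kept]
        repeats = [(s, s + rep_len) for s in starts]
        # validate spacers
        spacers: list[tuple[int, int]] = []
        flags: dict[str, list[int]] = {"long_spacer": [], "duplicate_spacer": []}
        ok = True
        for (a1, b1), (a2, b2) in zip(repeats, repeats[1:]):
            slen = a2 - b1
            if slen < params.spacer_len_min:
                ok = False
                break
            if slen > params.spacer_len_max * params.spacer_soft_factor:
                ok = False
                break
            if slen > params.spacer_len_max:
                flags["long_spacer"].append(len(spacers))
            spacers.append((b1, a2))
        if not ok or len(repeats) < params.min_repeats:
            continue
        rep_seqs = [seq[a:b] for a, b in repeats]
        consensus, mean_frac = _column_consensus(rep_seqs)
        if mean_frac < params.identity:
            continue
        spacer_seqs = [seq[a:b] for a, b in spacers]
        seen: dict[str, int] = {}
        for idx, s in enumerate(spacer_seqs):
            if s in seen:
                flags["duplicate_spacer"].append(idx)
            seen[s] = idx
        candidates.append(
            CrisprArray(
                array_id="",
                contig_id=genome.contig_id,
                strand=".",
                repeats=repeats,
                spacers=spacers,
                spacer_seqs=spacer_seqs,
                repeat_consensus=consensus,
                flags={k: v for k, v in flags.items() if v},
            )
        )
    # overlap resolution: a chain seeded off-register can cover only part of
    # an array; prefer candidates with more repeats, then longer span
    candidates.sort(key=lambda a: (-len(a.repeats), -(a.end - a.start), a.start))
    arrays: list[CrisprArray] = []
    for cand in candidates:
        if any(cand.start < a.end and a.start < cand.end for a in arrays):
            continue
        arrays.append(cand)
    arrays.sort(key=lambda a: a.start)
    for idx, arr in enumerate(arrays, start=1):
        arr.array_id = f"crispr_{idx}"
    return arrays


# ---------------------------------------------------------------------------
# orientation


def orient_array(
    array: CrisprArray,
    pileup: ReadPileup | None = None,
    genome: GenomeRecord | None = None,
    read_majority: float = 0.9,
    flank: int = 130,
) -> CrisprArray:
    """Assign the transcribed strand.

    With reads: the strand carrying >= ``read_majority`` of array-overlapping
    reads wins.  Without reads (or with inconclusive coverage) the AT-rich
    flank is taken as the leader side: CRISPR leaders are AT-rich relative to
    the degenerate boundary repeat on the 3' side.
    """
    read_call = None
    if pileup is not None:
        counts = {}
        for s in "+-":
            counts[s] = int(pileup.depth[s][array.start : array.end].sum())
        total = counts["+"] + counts["-"]
        if total > 0:
            if counts["+"] / total >= read_majority:
                read_call = "+"
            elif counts["-"] / total >= read_majority:
                read_call = "-"
    seq_call = None
    if genome is not None:
        seq = genome.sequence
        up = seq[max(0, array.start - flank) : array.start]
        down = seq[array.end : array.end + flank]

        def at_frac(s: str) -> float:
            return (s.count("A") + s.count("T")) / len(s) if s else 0.0

        seq_call = "+" if at_frac(up) >= at_frac(down) else "-"
    if read_call is not None:
        array.strand = read_call
        array.orientation_method = "reads"
        if seq_call is not None and seq_call != read_call:
            array.flags.setdefault("orientation_conflict", []).append(0)
    elif seq_call is not None:
        array.strand = seq_call
        array.orientation_method = "sequence"
    else:
        raise ValueError("orient_array needs a pileup or a genome")
    first = array.first_repeat()
    if array.strand == "+":
        array.leader = (max(0, first[0] - 500), first[0])
    else:
        array.leader = (first[1], first[1] + 500)
    return array


# ---------------------------------------------------------------------------
# maturation


def infer_maturation(
    array: CrisprArray,
    pileup: ReadPileup,
    max_tail: int | None = None,
) -> CrRnaProfile:
    """Per-spacer crRNA maturation statistics from the read pile-up.

    The 5' tag length of a spacer is the modal distance from read 5' ends to
    the spacer start, constrained to lie within the repeat; the array-level
    tag is the modal offset pooled over all spacers, and the tag sequence is
    the corresponding suffix (array-strand sense) of the repeat consensus.
    """
    if array.strand not in "+-":
        raise ValueError("array must be oriented before maturation inference")
    strand = array.strand
    rep_len = len(array.repeat_consensus)
    max_tail = max_tail if max_tail is not None else rep_len
    five = pileup.five_prime_ends[strand]
    counts: list[int] = []
    tag_modes: list[int | None] = []
    tag_pool: Counter = Counter()
    three_dists: list[dict[int, int]] = []
    hotspots: list[list[int]] = []
    zero: list[int] = []

    order = array.spacer_order()
    for rank, idx in enumerate(order):
        a, b = array.spacers[idx]
        if strand == "+":
            # 5' ends within the upstream repeat or early spacer
            lo, hi = a - rep_len, a + (b - a) // 2
            window = five[max(0, lo) : hi]
            offsets = {a - p: int(window[p - max(0, lo)]) for p in range(max(0, lo), hi)}
        else:
            lo, hi = b - (b - a) // 2, b + rep_len
            window = five[lo : min(pileup.length, hi)]
            offsets = {
                p - (b - 1): int(window[p - lo]) for p in range(lo, min(pileup.length, hi))
            }
        tag_offsets = {o: c for o, c in offsets.items() if 1 <= o <= rep_len and c > 0}
        n_reads = sum(c for c in offsets.values() if c > 0)
        counts.append(n_reads)
        if not tag_offsets:
            tag_modes.append(None)
            if n_reads == 0:
                zero.append(rank)
        else:
            mode = max(tag_offsets.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            tag_modes.append(mode)
            tag_pool.update(tag_offsets)
        # 3' end offsets relative to the spacer 3' terminus (array sense)
        three = pileup.three_prime_ends[strand]
        dist: dict[int, int] = {}
        if strand == "+":
            for p in range(a, min(pileup.length, b + max_tail)):
                if three[p]:
                    dist[p - (b - 1)] = int(three[p])
            region = (a, min(pileup.length, b + max_tail))
        else:
            for p in range(max(0, a - max_tail), b):
                if three[p]:
                    dist[a - p] = int(three[p])
            region = (max(0, a - max_tail), b)
        three_dists.append(dist)
        calls = call_termini(pileup, region, strand, "3p", min_support=2)
        if strand == "+":
            hotspots.append(sorted(c.position - (b - 1) for c in calls if c.is_hotspot))
        else:
            hotspots.append(sorted(a - c.position for c in calls if c.is_hotspot))

    total = sum(counts)
    abundance = [c / total if total else 0.0 for c in counts]
    if tag_pool:
        tag_len = max(tag_pool.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        cons = array.repeat_consensus
        cons_sense = revcomp(cons) if strand == "-" else cons
        tag_seq = cons_sense[-tag_len:]
    else:
        tag_len = None
        tag_seq = None
    return CrRnaProfile(
        array_id=array.array_id,
        read_counts=counts,
        relative_abundance=abundance,
        five_tag_length=tag_len,
        five_tag_sequence=tag_seq,
        per_spacer_tag_length=tag_modes,
        three_end_distribution=three_dists,
        trimming_hotspots=hotspots,
        zero_read_spacers=zero,
    )


# ---------------------------------------------------------------------------
# leader, TSS, box A


def compare_leaders(
    array_a: CrisprArray,
    array_b: CrisprArray,
    genome: GenomeRecord,
    max_len: int = 500,
) -> LeaderAnalysis:
    """Length of the identical stretch immediately upstream of the first
    repeat of each (oriented) array, walking away from the repeat."""
    from .model import COMPLEMENT

    seqs = []
    truncated = False
    for arr in (array_a, array_b):
        first = arr.first_repeat()
        if arr.strand == "-":
            # upstream on '-' extends to higher coordinates; read outward,
            # base-complemented to the transcript strand
            span = genome.sequence[first[1] : first[1] + max_len]
            seqs.append(span.translate(COMPLEMENT))
        else:
            span = genome.sequence[max(0, first[0] - max_len) : first[0]]
            seqs.append(span[::-1])
        truncated |= len(span) < max_len
    n = 0
    for x, y in zip(*seqs):
        if x != y:
            break
        n += 1
    return LeaderAnalysis(identical_prefix_length=n, truncated=truncated)


def call_tss(
    array: CrisprArray,
    pileup: ReadPileup,
    genome: GenomeRecord,
    leader_window: int = 200,
) -> LeaderAnalysis:
    """TSS = modal read 5'-end position within the leader (array strand).

    Ties break to the upstream-most position.  The offset convention counts
    bases from the TSS to the first repeat start on the array strand:
    ``first_repeat_start - tss = 33`` means the TSS adenosine sits 33 nt
    upstream of the repeat.
    """
    first = array.first_repeat()
    strand = array.strand
    five = pileup.five_prime_ends[strand]
    res = LeaderAnalysis()
    if strand == "+":
        lo, hi = max(0, first[0] - leader_window), first[0]
        window = five[lo:hi]
        if int(window.sum()) == 0:
            return res
        best = int(window.max())
        candidates = [lo + i for i in range(hi - lo) if window[i] == best]
        tss = candidates[0]  # upstream-most
        res.tss_tied = len(candidates) > 1
        res.tss_offset_to_first_repeat = first[0] - tss
        res.tss_base = genome.sequence[tss]
    else:
        lo, hi = first[1], min(pileup.length, first[1] + leader_window)
        window = five[lo:hi]
        if int(window.sum()) == 0:
            return res
        best = int(window.max())
        candidates = [lo + i for i in range(hi - lo) if window[i] == best]
        tss = candidates[-1]  # upstream-most on '-'
        res.tss_tied = len(candidates) > 1
        res.tss_offset_to_first_repeat = tss - (first[1] - 1)
        res.tss_base = revcomp(genome.sequence[tss])
    res.tss_position = tss
    return res


def find_boxA(
    genome: GenomeRecord,
    tss: int,
    strand: str = "+",
    hexamer: str = "TTTAAA",
    scan_window: tuple[int, int] = (-35, -20),
    preferred_offset: int = 26,
    max_mismatches: int = 1,
) -> LeaderAnalysis:
    """Best box A (TATA-like) hexamer match upstream of the TSS.

    The offset is counted from the 5'-most base of the hexamer to the TSS on
    the transcript strand; Hamming-distance ties break towards
    ``preferred_offset`` (the canonical archaeal promoter spacing).
    """
    res = LeaderAnalysis()
    hits = []
    for off in range(-scan_window[0], -scan_window[1] - 1, -1):
        if strand == "+":
            start = tss - off
            if start < 0 or start + len(hexamer) > genome.length:
                continue
            cand = genome.sequence[start : start + len(hexamer)]
            iv = (start, start + len(hexamer))
        else:
            end = tss + 1 + off
            start = end - len(hexamer)
            if start < 0 or end > genome.length:
                continue
            cand = revcomp(genome.sequence[start:end])
            iv = (start, end)
        mm = sum(1 for a, b in zip(cand, hexamer) if a != b)
        hits.append((mm, abs(off - preferred_offset), off, cand, iv))
    if not hits:
        return res
    hits.sort()
    mm, _, off, cand, iv = hits[0]
    if mm > max_mismatches:
        return res
    res.boxA_interval = iv
    res.boxA_sequence = cand
    res.boxA_offset = off
    res.boxA_mismatches = mm
    return res


def array_features(array: CrisprArray) -> list[Feature]:
    """GFF-exportable features for one array (array, repeats, spacers)."""
    feats = [
        Feature(
            array.array_id,
            array.contig_id,
            array.start,
            array.end,
            array.strand if array.strand in "+-" else ".",
            "CRISPR_array",
            {"repeats": str(len(array.repeats))},
        )
    ]
    for i, (a, b) in enumerate(array.spacers):
        feats.append(
            Feature(
                f"{array.array_id}_spacer_{i + 1}",
                array.contig_id,
                a,
                b,
                array.strand if array.strand in "+-" else ".",
                "other",
                {"class": "CRISPR_spacer"},
            )
        )
    return feats
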