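"""Read preprocessing, a micro-mapper for small genomes, and terminus calling.

The mapper is a seed-and-extend aligner intended for compact (<= 16 Mb)
archaeal genomes: exact k-mer seeds nominate candidate diagonals, a banded
edit-cost alignment (mismatch 2, indel 3 by default) scores each candidate,
and acceptance requires an aligned read fraction >= ``length_fraction`` and
an identity >= ``similarity``.  Reads with several cost-tied best placements
(CRISPR repeats, duplicated leaders) are handled by ``multimap_policy``;
the default places them at a seeded-random best hit so repeat-internal
coverage is preserved reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GenomeRecord, MappedRead, Read, revcomp

PHRED_ERROR = [10 ** (-q / 10) for q in range(100)]


@dataclass
class TrimConfig:
    adapter_sequences: list[str] = field(
        default_factory=lambda: ["AGATCGGAAGAGC"]  # TruSeq adapter prefix
    )
    quality_error_limit: float = 0.05
    min_length: int = 15
    polyA_min_run: int = 6
    adapter_min_overlap: int = 8
    adapter_min_identity: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.quality_error_limit < 1):
            raise ValueError("quality_error_limit must be in (0,1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class MapConfig:
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.5
    similarity: float = 0.8
    multimap_policy: str = "random_best_seeded"  # or report_all / discard
    seed_k: int = 12
    band: int = 8

    def __post_init__(self) -> None:
        for name in ("mismatch_cost", "insertion_cost", "deletion_cost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not (0 < self.length_fraction <= 1):
            raise ValueError("length_fraction must be in (0,1]")
        if not (0 < self.similarity <= 1):
            raise ValueError("similarity must be in (0,1]")
        if self.multimap_policy not in ("random_best_seeded", "report_all", "discard"):
            raise ValueError(f"unknown multimap_policy {self.multimap_policy!r}")


# ---------------------------------------------------------------------------
# trimming


def _trim_adapter(seq: str, cfg: TrimConfig) -> str:
    """Remove the best ungapped adapter suffix match (>=90% id over >=8 nt)."""
    best_cut = None
    best_matches = -1
    for adapter in cfg.adapter_sequences:
        for start in range(len(seq)):
            overlap = min(len(adapter), len(seq) - start)
            if overlap < cfg.adapter_min_overlap:
                break
            matches = sum(
                1 for a, b in zip(seq[start : start + overlap], adapter) if a == b
            )
            if matches / overlap >= cfg.adapter_min_identity and matches > best_matches:
                best_matches = matches
                best_cut = start
    return seq[:best_cut] if best_cut is not None else seq


def _trim_polya(seq: str, min_run: int) -> str:
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    return seq[:i] if n - i >= min_run else seq


def _trim_quality(seq: str, quals: list[int], limit: float) -> tuple[str, list[int]]:
    """Modified-Mott trimming: keep the segment maximising sum(limit - p_err).

    This is the standard open reimplementation of "quality score limit"
    trimming: each base contributes ``limit - p_err`` and the maximum-sum
    contiguous segment is retained (empty if every prefix sum is negative).
    """
    best_sum = cur_sum = 0.0
    best = (0, 0)
    start = 0
    for i, q in enumerate(quals):
        cur_sum += limit - PHRED_ERROR[min(q, 99)]
        if cur_sum <= 0:
            cur_sum = 0.0
            start = i + 1
        elif cur_sum > best_sum:
            best_sum = cur_sum
            best = (start, i + 1)
    return seq[best[0] : best[1]], quals[best[0] : best[1]]


def trim_reads(
    reads: list[Read], cfg: TrimConfig | None = None
) -> tuple[list[Read], dict[str, int]]:
    """Adapter, poly-A and quality trimming plus a minimum-length filter.

    Returns the surviving reads and a discard log with counts of reads
    dropped at each step.
    """
    cfg = cfg or TrimConfig()
    kept: list[Read] = []
    log = {"input": len(reads), "too_short": 0, "empty_after_quality": 0, "kept": 0}
    for read in reads:
        seq = _trim_adapter(read.sequence, cfg)
        seq = _trim_polya(seq, cfg.polyA_min_run)
        quals = read.qualities[: len(seq)] if read.qualities is not None else None
        if quals is not None:
            seq, quals = _trim_quality(seq, quals, cfg.quality_error_limit)
            if not seq:
                log["empty_after_quality"] += 1
                continue
        if len(seq) < cfg.min_length:
            log["too_short"] += 1
            continue
        kept.append(Read(read.read_id, seq, quals))
    log["kept"] = len(kept)
    return kept, log


# ---------------------------------------------------------------------------
# mapping


class _Alignment:
    __slots__ = ("cost", "start", "end", "matches", "columns")

    def __init__(self, cost, start, end, matches, columns):
        self.cost = cost
        self.start = start
        self.end = end
        self.matches = matches
        self.columns = columns

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _banded_align(
    read: str, ref: str, cfg: MapConfig
) -> _Alignment | None:
    """Semi-global banded alignment: full read vs. a reference window.

    Genome-side end gaps are free.  Returns the minimum-cost placement with
    per-path match/column counts (ties resolved diagonal > deletion >
    insertion, then leftmost start).
    """
    n, m = len(read), len(ref)
    if m == 0:
        return None
    band = cfg.band
    INF = float("inf")
    # rows: read prefix length 0..n ; cols: ref positions 0..m
    prev_cost = [0.0] * (m + 1)
    prev_start = list(range(m + 1))
    prev_match = [0] * (m + 1)
    prev_cols = [0] * (m + 1)
    for i in range(1, n + 1):
        lo = max(0, i - band)
        hi = min(m, i + band + (m - n))
        cur_cost = [INF] * (m + 1)
        cur_start = [0] * (m + 1)
        cur_match = [0] * (m + 1)
        cur_cols = [0] * (m + 1)
        ri = read[i - 1]
        for j in range(lo, hi + 1):
            best = INF
            bstart = bmatch = bcols = 0
            if j > 0 and prev_cost[j - 1] < INF:  # diagonal
                hit = ri == ref[j - 1]
                c = prev_cost[j - 1] + (0 if hit else cfg.mismatch_cost)
                if c < best:
                    best = c
                    bstart = prev_start[j - 1]
                    bmatch = prev_match[j - 1] + (1 if hit else 0)
                    bcols = prev_cols[j - 1] + 1
            if j > 0 and cur_cost[j - 1] < INF:  # deletion (gap in read)
                c = cur_cost[j - 1] + cfg.deletion_cost
                if c < best:
                    best = c
                    bstart = cur_start[j - 1]
                    bmatch = cur_match[j - 1]
                    bcols = cur_cols[j - 1] + 1
            if prev_cost[j] < INF:  # insertion (extra read base)
                c = prev_cost[j] + cfg.insertion_cost
                if c < best:
                    best = c
                    bstart = prev_start[j]
                    bmatch = prev_match[j]
                    bcols = prev_cols[j] + 1
            cur_cost[j] = best
            cur_start[j] = bstart
            cur_match[j] = bmatch
            cur_cols[j] = bcols
        prev_cost, prev_start, prev_match, prev_cols = (
            cur_cost,
            cur_start,
            cur_match,
            cur_cols,
        )
    best_j = None
    for j in range(m + 1):
        if prev_cost[j] < INF and (best_j is None or prev_cost[j] < prev_cost[best_j]):
            best_j = j
    if best_j is None:
        return None
    return _Alignment(
        prev_cost[best_j],
        prev_start[best_j],
        best_j,
        prev_match[best_j],
        prev_cols[best_j],
    )


class MicroMapper:
    """Exact-seed + banded-extension mapper for one contig."""

    def __init__(self, genome: GenomeRecord, cfg: MapConfig | None = None):
        if genome.length > 16_000_000:
            raise ValueError("micro-mapper is designed for genomes <= 16 Mb")
        self.genome = genome
        self.cfg = cfg or MapConfig()
        self._indexes: dict[int, dict[str, list[int]]] = {}

    def _index(self, k: int) -> dict[str, list[int]]:
        if k not in self._indexes:
            seq = self.genome.sequence
            idx: dict[str, list[int]] = {}
            for i in range(len(seq) - k + 1):
                idx.setdefault(seq[i : i + k], []).append(i)
            self._indexes[k] = idx
        return self._indexes[k]

    def _exact_hits(self, seq: str) -> list[int]:
        hits = []
        pos = self.genome.sequence.find(seq)
        while pos != -1:
            hits.append(pos)
            pos = self.genome.sequence.find(seq, pos + 1)
        return hits

    def _candidates(self, seq: str) -> list[int]:
        """Candidate window starts (diagonals) from exact k-mer seeds."""
        k = max(6, min(self.cfg.seed_k, len(seq) // 3 or len(seq)))
        if k > len(seq):
            return []
        idx = self._index(k)
        diags: set[int] = set()
        for off in range(0, len(seq) - k + 1):
            for pos in idx.get(seq[off : off + k], ()):
                diags.add(pos - off)
        # cluster diagonals within the band into one representative
        out: list[int] = []
        for d in sorted(diags):
            if not out or d - out[-1] > self.cfg.band:
                out.append(d)
        return out

    def map_read(self, read: Read) -> list[MappedRead]:
        """All cost-tied best acceptable placements of one read."""
        cfg = self.cfg
        seq = read.sequence
        placements: list[tuple[float, int, int, str]] = []
        # exact fast path: a full-length exact match is always optimal
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for pos in self._exact_hits(s):
                placements.append((0.0, pos, pos + len(s), strand))
        if not placements:
            min_id = cfg.similarity
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for diag in self._candidates(s):
                    lo = max(0, diag - cfg.band)
                    hi = min(self.genome.length, diag + len(s) + cfg.band)
                    aln = _banded_align(s, self.genome.sequence[lo:hi], cfg)
                    if aln is None or aln.columns == 0:
                        continue
                    if aln.identity < min_id:
                        continue
                    placements.append((aln.cost, lo + aln.start, lo + aln.end, strand))
        if not placements:
            return []
        best_cost = min(p[0] for p in placements)
        best = sorted(
            {p for p in placements if p[0] == best_cost},
            key=lambda p: (p[1], p[3]),
        )
        unique = len(best) == 1
        return [
            MappedRead(read.read_id, self.genome.contig_id, s, e, st, c, unique)
            for c, s, e, st in best
        ]


def map_reads(
    reads: list[Read],
    genome: GenomeRecord,
    cfg: MapConfig | None = None,
    seed: int = 0,
) -> tuple[list[MappedRead], dict[str, int]]:
    """Map a read set; multireads are resolved per ``multimap_policy``."""
    cfg = cfg or MapConfig()
    mapper = MicroMapper(genome, cfg)
    rng = np.random.default_rng(seed)
    mapped: list[MappedRead] = []
    log = {"input": len(reads), "mapped": 0, "unmapped": 0, "multimapped": 0}
    for read in reads:
        hits = mapper.map_read(read)
        if not hits:
            log["unmapped"] += 1
            continue
        if len(hits) == 1:
            mapped.append(hits[0])
        else:
            log["multimapped"] += 1
            if cfg.multimap_policy == "discard":
                continue
            if cfg.multimap_policy == "report_all":
                mapped.extend(hits)
            else:  # random_best_seeded
                mapped.append(hits[int(rng.integers(len(hits)))])
        log["mapped"] += 1
    return mapped, log


# ---------------------------------------------------------------------------
# pileup and termini


class ReadPileup:
    """Per-strand depth and 5'/3' end-count arrays for one contig."""

    def __init__(self, genome: GenomeRecord):
        self.contig_id = genome.contig_id
        self.length = genome.length
        self.depth = {s: np.zeros(genome.length, dtype=np.int64) for s in "+-"}
        self.five_prime_ends = {
            s: np.zeros(genome.length, dtype=np.int64) for s in "+-"
        }
        self.three_prime_ends = {
            s: np.zeros(genome.length, dtype=np.int64) for s in "+-"
        }
        self.total_mapped = {"+": 0, "-": 0}

    def add(self, m: MappedRead) -> None:
        if m.contig_id != self.contig_id:
            raise ValueError(f"read {m.read_id}: unknown contig {m.contig_id}")
        if m.start < 0 or m.end > self.length:
            raise ValueError(f"read {m.read_id}: interval outside contig")
        self.depth[m.strand][m.start : m.end] += 1
        self.five_prime_ends[m.strand][m.five_prime] += 1
        self.three_prime_ends[m.strand][m.three_prime] += 1
        self.total_mapped[m.strand] += 1

    def check(self) -> None:
        """Assert end-count conservation (one 5' and one 3' end per read)."""
        for s in "+-":
            n = self.total_mapped[s]
            if (
                int(self.five_prime_ends[s].sum()) != n
                or int(self.three_prime_ends[s].sum()) != n
            ):
                raise AssertionError(f"end-count conservation violated on strand {s}")


def build_pileup(mapped: list[MappedRead], genome: GenomeRecord) -> ReadPileup:
    pileup = ReadPileup(genome)
    for m in mapped:
        pileup.add(m)
    pileup.check()
    return pileup


@dataclass
class TerminusCall:
    contig_id: str
    position: int
    strand: str
    side: str  # '5p' or '3p'
    support: int
    local_fraction: float
    is_hotspot: bool

    def __post_init__(self) -> None:
        if not (0 <= self.local_fraction <= 1):
            raise ValueError("local_fraction outside [0,1]")


def call_termini(
    pileup: ReadPileup,
    region: tuple[int, int],
    strand: str,
    side: str,
    min_support: int = 2,
    window: int = 10,
    hotspot_fraction: float = 0.10,
) -> list[TerminusCall]:
    """Call read-end maxima in ``region``.

    Every local maximum of the end-count array with ``support >= min_support``
    is returned; the global maximum is the modal terminus (listed first,
    ``is_hotspot`` False), secondary maxima whose share of termini within
    ``+-window`` reaches ``hotspot_fraction`` are flagged as trimming
    hotspots.  Coordinate ties break towards the smaller genomic position.
    """
    arr = (pileup.five_prime_ends if side == "5p" else pileup.three_prime_ends)[strand]
    lo, hi = max(0, region[0]), min(pileup.length, region[1])
    if hi <= lo:
        return []
    sub = arr[lo:hi]
    if int(sub.sum()) == 0:
        return []
    calls = []
    for p in range(lo, hi):
        v = arr[p]
        if v < min_support:
            continue
        left = arr[p - 1] if p > lo else 0
        right = arr[p + 1] if p + 1 < hi else 0
        if v > left and v >= right:  # leftmost point of a plateau
            wlo, whi = max(lo, p - window), min(hi, p + window + 1)
            denom = int(arr[wlo:whi].sum())
            frac = v / denom if denom else 0.0
            calls.append((int(v), p, frac))
    if not calls:
        return []
    calls.sort(key=lambda c: (-c[0], c[1]))
    modal = calls[0]
    out = [
        TerminusCall(pileup.contig_id, modal[1], strand, side, modal[0], modal[2], False)
    ]
    for support, pos, frac in calls[1:]:
        if frac >= hotspot_fraction:
            out.append(
                TerminusCall(pileup.contig_id, pos, strand, side, support, frac, True)
            )
    return out


def screen_intergenic(
    pileup: ReadPileup,
    features: list,
    min_coverage: int = 1000,
    merge_gap: int = 10,
) -> list[tuple[int, int, str]]:
    """Expressed intergenic intervals: depth >= ``min_coverage`` (inclusive)
    on either strand, outside annotated features, merged within ``merge_gap``.
    """
    genic = np.zeros(pileup.length, dtype=bool)
    for f in features:
        genic[max(0, f.start) : min(pileup.length, f.end)] = True
    out: list[tuple[int, int, str]] = []
    for strand in "+-":
        mask = (pileup.depth[strand] >= min_coverage) & ~genic
        intervals: list[list[int]] = []
        pos = np.flatnonzero(mask)
        for p in pos:
            if intervals and p - intervals[-1][1] <= merge_gap:
                intervals[-1][1] = p + 1
            else:
                intervals.append([int(p), int(p) + 1])
        out.extend((a, b, strand) for a, b in intervals)
    return sorted(out)
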