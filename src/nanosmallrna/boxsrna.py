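"""C/D box and H/ACA box sRNA discovery, classification and guide targets.

C/D box sRNAs are found by motif scanning: box C (RUGAUGA, one mismatch
allowed outside the central GAU core) and box D (CUGA, exact), with internal
C'/D' boxes at relaxed budgets and the compact archaeal geometry
(guide regions of 10-21 nt upstream of each D box).  A genomically inverted
D...C order is reported as a permuted locus when the circularised reading
restores the canonical C-before-D architecture; junction-spanning reads
upgrade a permuted call to circular_permuted.  H/ACA sRNAs are identified
from a maximum-base-pairing fold as two hairpins separated by an ACA hinge.

Target prediction reimplements the standard rules in simplified form:
2'-O-methylation by the D+5 rule over a contiguous antisense duplex, and
pseudouridylation by bipartite pocket pairing flanking an unpaired UN
dinucleotide at the canonical 14-16 nt distance from the ACA box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fold import can_pair, hairpins_from_pairs, nussinov, pair_map
from .model import Feature, GenomeRecord, Read, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "N": "ACGT",
}


@dataclass
class CdParams:
    boxC_pattern: str = "RTGATGA"
    boxC_max_mm: int = 1
    boxC_core: tuple[int, ...] = (2, 3, 4)  # 0-based: the central GAT, exact
    boxD_pattern: str = "CTGA"
    boxD_max_mm: int = 0
    boxCp_max_mm: int = 2
    boxDp_max_mm: int = 1
    span_min: int = 40  # box C end to box D start (canonical)
    span_max: int = 90
    guide_min: int = 10  # region upstream of each D box
    guide_max: int = 21
    dp_cp_gap_max: int = 10
    permuted_gap_max: int = 30  # box D end to box C start in a permuted locus
    max_total_mm: int = 2  # summed box mismatches per candidate
    require_internal: bool = True


@dataclass
class BoxHit:
    start: int  # genomic forward-strand start
    end: int
    sequence: str  # sense
    mismatches: int


@dataclass
class CdBoxSrna:
    srna_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    boxC: BoxHit
    boxD: BoxHit
    boxCp: BoxHit | None
    boxDp: BoxHit | None
    arrangement: str  # canonical / permuted / circular_permuted
    sequence: str = ""  # sense sequence of the locus
    terminal_pairing: int | None = None
    context: str | None = None
    guide_seqs: dict[str, str] = field(default_factory=dict)  # 'D'/'Dp' -> sense seq
    guide_flags: list[str] = field(default_factory=list)
    junction_read_support: int = 0
    circular: bool = False
    circle_length: int | None = None
    total_mismatches: int = 0
    shadowed: bool = False
    wraps_origin: bool = False

    @property
    def unpaired_ends(self) -> bool | None:
        return self.terminal_pairing <= 1 if self.terminal_pairing is not None else None


# ---------------------------------------------------------------------------
# motif scanning


def find_motif(
    seq: str,
    pattern: str,
    max_mm: int,
    exact_positions: tuple[int, ...] = (),
) -> list[tuple[int, int]]:
    """All (position, mismatches) where ``pattern`` (IUPAC) matches ``seq``
    with at most ``max_mm`` mismatches; ``exact_positions`` must match."""
    allowed = [IUPAC[p] for p in pattern]
    k = len(pattern)
    hits = []
    for i in range(len(seq) - k + 1):
        mm = 0
        ok = True
        for p in range(k):
            if seq[i + p] not in allowed[p]:
                if p in exact_positions:
                    ok = False
                    break
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            hits.append((i, mm))
    return hits


def _find_internal(
    s: str, c_end: int, d_start: int, params: CdParams
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Locate box D' then box C' between an outer C...D pair (local coords).

    Geometry: guide1 (10-21 nt) then D', a short spacer (<= dp_cp_gap_max),
    C', then guide2 (10-21 nt) before the outer box D.  Returns the first
    geometry-consistent (D', C') chain with the fewest total mismatches.
    """
    region = s[c_end:d_start]
    dp_hits = find_motif(region, params.boxD_pattern, params.boxDp_max_mm)
    cp_hits = find_motif(
        region, params.boxC_pattern, params.boxCp_max_mm, params.boxC_core
    )
    best = None
    for dp_pos, dp_mm in dp_hits:
        if not (params.guide_min <= dp_pos <= params.guide_max):
            continue
        for cp_pos, cp_mm in cp_hits:
            gap = cp_pos - (dp_pos + len(params.boxD_pattern))
            if not (0 <= gap <= params.dp_cp_gap_max):
                continue
            guide2 = len(region) - (cp_pos + len(params.boxC_pattern))
            if not (params.guide_min <= guide2 <= params.guide_max):
                continue
            cand = (dp_mm + cp_mm, dp_pos, cp_pos, dp_mm, cp_mm)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None, None
    _, dp_pos, cp_pos, dp_mm, cp_mm = best
    return (c_end + dp_pos, dp_mm), (c_end + cp_pos, cp_mm)


def _canonical_candidates(s: str, params: CdParams, require_internal: bool):
    """Canonical C...D candidates on one sense sequence (local coords)."""
    c_hits = find_motif(s, params.boxC_pattern, params.boxC_max_mm, params.boxC_core)
    d_hits = find_motif(s, params.boxD_pattern, params.boxD_max_mm)
    lc, ld = len(params.boxC_pattern), len(params.boxD_pattern)
    out = []
    for c_pos, c_mm in c_hits:
        c_end = c_pos + lc
        best = None
        for d_pos, d_mm in d_hits:
            sep = d_pos - c_end
            if not (params.span_min <= sep <= params.span_max):
                continue
            dp, cp = _find_internal(s, c_end, d_pos, params)
            if require_internal and dp is None:
                continue
            total_mm = c_mm + d_mm + (dp[1] if dp else 0) + (cp[1] if cp else 0)
            if total_mm > params.max_total_mm:
                continue
            cand = {
                "c": (c_pos, c_mm),
                "d": (d_pos, d_mm),
                "dp": dp,
                "cp": cp,
                "start": c_pos,
                "end": d_pos + ld,
                "mm": total_mm,
                "arrangement": "canonical",
            }
            # per box C anchor keep the fewest-mismatch, tightest candidate
            key = (total_mm, d_pos - c_end)
            if best is None or key < best[0]:
                best = (key, cand)
        if best is not None:
            out.append(best[1])
    return out


def _permuted_candidates(s: str, params: CdParams):
    """Permuted loci: genomic order C' ... D ... C ... D'.

    Confirmed by rotating the locus to start at box C and re-checking the
    canonical architecture on the rotated (circularised) reading.
    """
    c_hits = find_motif(s, params.boxC_pattern, params.boxC_max_mm, params.boxC_core)
    d_hits = find_motif(s, params.boxD_pattern, params.boxD_max_mm)
    cp_hits = find_motif(s, params.boxC_pattern, params.boxCp_max_mm, params.boxC_core)
    dp_hits = find_motif(s, params.boxD_pattern, params.boxDp_max_mm)
    lc, ld = len(params.boxC_pattern), len(params.boxD_pattern)
    out = []
    for d_pos, d_mm in d_hits:
        for c_pos, c_mm in c_hits:
            gap = c_pos - (d_pos + ld)
            if not (0 <= gap <= params.permuted_gap_max):
                continue
            # box C' upstream of box D (guide2 geometry)
            cps = [
                (p, mm)
                for p, mm in cp_hits
                if params.guide_min <= d_pos - (p + lc) <= params.guide_max
            ]
            # box D' downstream of box C (guide1 geometry)
            dps = [
                (p, mm)
                for p, mm in dp_hits
                if params.guide_min <= p - (c_pos + lc) <= params.guide_max
            ]
            best = None
            for cp_pos, cp_mm in cps:
                for dp_pos, dp_mm in dps:
                    if c_mm + d_mm + cp_mm + dp_mm > params.max_total_mm:
                        continue
                    start, end = cp_pos, dp_pos + ld
                    w = s[start:end]
                    rot_at = c_pos - start
                    rot = w[rot_at:] + w[:rot_at]
                    if not _canonical_candidates(rot, params, True):
                        continue
                    cand = {
                        "c": (c_pos, c_mm),
                        "d": (d_pos, d_mm),
                        "dp": (dp_pos, dp_mm),
                        "cp": (cp_pos, cp_mm),
                        "start": start,
                        "end": end,
                        "mm": c_mm + d_mm + cp_mm + dp_mm,
                        "arrangement": "permuted",
                    }
                    # per anchor pair keep the chain with the fewest box
                    # mismatches, then the tightest span
                    key = (cand["mm"], end - start)
                    if best is None or key < best[0]:
                        best = (key, cand)
            if best is not None:
                out.append(best[1])
    return out


def _to_genomic(pos: int, length: int, strand: str, n: int) -> tuple[int, int]:
    """Map a local sense position to a forward-strand genomic interval."""
    if strand == "+":
        return pos, pos + length
    return n - (pos + length), n - pos


def _box_hit(cand_box, s: str, strand: str, n: int, box_len: int) -> BoxHit:
    pos, mm = cand_box
    g = _to_genomic(pos, box_len, strand, n)
    return BoxHit(g[0], g[1], s[pos : pos + box_len], mm)


def scan_cd(
    genome: GenomeRecord,
    params: CdParams | None = None,
    regions: list[tuple[int, int, str]] | None = None,
    require_internal: bool | None = None,
) -> list[CdBoxSrna]:
    """Scan for C/D box sRNAs on both strands.

    Genome-wide scans require the full C/D'/C'/D architecture (the default
    stringency that keeps the false-positive rate on random sequence low);
    when explicit candidate ``regions`` (start, end, strand) are given --
    expressed intergenic intervals, annotated tRNA introns -- the internal
    boxes become optional.  Overlapping candidates are resolved by total box
    mismatches; losers are returned with ``shadowed=True``.
    """
    params = params or CdParams()
    n = genome.length
    lc, ld = len(params.boxC_pattern), len(params.boxD_pattern)
    results: list[CdBoxSrna] = []

    if regions is None:
        req = params.require_internal if require_internal is None else require_internal
        wrap = min(200, n) if genome.is_circular else 0
        scan_list = [(0, n + wrap, st) for st in "+-"]
    else:
        req = False if require_internal is None else require_internal
        wrap = 0
        scan_list = [(a, b, st) for a, b, st in regions]

    seen: set[tuple[int, int, str]] = set()
    for a, b, strand in scan_list:
        if wrap:
            fwd = genome.sequence + genome.sequence[: wrap]
        else:
            fwd = genome.sequence[a:b]
        s = revcomp(fwd) if strand == "-" else fwd
        cands = _canonical_candidates(s, params, req)
        cands += _permuted_candidates(s, params)
        seg_len = len(fwd)
        for cand in cands:
            # map local (sense) coords back to forward-strand genomic coords
            if strand == "+":
                g_start, g_end = a + cand["start"], a + cand["end"]
            else:
                g_start = a + (seg_len - cand["end"])
                g_end = a + (seg_len - cand["start"])
            wraps = False
            if wrap and g_end > n:
                if g_start >= n:
                    continue  # duplicate of an unwrapped hit
                wraps = True
            key = (g_start % n, g_end % n if wraps else g_end, strand)
            if key in seen:
                continue
            seen.add(key)

            srna_seq = s[cand["start"] : cand["end"]]
            boxes = {}
            for name, blen in (("c", lc), ("d", ld), ("cp", lc), ("dp", ld)):
                cb = cand[name]
                if cb is None:
                    boxes[name] = None
                    continue
                pos, mm = cb
                if strand == "+":
                    gs = a + pos
                    ge = gs + blen
                else:
                    gs = a + (seg_len - (pos + blen))
                    ge = a + (seg_len - pos)
                if wrap:
                    gs = gs % n
                    ge = gs + blen
                boxes[name] = BoxHit(gs, ge, s[pos : pos + blen], mm)
            srna = CdBoxSrna(
                srna_id="",
                contig_id=genome.contig_id,
                start=g_start % n if wrap else g_start,
                end=g_end,  # may exceed contig length for origin-spanning hits
                strand=strand,
                boxC=boxes["c"],
                boxD=boxes["d"],
                boxCp=boxes["cp"],
                boxDp=boxes["dp"],
                arrangement=cand["arrangement"],
                sequence=srna_seq,
                total_mismatches=cand["mm"],
                wraps_origin=wraps,
            )
            srna.terminal_pairing = check_terminal_pairing(srna_seq)
            _attach_guides(srna, cand, s, params)
            results.append(srna)

    # overlap resolution: fewest mismatches wins, then the tighter geometry
    results.sort(key=lambda r: (r.total_mismatches, r.end - r.start, r.start))
    kept: list[CdBoxSrna] = []
    for r in results:
        clash = any(
            k.strand == r.strand and k.start < r.end and r.start < k.end for k in kept
        )
        r.shadowed = clash
        if not clash:
            kept.append(r)
    final = sorted(results, key=lambda r: (r.start, r.end, r.strand))
    for i, r in enumerate([x for x in final if not x.shadowed], start=1):
        r.srna_id = f"cd_srna_{i}"
    return final


def _attach_guides(srna: CdBoxSrna, cand: dict, s: str, params: CdParams) -> None:
    """Guide regions: up to guide_max nt immediately upstream of D and D'."""
    lc, ld = len(params.boxC_pattern), len(params.boxD_pattern)
    anchors = {"D": cand["d"], "Dp": cand["dp"]}
    floors = {
        "D": (cand["cp"][0] + lc) if cand["cp"] else cand["c"][0] + lc,
        "Dp": (cand["c"][0] + lc) if cand["dp"] else None,
    }
    for name, box in anchors.items():
        if box is None:
            continue
        d_pos = box[0]
        floor = floors[name]
        lo = max(floor if floor is not None else 0, d_pos - params.guide_max)
        guide = s[lo:d_pos]
        if len(guide) < params.guide_min:
            srna.guide_flags.append(f"{name}:truncated")
            continue
        srna.guide_seqs[name] = guide


def check_terminal_pairing(seq: str, k: int = 6) -> int:
    """Antiparallel complementary pairs between the first and last ``k`` nt.

    Position i from the 5' end is tested against position i from the 3' end
    (WC and GU both count).  A count <= 1 is reported as "unpaired ends",
    the configuration expected for box C/D sRNAs whose termini are held
    apart by the k-turn rather than a terminal stem.
    """
    head, tail = seq[:k], seq[-k:]
    return sum(1 for a, b in zip(head, tail[::-1]) if can_pair(a, b))


# ---------------------------------------------------------------------------
# circularity


def detect_circular(
    srna: CdBoxSrna,
    reads: list[Read],
    min_support: int = 5,
    min_part: int = 12,
) -> CdBoxSrna:
    """Count reads spanning a head-to-tail circularisation junction.

    A junction read carries the locus 3' end followed by its 5' start; the
    test requires an exact match of at least ``min_part`` nt on each side of
    the junction.  A permuted locus with sufficient support becomes
    ``circular_permuted`` -- its circular reading restores the canonical
    C-before-D box order (verified at scan time).
    """
    locus = srna.sequence
    m = len(locus)
    if m < 2 * min_part:
        return srna
    max_read = max((len(r) for r in reads), default=0)
    tail = locus[-min(m, max_read) :]
    head = locus[: min(m, max_read)]
    junction = len(tail)
    j_seq = tail + head
    support = 0
    for read in reads:
        for seq in (read.sequence, revcomp(read.sequence)):
            pos = j_seq.find(seq)
            hit = False
            while pos != -1:
                left = junction - pos
                right = len(seq) - left
                if left >= min_part and right >= min_part:
                    hit = True
                    break
                pos = j_seq.find(seq, pos + 1)
            if hit:
                support += 1
                break
    srna.junction_read_support = support
    srna.circular = support >= min_support
    if srna.circular:
        srna.circle_length = m
        if srna.arrangement == "permuted":
            srna.arrangement = "circular_permuted"
    return srna


# ---------------------------------------------------------------------------
# genomic context


def classify_context(
    srna: CdBoxSrna,
    features: list[Feature],
    dicistronic_gap: int = 5,
    split_flank: int = 100,
) -> str:
    """Genomic-context label, tested in priority order.

    tRNA_intronic > tRNA_dicistronic (RNase Z processing of a tRNA-sRNA
    precursor generates the sRNA 5' end) > split_gene_flank > mRNA_overlap >
    standalone.
    """
    s, e = srna.start, srna.end
    for f in features:
        if f.kind == "tRNA_intron" and f.start <= s and e <= f.end:
            srna.context = "tRNA_intronic"
            return srna.context
    for f in features:
        if f.kind != "tRNA" or f.strand != srna.strand:
            continue
        gap = (s - f.end) if srna.strand == "+" else (f.start - e)
        if 0 <= gap <= dicistronic_gap:
            srna.context = "tRNA_dicistronic"
            return srna.context
    for f in features:
        if f.attributes.get("split_part") in ("N_terminal", "C_terminal"):
            gap = max(f.start - e, s - f.end)
            if gap <= split_flank:
                srna.context = "split_gene_flank"
                return srna.context
    for f in features:
        if f.kind == "gene" and f.overlaps(s, e):
            srna.context = "mRNA_overlap"
            return srna.context
    srna.context = "standalone"
    return srna.context


# ---------------------------------------------------------------------------
# 2'-O-methylation targets (D+5 rule)


@dataclass
class TargetPrediction:
    srna_id: str
    guide_source: str  # D / Dp / pocket1 / pocket2
    target_rna: str
    target_position: int  # 0-based in the target
    duplex_len: int
    n_gu: int
    modification: str  # 2pOme / pseudouridine


def predict_2ome_targets(
    srna: CdBoxSrna,
    rrnas: list[GenomeRecord],
    min_duplex: int = 10,
) -> list[TargetPrediction]:
    """Scan rRNAs for contiguous antisense duplexes to each guide region.

    The methylated nucleotide is the target base paired to the guide
    nucleotide five positions upstream of the associated D box (D+5 rule);
    only duplexes of >= ``min_duplex`` contiguous pairs (GU allowed) that
    cover that guide position qualify.  Results are ranked by duplex length,
    then fewest GU pairs.
    """
    preds: list[TargetPrediction] = []
    for source, guide in sorted(srna.guide_seqs.items()):
        g = guide
        lg = len(g)
        anchor = lg - 5  # guide base 5 nt upstream of the D box
        if anchor < 0:
            continue
        for rrna in rrnas:
            r = rrna.sequence
            for t in range(len(r) - lg + 1):
                # antiparallel: g[i] pairs r[t + lg - 1 - i]
                paired = [can_pair(g[i], r[t + lg - 1 - i]) for i in range(lg)]
                if not paired[anchor]:
                    continue
                lo = anchor
                while lo > 0 and paired[lo - 1]:
                    lo -= 1
                hi = anchor
                while hi < lg - 1 and paired[hi + 1]:
                    hi += 1
                run = hi - lo + 1
                if run < min_duplex:
                    continue
                n_gu = sum(
                    1
                    for i in range(lo, hi + 1)
                    if (g[i], r[t + lg - 1 - i]) in {("G", "T"), ("T", "G")}
                )
                preds.append(
                    TargetPrediction(
                        srna_id=srna.srna_id,
                        guide_source=source,
                        target_rna=rrna.contig_id,
                        target_position=t + lg - 1 - anchor,
                        duplex_len=run,
                        n_gu=n_gu,
                        modification="2pOme",
                    )
                )
    preds.sort(key=lambda p: (-p.duplex_len, p.n_gu, p.target_rna, p.target_position))
    return preds


# ---------------------------------------------------------------------------
# H/ACA sRNAs


@dataclass
class HacaSrna:
    srna_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    hairpins: list[tuple[int, int]]  # local sense coords
    hinge_aca: int | None  # local position of the hinge ACA
    terminal_aca: int | None
    kturn_flags: list[bool]
    pockets: list[tuple[tuple[int, int], tuple[int, int]] | None]  # (5'arm, 3'arm)
    h_domain_status: str  # canonical_ANANNA / ACA_only


def _find_kturn(seq: str, partner: list[int], span: tuple[int, int]) -> bool:
    """Heuristic k-turn test inside one hairpin.

    Looks for a stem pair (i, j) whose 5' strand continues with GA and whose
    3' strand is preceded by AG (the tandem sheared G.A pairs), with a short
    (<= 8 nt total) bulged region before the next stacked pair -- the
    geometry of the canonical kink-turn.
    """
    lo, hi = span
    for i in range(lo, hi):
        j = partner[i]
        if j <= i or not (lo <= j < hi):
            continue
        if seq[i + 1 : i + 3] == "GA" and seq[j - 2 : j] == "AG":
            for i2 in range(i + 3, min(i + 9, hi)):
                j2 = partner[i2]
                if j2 > i2 and j2 <= j - 3 and (i2 - i - 1) + (j - j2 - 1) <= 8:
                    return True
    return False


def _find_pocket(
    partner: list[int], stem: list[tuple[int, int]]
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Largest internal loop (>= 3 unpaired nt on both strands) in a stem."""
    best = None
    for (a, b), (a2, b2) in zip(stem, stem[1:]):
        left = a2 - a - 1
        right = b - b2 - 1
        if left >= 3 and right >= 3:
            size = left + right
            if best is None or size > best[0]:
                best = (size, (a + 1, a2), (b2 + 1, b))
    if best is None:
        return None
    return best[1], best[2]


def find_haca(
    regions: list[tuple[int, int, str]],
    genome: GenomeRecord,
    min_hairpin_span: int = 25,
    min_hairpin_pairs: int = 5,
) -> list[HacaSrna]:
    """Identify two-hairpin H/ACA box sRNAs in candidate regions.

    Each region is folded by pairing maximisation; a candidate qualifies
    when exactly two ordered hairpin domains of >= ``min_hairpin_span`` nt
    emerge and an ACA motif sits directly 3' of hairpin 1 (the hinge) and/or
    three nt from the 3' end.  The H-domain status records whether the hinge
    is a full ANANNA H box or a bare ACA.
    """
    out: list[HacaSrna] = []
    for a, b, strand in regions:
        seq = genome.fetch(a, b)
        if strand == "-":
            seq = revcomp(seq)
        pairs = nussinov(seq)
        hp = hairpins_from_pairs(pairs, min_hairpin_span, min_hairpin_pairs)
        if len(hp) != 2:
            continue
        partner = pair_map(pairs, len(seq))
        (h1s, h1e, stem1), (h2s, h2e, stem2) = hp
        hinge = seq[h1e : h1e + 3]
        hinge_aca = h1e if hinge == "ACA" else None
        term_aca = len(seq) - 6 if seq[len(seq) - 6 : len(seq) - 3] == "ACA" else None
        if hinge_aca is None and term_aca is None:
            continue
        hinge_region = seq[h1e:h2s]
        if (
            len(hinge_region) >= 6
            and hinge_region[0] == "A"
            and hinge_region[2] == "A"
            and hinge_region[5] == "A"
        ):
            status = "canonical_ANANNA"
        else:
            status = "ACA_only"
        out.append(
            HacaSrna(
                srna_id=f"haca_srna_{len(out) + 1}",
                contig_id=genome.contig_id,
                start=a,
                end=b,
                strand=strand,
                sequence=seq,
                hairpins=[(h1s, h1e), (h2s, h2e)],
                hinge_aca=hinge_aca,
                terminal_aca=term_aca,
                kturn_flags=[
                    _find_kturn(seq, partner, (h1s, h1e)),
                    _find_kturn(seq, partner, (h2s, h2e)),
                ],
                pockets=[
                    _find_pocket(partner, stem1),
                    _find_pocket(partner, stem2),
                ],
                h_domain_status=status,
            )
        )
    return out


def predict_psi_targets(
    haca: HacaSrna,
    rrnas: list[GenomeRecord],
    min_arm: int = 4,
    max_arm: int = 8,
    aca_distance: tuple[int, int] = (14, 16),
) -> list[TargetPrediction]:
    """Pseudouridylation targets by bipartite pocket pairing.

    For each hairpin pocket the target U must be flanked by an unpaired UN
    dinucleotide: the bases 5' of the U pair antiparallel into the pocket's
    3' arm and the bases 3' of the UN pair into the 5' arm, each with
    ``min_arm``-``max_arm`` contiguous pairs.  The pocket midpoint must lie
    14-16 nt upstream of the hairpin's ACA motif on the sRNA.
    """
    preds: list[TargetPrediction] = []
    acas = [haca.hinge_aca, haca.terminal_aca]
    for h_idx, pocket in enumerate(haca.pockets):
        if pocket is None:
            continue
        aca = acas[h_idx] if acas[h_idx] is not None else haca.terminal_aca
        if aca is None:
            continue
        (l1, l2), (r1, r2) = pocket
        d = aca - (r1 + r2) // 2
        if not (aca_distance[0] <= d <= aca_distance[1]):
            continue
        left_arm = haca.sequence[l1:l2]
        right_arm = haca.sequence[r1:r2]
        for rrna in rrnas:
            r = rrna.sequence
            for u in range(max_arm, len(r) - max_arm - 1):
                if r[u] != "T":
                    continue
                # 5' of U pairs the pocket 3' arm: r[u-t] vs right_arm[t-1]
                k1 = 0
                while (
                    k1 < min(max_arm, len(right_arm), u)
                    and can_pair(r[u - (k1 + 1)], right_arm[k1])
                ):
                    k1 += 1
                # 3' of UN pairs the pocket 5' arm: r[u+2+t] vs left_arm[-1-t]
                k2 = 0
                while (
                    k2 < min(max_arm, len(left_arm), len(r) - (u + 2))
                    and can_pair(r[u + 2 + k2], left_arm[len(left_arm) - 1 - k2])
                ):
                    k2 += 1
                if k1 >= min_arm and k2 >= min_arm:
                    preds.append(
                        TargetPrediction(
                            srna_id=haca.srna_id,
                            guide_source=f"pocket{h_idx + 1}",
                            target_rna=rrna.contig_id,
                            target_position=u,
                            duplex_len=k1 + k2,
                            n_gu=0,
                            modification="pseudouridine",
                        )
                    )
    preds.sort(key=lambda p: (-p.duplex_len, p.target_rna, p.target_position))
    return preds
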