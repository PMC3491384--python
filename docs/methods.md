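# Methods

This note documents the models, rules and numerical choices behind
`nanosmallrna`, and what the synthetic scenarios do and do not emulate.

## Coordinates and formats

All internal intervals are 0-based half-open on the forward strand;
minus-strand features keep forward coordinates with a strand flag.
Conversion to 1-based inclusive coordinates happens only at the GFF3
boundary. A read's biological 5′/3′ ends are base positions (`start` /
`end − 1` on `+`, mirrored on `−`), not half-open bounds. Circular
contigs are supported in the genome scanners by evaluating an
origin-wrapped window (200 nt) and reporting wrapped hits with unwrapped
end coordinates plus a flag.

## Read preprocessing

Adapter removal is an ungapped best suffix match (≥ 90 % identity over
≥ 8 nt) against the configured adapter set; a trailing poly-A run of
≥ `polyA_min_run` (default 6) is removed; quality trimming uses the
modified-Mott algorithm: each base contributes `limit − p_err`
(limit 0.05) and the maximum-sum contiguous segment is kept. Reads
shorter than 15 nt are discarded and counted.

## Micro-mapper

A seed-and-extend aligner for genomes ≤ 16 Mb. Exact k-mer seeds
(k = 12, lowered to ⌊read/3⌋, minimum 6, for short reads so that two
edits still leave an exact seed) nominate diagonals; each candidate is
scored by a banded (band 8) semi-global alignment with edit costs
mismatch 2, insertion 3, deletion 3 and free genome-side end gaps. A
placement is accepted when identity (matches / alignment columns)
≥ 0.8. Full-length exact matches short-circuit the DP. The mapper aligns
the entire read — there is no soft clipping — so the `length_fraction`
parameter of the configuration is retained for completeness but the
identity threshold is what rejects partial matches (e.g. circle-junction
reads, which are deliberately left unmapped and handled by the dedicated
junction test). Cost ties are resolved by `multimap_policy`; the default
`random_best_seeded` places the read at one of its best hits using the
run seed, which preserves coverage inside identical CRISPR repeats and
duplicated leader regions while keeping runs reproducible. On small
genomes the accepted placements and costs equal an exhaustive
full-matrix alignment oracle (tested).

## Pileups and termini

Per contig and strand the pipeline keeps depth, 5′-end and 3′-end count
arrays; conservation (Σ five-prime ends = Σ three-prime ends = mapped
reads) is asserted on construction. Terminus calling returns all local
maxima of the end-count array with support ≥ 2; the global maximum is
the modal terminus and secondary maxima are flagged as trimming hotspots
when they hold ≥ 10 % of the termini within ±10 nt (`local_fraction`
uses termini within the window as its denominator). Coordinate ties
break towards the smaller genomic position; the TSS caller breaks ties
upstream-most on the transcript strand.

## CRISPR arrays and crRNA maturation

Detection chains exact 12-mer self-matches whose spacing is consistent
with a repeat period (repeat 20–50 nt, spacer 17–50 nt; spacers up to
1.5× the maximum are tolerated and flagged `long_spacer`, since real
arrays contain one markedly longer spacer). Repeat boundaries are
refined column-wise: a flanking column joins the repeat while ≥ 90 % of
copies agree on the majority base. All candidate chains are collected
and overlaps resolved in favour of more repeats, then longer span — a
chain seeded off-register (flanking bases coincide across a few copies)
covers only part of an array and must not claim it.

Orientation uses reads when available (≥ 90 % strand majority over the
array span) and otherwise falls back to the AT-richer flank as the
leader side; the method used is recorded and conflicts flagged.

Maturation statistics per spacer: read count, relative abundance
(normalised within the array), the 5′ tag length as the modal distance
from read 5′ ends to the spacer start constrained to lie within the
repeat, the 3′-end offset distribution relative to the spacer 3′ end,
and trimming hotspots from the terminus caller. The array-level tag
pools all spacers; the tag sequence is read from the repeat consensus
suffix, so it is a consensus suffix by construction. Offsets follow the
convention `first_repeat_start − tss = 33` ⇒ the TSS sits 33 nt upstream
of the repeat. Box A is the best Hamming match to TTTAAA within
[−35, −20] of the TSS (≤ 1 mismatch), ties resolved towards the
canonical −26 spacing. Leader identity between two arrays is the exact
common prefix walking upstream from each first repeat, strand-aware.

## tRNA halves

Clamp extraction takes the 40-nt intron-side flank (downstream of a 5′
half, upstream of a 3′ half, in transcript sense) and trims it at the
first run of ≥ 5 T (the polypyrimidine terminator). When the annotation
provides a `clamp_len` attribute it overrides the heuristic; this
matters because templated precursor extensions upstream of a 3′-half
clamp would otherwise be absorbed into the extracted clamp and the
+2/+1/−1 terminus offsets would become unmeasurable. Clamps with GC
fraction < 0.5 are flagged, not rejected.

Pair scoring is the best contiguous antiparallel duplex between two
clamps (WC = 1, G·U = 0.5, configurable); assignment is the exact
maximum-weight bipartite matching (Hungarian algorithm), pairs with a
best run < 8 nt are rejected, and a pair is flagged ambiguous when
another partner ties its score. Mature tRNAs are the concatenated half
bodies (sanity bounds 70–100 nt, junction recorded). Precursor termini
are modal 5′/3′ calls per half with offsets against body and clamp
boundaries; `clamp_side_offset` is signed in transcript sense (+2 =
two templated bases beyond the clamp). The leaderless report gives, per
tRNA gene, the fraction of 5′ ends exactly at the mature start, the
start base and purine flag, and the −1 test (fraction of reads starting
one base upstream plus the templated base identity).

## C/D box sRNAs

Box patterns: box C = RUGAUGA with ≤ 1 mismatch outside the central GAU
(positions 3–5, always exact), box D = CUGA exact; internal C′/D′ use
relaxed budgets (≤ 2 / ≤ 1). Canonical geometry: guide regions of
10–21 nt upstream of D′ and D, a D′→C′ spacer of ≤ 10 nt, and a total
box C→box D separation of 40–90 nt. Genome-wide scans require the full
C/D′/C′/D architecture and a total mismatch budget of ≤ 2: box C + box D
alone would produce on the order of 50 chance hits per 100 kb of random
sequence, while the full architecture keeps the measured false-positive
rate below 1 per 100 kb (tested over 400 kb of random sequence). Scans
of explicit candidate regions (annotated tRNA introns, expressed
intergenic intervals) drop the internal-box requirement, which is what
admits the intronic sRNA whose box C carries the naturally occurring
T→G substitution. Per box C anchor only the fewest-mismatch, tightest
candidate is kept, and overlapping candidates resolve to fewest
mismatches then tightest geometry; displaced candidates are returned
with a `shadowed` flag.

A permuted locus (genomic order C′ … D … C … D′) is reported when an
exact box D is followed by a box C within 30 nt and the flanking
C′ (upstream of D) and D′ (downstream of C) complete the geometry; the
call is confirmed by rotating the locus to start at box C and
re-checking the full canonical architecture on the rotated reading —
exactly the "circular reading restores C before D" argument. Note that
a permuted locus whose internal boxes were *perfect* would be
architecture-isomorphic to a canonical one; real internal boxes are
degenerate, and the scanner relies on the outer box D being exact.

Terminal pairing counts antiparallel complementary pairs (WC + GU)
between the first and last 6 nt; ≤ 1 is classified "unpaired ends", the
expected configuration for C/D sRNAs. Circularity is called from reads
whose sequence spans a head-to-tail junction of the locus with ≥ 12 nt
exact match on each side; ≥ 5 junction reads set the circular flag, and
a circular permuted locus is promoted to `circular_permuted`. Context
classification tests, in priority order: inside an annotated tRNA
intron; ≤ 5 nt downstream of a same-strand tRNA (the RNase Z
dicistronic case); within 100 nt of a split-gene part (annotation
attribute `split_part`); overlapping a gene; standalone.

2′-O-methylation targets follow the D+5 rule: for each guide region the
rRNAs are scanned for a contiguous antisense duplex (GU allowed) of
≥ 10 nt covering the guide base five positions upstream of the D box;
the methylated nucleotide is the target base paired to that guide base.
Predictions are ranked by duplex length, then fewest GU pairs.

## RNA folding and H/ACA sRNAs

Secondary structure uses Nussinov pairing maximisation (WC + GU, minimum
loop 3). Because the maximum pair count is highly degenerate, the
recurrence adds an infinitesimal stacking bonus (total < 1, so the pair
count is still the exact maximum — verified against a brute-force
oracle); among co-optimal structures this selects helical ones, without
which hairpin decomposition would fail. Hairpins are grown from each
terminal loop through enclosing pairs that enclose only that loop; a
candidate region is an H/ACA sRNA when exactly two ordered hairpins of
≥ 25 nt (≥ 5 stem pairs) emerge and an ACA motif sits directly 3′ of
hairpin 1 (hinge) and/or 3 nt from the 3′ end. The H-domain status
records whether the hinge is a full ANANNA box or a bare ACA. K-turns
are flagged heuristically: a stem pair continued by GA on the 5′ strand
and preceded by AG on the 3′ strand, with a ≤ 8-nt bulged region before
the next stacked pair. The pocket is the largest internal loop (≥ 3 nt
unpaired on both strands). Pseudouridylation targets require the target
U's 5′ flank to pair 4–8 nt into the pocket's 3′ arm and the bases 3′ of
the unpaired UN to pair into the 5′ arm, with the pocket midpoint
14–16 nt upstream of the hairpin's ACA motif — a deliberately simplified
geometric stand-in for thermodynamic co-folding tools.

## Synthetic scenarios

The default scenario (seed 42) plants, in a 50 kb uniform-random
background: two same-strand CRISPR arrays (21 + 20 distinct spacers of
35–44 nt plus one 60-nt spacer, 28-nt repeat ending ATTGAAAG, leaders
identical for exactly 130 nt with the TSS adenosine at −33 and a clean
TTTAAA at −27, competing near-hexamers sanitised away); six tRNA-half
pairs with mutually distinct GC-rich 12-nt clamps (~80 % G/C; cross-pair
duplex runs < 6 nt) and T-stretch terminators, three 3′ halves carrying
+2 (GC), +1 (A) and −1 (A) terminus offsets, one pair on the minus
strand; three ordinary leaderless tRNAs, a tRNA-Tyr with a templated
G−1 (90 % of reads), and an intron-bearing tRNA-Met whose 66-nt intron
holds a C/D sRNA with the T→G box C variant and a 6-bp GC hairpin; C/D
sRNA loci for every context class, one of them permuted and circular and
one canonical circle; a designed two-hairpin H/ACA sRNA; and a 300-nt
rRNA with planted 2′-O-me and Ψ target sites. C/D guides and flanks are
rejection-sampled so the planted locus is the unique
architecture-consistent reading of its own sequence, and the internal
D′ carries one mismatch so canonical and permuted readings stay
distinguishable (see above).

The H/ACA cassette is T-free with pure-A pockets, loops and spacers and
G/C stems of opposite arm polarity between the two hairpins, which makes
the designed fold the strict pairing maximum — every alternative pairing
either crosses designed stem pairs or ties and loses to the stacking
preference. This is a designed property, not typical of real H/ACA
sequences, and it is what makes fold-based detection deterministic at
desk scale.

Reads are drawn per transcript with Poisson counts: crRNAs decay 0.8×
per spacer position from depth 100 at the leader-proximal spacer and
carry the 8-nt tag plus a geometrically trimmed (p = 0.25) 3′ repeat
tail; 50 pre-crRNA reads per array start at the TSS; tRNA-class
transcripts are suppressed by an exponential factor e^(−0.02·length)
standing in for reverse-transcriptase drop-off on structured, modified
RNA (so tRNA counts sit well below sRNA counts, as in real libraries);
C/D sRNAs get 10× depth (≈ 1000 reads each, a scaled-down echo of the
thousands of reads per sRNA in real data); circles emit 50
junction-spanning reads; substitution errors occur at 0.1 % per base
with flat Q30 qualities. About 9,000 reads result, and the full pipeline
runs in a few seconds.

What the generator does **not** emulate: sequencing-quality decay,
indel errors, ligation/RT sequence bias, paired ends, rRNA-dominated
library composition, expression noise between loci of one class, and
genuinely ambiguous motif landscapes (guides are sanitised against
competing box hits). Passing the recovery tests therefore demonstrates
correctness of the inference rules under the stated processing model,
not robustness to every artefact of real libraries.

## Problem sizes used in tests

The flagship integration uses the full default scenario (50 kb, ~9,000
reads). The oracle suites run on 0.6–5 kb random sequences, reads of
18–50 nt, folds ≤ 40 nt, and matchings ≤ 6×6. The statistical suite uses
20 seeds of a reduced arrays-only scenario (20 kb, 8 + 7 spacers, depth
50) for decay recovery, and 20 × 20 kb of random sequence for the
false-positive bound; the per-spacer decay check requires pipeline
counts to match the planted library within ±3 reads and allows the
planted Poisson draws themselves to exceed the 3σ band of the decay
model in at most ~1 % of draws (the expected tail fraction across 300
draws).

## Known limitations

- The mapper has no soft clipping and no paired-end or spliced-alignment
  support; junction reads are intentionally handled outside it.
- Pairing maximisation is not free energy: on real sequences co-optimal
  and near-optimal structures abound, and H/ACA detection is
  correspondingly less reliable than with a thermodynamic folder.
- Target prediction is rule-based (duplex length and geometry only), with
  no energy model or multiple-site statistics; it is labelled a
  simplified rule wherever surfaced.
- The sRNA numbering in reports is coordinate-sorted and need not match
  any external numbering of the same loci.
- Real-data scale: the micro-mapper is pure Python and appropriate for
  sub-Mb genomes at desk-scale read counts, not for tens of millions of
  reads.
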