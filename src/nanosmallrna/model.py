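"""Core domain types and coordinate conventions.

All genomic intervals are 0-based half-open on the forward strand.
Minus-strand features keep forward-strand ``start < end`` coordinates and
carry a ``strand`` flag; conversion to the 1-based inclusive GFF3 convention
happens only at the I/O boundary (:mod:`nanosmallrna.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: feature kinds understood by the pipeline
FEATURE_KINDS = (
    "gene",
    "tRNA",
    "tRNA_half",
    "tRNA_intron",
    "rRNA",
    "CRISPR_array",
    "CD_sRNA",
    "HACA_sRNA",
    "leader",
    "other",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def is_purine(base: str) -> bool:
    return base.upper() in ("A", "G")


@dataclass
class GenomeRecord:
    """A contig: sequence plus circularity flag.

    The sequence is uppercase DNA over {A,C,G,T,N}; ``length`` always equals
    ``len(sequence)``.
    """

    contig_id: str
    sequence: str
    is_circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"contig {self.contig_id}: non-nucleotide characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Forward-strand subsequence; wraps across the origin when circular."""
        n = self.length
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if not self.is_circular:
            raise IndexError(
                f"interval [{start},{end}) outside linear contig {self.contig_id}"
            )
        start %= n
        end %= n
        if start < end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]


@dataclass
class Feature:
    """A typed genomic interval with free-form attributes."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' (unset, e.g. unoriented CRISPR array)
    kind: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.feature_id}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def sequence(self, genome: GenomeRecord) -> str:
        """Sense-strand sequence of the feature."""
        s = genome.fetch(self.start, self.end)
        return revcomp(s) if self.strand == "-" else s


@dataclass
class Read:
    """An unaligned sequencing read."""

    read_id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.read_id}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MappedRead:
    """A read placement on the forward-strand coordinate system.

    ``start``/``end`` are 0-based half-open.  The biological 5' end is
    ``start`` on '+' and ``end - 1`` on '-'; the 3' end is ``end - 1`` on '+'
    and ``start`` on '-'.
    """

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    edit_cost: float = 0.0
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"mapped read {self.read_id}: empty interval")
        if self.edit_cost < 0:
            raise ValueError(f"mapped read {self.read_id}: negative edit cost")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start
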