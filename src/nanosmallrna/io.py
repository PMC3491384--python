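"""Readers and writers for the standard formats used by the pipeline.

FASTA/FASTQ go through Bio.SeqIO; SAM input goes through pysam.  GFF3 is the
only annotation interchange format: 1-based inclusive on disk, converted to
the internal 0-based half-open convention on read.
"""

from __future__ import annotations

import json
import os
import urllib.parse
from typing import Iterable

import pysam
from Bio import SeqIO

from .model import Feature, GenomeRecord, MappedRead, Read

# GFF3 type column -> internal feature kind.  Unlisted types map to "other".
GFF_TYPE_TO_KIND = {
    "gene": "gene",
    "CDS": "gene",
    "mRNA": "gene",
    "tRNA": "tRNA",
    "tRNA_half": "tRNA_half",
    "tRNA_intron": "tRNA_intron",
    "intron": "tRNA_intron",
    "rRNA": "rRNA",
    "CRISPR_array": "CRISPR_array",
    "repeat_region": "CRISPR_array",
    "CD_sRNA": "CD_sRNA",
    "C_D_box_snoRNA": "CD_sRNA",
    "HACA_sRNA": "HACA_sRNA",
    "H_ACA_box_snoRNA": "HACA_sRNA",
    "leader": "leader",
    "sequence_feature": "other",
}
KIND_TO_GFF_TYPE = {
    "gene": "gene",
    "tRNA": "tRNA",
    "tRNA_half": "tRNA_half",
    "tRNA_intron": "tRNA_intron",
    "rRNA": "rRNA",
    "CRISPR_array": "CRISPR_array",
    "CD_sRNA": "CD_sRNA",
    "HACA_sRNA": "HACA_sRNA",
    "leader": "leader",
    "other": "sequence_feature",
}


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


def read_fasta(path: str) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is transliterated to T so RNA FASTA files
    are accepted transparently.
    """
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        try:
            records.append(GenomeRecord(rec.id, seq))
        except ValueError as exc:
            raise FormatError(f"{path}: record {rec.id}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = rec.letter_annotations.get("phred_quality")
        reads.append(Read(rec.id, str(rec.seq).upper(), list(quals) if quals else None))
    return reads


def write_fastq(reads: Iterable[Read], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else [30] * len(r)
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qstr}\n")


def _esc(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" :/+_.|-")


def read_gff3(path: str) -> list[Feature]:
    """Parse GFF3 into internal features (0-based half-open coordinates)."""
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i > end_i:
                raise FormatError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            attributes: dict[str, str] = {}
            for item in attrs.split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attributes[key.strip()] = urllib.parse.unquote(value)
            fid = attributes.pop("ID", f"feature_{lineno}")
            kind = GFF_TYPE_TO_KIND.get(ftype, "other")
            if kind == "other" and ftype in GFF_TYPE_TO_KIND.values():
                kind = ftype
            features.append(
                Feature(fid, contig, start_i - 1, end_i, strand, kind, attributes)
            )
    return features


def write_gff3(features: Iterable[Feature], path: str) -> None:
    """Write features as GFF3 (sorted by contig, start; deterministic)."""
    feats = sorted(features, key=lambda f: (f.contig_id, f.start, f.end, f.feature_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            attrs = ";".join(
                [f"ID={_esc(f.feature_id)}"]
                + [f"{k}={_esc(v)}" for k, v in sorted(f.attributes.items())]
            )
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "nanosmallrna",
                        KIND_TO_GFF_TYPE[f.kind],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_sam(path: str) -> list[MappedRead]:
    """Read pre-mapped reads from a (text) SAM file."""
    mapped = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            mapped.append(
                MappedRead(
                    read_id=aln.query_name,
                    contig_id=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    edit_cost=float(aln.get_tag("AS")) if aln.has_tag("AS") else 0.0,
                    is_unique=aln.mapping_quality > 0,
                )
            )
    return mapped


def write_sam(
    mapped: Iterable[MappedRead], genome: GenomeRecord, path: str
) -> None:
    """Minimal unsorted SAM output (placement only, no sequence/tags)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        fh.write(f"@SQ\tSN:{genome.contig_id}\tLN:{genome.length}\n")
        for m in mapped:
            flag = 16 if m.strand == "-" else 0
            cigar = f"{m.end - m.start}M"
            fh.write(
                f"{m.read_id}\t{flag}\t{m.contig_id}\t{m.start + 1}\t"
                f"{60 if m.is_unique else 0}\t{cigar}\t*\t0\t0\t*\t*\n"
            )


def write_bed6(rows: Iterable[tuple], path: str) -> None:
    """BED6 writer; rows are (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def _json_default(obj):
    """Fold numpy scalars into native JSON types."""
    import numpy as np

    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj).__name__}")


def write_reports(results: dict, out_dir: str) -> dict[str, str]:
    """Emit the standard report bundle into ``out_dir``.

    ``results`` may contain: ``features`` (list of Feature), pandas DataFrames
    under ``tables`` (name -> frame), and a JSON-serialisable ``summary``.
    Output is deterministic: tables are written with a fixed column order and
    sorted index, the summary with sorted keys.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    gff_path = os.path.join(out_dir, "features.gff3")
    write_gff3(results.get("features", []), gff_path)
    paths["features"] = gff_path

    for name, frame in sorted(results.get("tables", {}).items()):
        tsv_path = os.path.join(out_dir, f"{name}.tsv")
        frame.to_csv(tsv_path, sep="\t", index=False)
        paths[name] = tsv_path

    summary_path = os.path.join(out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(
            results.get("summary", {}),
            fh,
            indent=2,
            sort_keys=True,
            default=_json_default,
        )
        fh.write("\n")
    paths["summary"] = summary_path
    return paths
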