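"""Pipeline orchestration: trim -> map -> pileup -> crispr / trna / srna.

``run_all`` executes the stages in dependency order on real or synthetic
inputs and produces one machine-readable summary (plus GFF3/TSV reports).
Stages whose inputs are missing are skipped with an explicit ``None`` entry
in the summary, never silently.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import boxsrna, crispr, trna
from .io import read_fasta, read_fastq, read_gff3, read_sam, write_reports
from .model import Feature, GenomeRecord, Read
from .reads import (
    MapConfig,
    TrimConfig,
    build_pileup,
    map_reads,
    screen_intergenic,
    trim_reads,
)

log = logging.getLogger("nanosmallrna")


@dataclass
class RunConfig:
    genome: str | None = None
    gff: str | None = None
    reads: str | None = None  # FASTQ
    sam: str | None = None  # pre-mapped alternative to reads
    rrna: str | None = None
    out_dir: str = "nanosmallrna_out"
    seed: int = 0
    run_crispr: bool = True
    run_trna: bool = True
    run_srna: bool = True
    trim: TrimConfig = field(default_factory=TrimConfig)
    map: MapConfig = field(default_factory=MapConfig)
    crispr_params: crispr.CrisprParams = field(default_factory=crispr.CrisprParams)
    cd_params: boxsrna.CdParams = field(default_factory=boxsrna.CdParams)
    srna_candidate_min_coverage: int = 50
    intergenic_min_coverage: int = 1000
    min_junction_support: int = 5
    log_level: str = "INFO"


def validate_config(cfg: RunConfig | dict) -> RunConfig:
    """Range-check and normalise a run configuration (idempotent)."""
    if isinstance(cfg, dict):
        kwargs = dict(cfg)
        for key, cls in (
            ("trim", TrimConfig),
            ("map", MapConfig),
            ("crispr_params", crispr.CrisprParams),
            ("cd_params", boxsrna.CdParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = cls(**kwargs[key])
        cfg = RunConfig(**kwargs)
    errors = []
    # sub-config dataclasses validate themselves on construction; re-run
    # their __post_init__ in case fields were mutated afterwards
    for sub in (cfg.trim, cfg.map):
        try:
            sub.__post_init__()
        except ValueError as exc:
            errors.append(str(exc))
    if cfg.srna_candidate_min_coverage < 1:
        errors.append("srna_candidate_min_coverage must be >= 1")
    if cfg.intergenic_min_coverage < 1:
        errors.append("intergenic_min_coverage must be >= 1")
    if cfg.min_junction_support < 1:
        errors.append("min_junction_support must be >= 1")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg


def run_all(
    cfg: RunConfig,
    genome: GenomeRecord | None = None,
    features: list[Feature] | None = None,
    reads: list[Read] | None = None,
    write: bool = True,
) -> dict[str, Any]:
    """Execute the full analysis; returns (and optionally writes) the summary.

    In-memory objects may be passed directly (as the synthetic flagship run
    does); otherwise they are loaded from the configured paths.
    """
    cfg = validate_config(cfg)
    logging.basicConfig(level=cfg.log_level)
    if genome is None:
        if cfg.genome is None:
            raise ValueError("a genome is required")
        genome = read_fasta(cfg.genome)[0]
    if features is None:
        features = read_gff3(cfg.gff) if cfg.gff else []
    if reads is None and cfg.reads:
        reads = read_fastq(cfg.reads)

    summary: dict[str, Any] = {"seed": cfg.seed, "contig": genome.contig_id}
    out_features: list[Feature] = list(features)
    tables: dict[str, pd.DataFrame] = {}

    # --- reads: trim, map, pileup -----------------------------------------
    pileup = None
    kept_reads: list[Read] = []
    if reads is not None:
        kept_reads, trim_log = trim_reads(reads, cfg.trim)
        mapped, map_log = map_reads(kept_reads, genome, cfg.map, cfg.seed)
        pileup = build_pileup(mapped, genome)
        summary["read_accounting"] = {
            "input": trim_log["input"],
            "discarded_short": trim_log["too_short"],
            "after_trimming": trim_log["kept"],
            "mapped": map_log["mapped"],
            "unmapped": map_log["unmapped"],
            "multimapped": map_log["multimapped"],
        }
        log.info("mapped %d/%d reads", map_log["mapped"], trim_log["kept"])
    elif cfg.sam:
        mapped = read_sam(cfg.sam)
        pileup = build_pileup(mapped, genome)
        summary["read_accounting"] = {"mapped": len(mapped)}
    else:
        summary["read_accounting"] = None
        log.warning("no reads given; coverage-dependent stages degrade")

    # --- CRISPR stage ------------------------------------------------------
    if cfg.run_crispr:
        summary["crispr"] = _crispr_stage(
            genome, pileup, cfg, out_features, tables
        )
    else:
        summary["crispr"] = None

    # --- tRNA stage --------------------------------------------------------
    halves = [f for f in features if f.kind == "tRNA_half"]
    if cfg.run_trna and halves and pileup is not None:
        summary["trna"] = _trna_stage(
            genome, features, halves, pileup, tables
        )
    else:
        summary["trna"] = None
        if cfg.run_trna and not halves:
            log.warning("trna stage skipped: no tRNA_half annotations")

    # --- sRNA stage --------------------------------------------------------
    if cfg.run_srna:
        summary["srna"] = _srna_stage(
            genome, features, pileup, kept_reads, cfg, out_features, tables
        )
    else:
        summary["srna"] = None

    if write:
        write_reports(
            {"features": out_features, "tables": tables, "summary": summary},
            cfg.out_dir,
        )
    return summary


def _crispr_stage(genome, pileup, cfg, out_features, tables) -> dict:
    arrays = crispr.detect_arrays(genome, cfg.crispr_params)
    for arr in arrays:
        crispr.orient_array(arr, pileup, genome)
    stage: dict[str, Any] = {"n_arrays": len(arrays), "arrays": []}
    spacer_rows = []
    for arr in arrays:
        entry: dict[str, Any] = {
            "array_id": arr.array_id,
            "strand": arr.strand,
            "n_repeats": len(arr.repeats),
            "n_spacers": len(arr.spacers),
            "repeat_consensus": arr.repeat_consensus,
            "repeat_len": len(arr.repeat_consensus),
            "orientation_method": arr.orientation_method,
            "flags": arr.flags,
        }
        if pileup is not None:
            profile = crispr.infer_maturation(arr, pileup)
            tss = crispr.call_tss(arr, pileup, genome)
            entry.update(
                {
                    "five_tag_length": profile.five_tag_length,
                    "five_tag_sequence": profile.five_tag_sequence,
                    "tss_position": tss.tss_position,
                    "tss_base": tss.tss_base,
                    "tss_offset": tss.tss_offset_to_first_repeat,
                }
            )
            if tss.tss_position is not None:
                boxa = crispr.find_boxA(genome, tss.tss_position, arr.strand)
                entry["boxA_offset"] = boxa.boxA_offset
                entry["boxA_sequence"] = boxa.boxA_sequence
                entry["boxA_mismatches"] = boxa.boxA_mismatches
            order = arr.spacer_order()
            for rank, idx in enumerate(order):
                a, b = arr.spacers[idx]
                spacer_rows.append(
                    {
                        "array_id": arr.array_id,
                        "spacer_rank": rank + 1,
                        "start": a,
                        "end": b,
                        "strand": arr.strand,
                        "read_count": profile.read_counts[rank],
                        "relative_abundance": profile.relative_abundance[rank],
                        "tag_length": profile.per_spacer_tag_length[rank],
                        "hotspots": ",".join(
                            str(h) for h in profile.trimming_hotspots[rank]
                        ),
                    }
                )
            entry["spacer_read_counts"] = [
                spacer_rows[-len(order) + i]["read_count"] for i in range(len(order))
            ]
        stage["arrays"].append(entry)
        out_features.extend(crispr.array_features(arr))
    if len(arrays) >= 2:
        leaders = crispr.compare_leaders(arrays[0], arrays[1], genome)
        stage["leader_identity"] = leaders.identical_prefix_length
    else:
        stage["leader_identity"] = None
    if spacer_rows:
        tables["spacers"] = pd.DataFrame(spacer_rows)
    return stage


def _trna_stage(genome, features, half_feats, pileup, tables) -> dict:
    halves = [trna.TrnaHalfGene.from_feature(f, genome) for f in half_feats]
    clamp_lens = {
        h.feature_id: int(f.attributes["clamp_len"])
        for h, f in zip(halves, half_feats)
        if "clamp_len" in f.attributes
    }
    trna.extract_clamps(halves, genome)
    for h in halves:
        # an annotated clamp length overrides the T-stretch heuristic
        if h.feature_id in clamp_lens:
            n = clamp_lens[h.feature_id]
            if (h.half_side == "five_prime") == (h.strand == "+"):
                lo = h.clamp_interval[0]
                h.clamp_interval = (lo, lo + n)
            else:
                hi = h.clamp_interval[1]
                h.clamp_interval = (hi - n, hi)
            a, b = h.clamp_interval
            seq = genome.sequence[a:b]
            h.clamp_seq = trna.revcomp(seq) if h.strand == "-" else seq
    pairs = trna.pair_halves(halves)
    termini = trna.annotate_precursor_termini(halves, pileup, genome, features)
    trna_genes = [f for f in features if f.kind == "tRNA"]
    leaderless = trna.leaderless_report(trna_genes, pileup, genome)
    tables["trna_pairs"] = pd.DataFrame(
        [
            {
                "five_id": p.five_half.feature_id,
                "three_id": p.three_half.feature_id,
                "duplex_len": p.duplex_len,
                "duplex_score": p.duplex_score,
                "gc_fraction": p.gc_fraction_of_duplex,
                "mature_len": len(p.mature_seq),
                "junction": p.junction,
                "ambiguous": p.ambiguous,
            }
            for p in pairs
        ]
    )
    tables["trna_termini"] = pd.DataFrame([dataclasses.asdict(r) for r in termini])
    tables["leaderless"] = pd.DataFrame([dataclasses.asdict(r) for r in leaderless])
    return {
        "n_halves": len(halves),
        "n_pairs": len(pairs),
        "pairs": [
            {
                "five_id": p.five_half.feature_id,
                "three_id": p.three_half.feature_id,
                "duplex_len": p.duplex_len,
                "duplex_score": p.duplex_score,
            }
            for p in pairs
        ],
        "termini": [dataclasses.asdict(r) for r in termini],
        "leaderless": [dataclasses.asdict(r) for r in leaderless],
    }


def _srna_stage(genome, features, pileup, reads, cfg, out_features, tables) -> dict:
    srnas = boxsrna.scan_cd(genome, cfg.cd_params)
    intron_regions = [
        (f.start, f.end, f.strand) for f in features if f.kind == "tRNA_intron"
    ]
    if intron_regions:
        srnas += boxsrna.scan_cd(genome, cfg.cd_params, regions=intron_regions)
    kept = [s for s in srnas if not s.shadowed]
    for i, s in enumerate(kept, start=1):
        s.srna_id = f"cd_srna_{i}"
        boxsrna.classify_context(s, features)
        if reads:
            boxsrna.detect_circular(s, reads, cfg.min_junction_support)
    haca_list = []
    if pileup is not None:
        regions = screen_intergenic(
            pileup, features, min_coverage=cfg.srna_candidate_min_coverage
        )
        haca_regions = [
            r
            for r in regions
            if not any(
                s.start < r[1] and r[0] < s.end and s.strand == r[2] for s in kept
            )
        ]
        haca_list = boxsrna.find_haca(haca_regions, genome)
    rrnas = []
    if cfg.rrna:
        rrnas = read_fasta(cfg.rrna)
    else:
        rrnas = [
            GenomeRecord(f.feature_id, f.sequence(genome))
            for f in features
            if f.kind == "rRNA"
        ]
    predictions = []
    for s in kept:
        predictions.extend(boxsrna.predict_2ome_targets(s, rrnas))
    for h in haca_list:
        predictions.extend(boxsrna.predict_psi_targets(h, rrnas))
    for s in kept:
        out_features.append(
            Feature(
                s.srna_id, s.contig_id, s.start % genome.length,
                min(s.end, genome.length), s.strand, "CD_sRNA",
                {"arrangement": s.arrangement, "context": s.context or "NA"},
            )
        )
    for h in haca_list:
        out_features.append(
            Feature(h.srna_id, h.contig_id, h.start, h.end, h.strand, "HACA_sRNA",
                    {"h_domain": h.h_domain_status})
        )
    tables["cd_srnas"] = pd.DataFrame(
        [
            {
                "srna_id": s.srna_id,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "arrangement": s.arrangement,
                "context": s.context,
                "terminal_pairing": s.terminal_pairing,
                "junction_support": s.junction_read_support,
                "circular": s.circular,
                "mismatches": s.total_mismatches,
            }
            for s in kept
        ]
    )
    tables["targets"] = pd.DataFrame([dataclasses.asdict(p) for p in predictions])
    return {
        "n_cd_srnas": len(kept),
        "cd_srnas": [
            {
                "srna_id": s.srna_id,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "arrangement": s.arrangement,
                "context": s.context,
                "circular": s.circular,
                "junction_support": s.junction_read_support,
                "terminal_pairing": s.terminal_pairing,
            }
            for s in kept
        ],
        "n_haca": len(haca_list),
        "haca": [
            {
                "srna_id": h.srna_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "h_domain_status": h.h_domain_status,
                "kturn_flags": h.kturn_flags,
                "hinge_aca": h.hinge_aca,
            }
            for h in haca_list
        ],
        "n_target_predictions": len(predictions),
    }
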