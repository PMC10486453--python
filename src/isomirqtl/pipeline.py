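"""End-to-end orchestration: preprocess -> align -> classify -> compose -> associate.

Every stage communicates through plain TSV files so each is independently
invokable and a chained run equals a monolithic one.  All defaults equal
the analysis parameters the pipeline is built around (adaptor, length 16-28,
5 trimming rounds, >= 10 subjects, MAF > 1%, ±8-base window, +0.5
pseudocount, FDR 0.05).  A resolved-config copy and a line-count log are
written to the run directory; nothing in the outputs depends on wall
clock, so reruns with the same seed and config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import align as al
from . import allele as aa
from . import classify as cl
from . import composition as cp
from . import association as asn
from . import preprocess as pp
from .errors import InputError
from .io import read_fasta, read_fastq_sequences, read_mirbase_gff3, read_tsv, write_tsv


@dataclass
class PipelineConfig:
    fastq_dir: str
    precursor_fasta: str
    gff3: str
    out_dir: str
    vcf: str | None = None
    decoy_fasta: str | None = None
    metadata: str | None = None
    adaptor: str = pp.DEFAULT_ADAPTOR
    min_overlap: int = 3
    min_length: int = 16
    max_length: int = 28
    max_trim_rounds: int = 5
    min_subjects: int = 10
    maf_min: float = 0.01
    window: int = 8
    pseudocount_mode: str = "shared"
    fdr: float = 0.05
    min_informative_subjects: int = 10
    strata_column: str = "population"
    allele_aware: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def preprocess_stage(config: PipelineConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Trim, length-filter and collapse every subject FASTQ in ``fastq_dir``."""
    fastqs = sorted(Path(config.fastq_dir).glob("*.fastq"))
    if not fastqs:
        raise InputError(f"preprocess: no FASTQ files found in {config.fastq_dir}")
    tables, stats = [], []
    for fq in fastqs:
        reads = read_fastq_sequences(fq)
        table, st = pp.preprocess_reads(
            reads, fq.stem, config.adaptor, config.min_overlap, config.min_length
        )
        tables.append(table)
        stats.append(st)
    collapsed = pd.concat(tables, ignore_index=True)
    if collapsed.empty:
        raise InputError("preprocess: no reads survived trimming and length filtering")
    return collapsed, stats


def load_references(config: PipelineConfig):
    seqs = read_fasta(config.precursor_fasta)
    precursors, matures = read_mirbase_gff3(config.gff3, seqs)
    genome = read_fasta(config.decoy_fasta) if config.decoy_fasta else None
    return precursors, matures, genome


def align_stage(
    collapsed: pd.DataFrame,
    precursors,
    genome,
    config: PipelineConfig,
    dosages: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
):
    """Align unique sequences once (allele-aware when a VCF is supplied), then
    broadcast placements back to subjects and apply the subject filter."""
    references = {p.id: p.sequence for p in precursors}
    alt_refs: dict[str, str] = {}
    snps: list[aa.SNPRecord] = []
    if config.allele_aware and dosages is not None:
        snps = aa.select_snps(dosages, precursors, config.maf_min)
        alt_refs = aa.build_personalized_references(precursors, snps)
    unique_seqs = sorted(collapsed["sequence"].unique())
    per_seq: dict[str, list] = {}
    status_counts = {"aligned": 0, "length": 0, "genome": 0, "unaligned": 0}
    for seq in unique_seqs:
        hits, status = aa.align_read_allele_aware(
            seq, references, alt_refs, genome, config.max_trim_rounds
        )
        status_counts[status] += 1
        if hits:
            per_seq[seq] = hits
    rows = []
    for rec in collapsed.itertuples(index=False):
        for hit in per_seq.get(rec.sequence, []):
            rows.append((rec.subject, int(rec.count), hit))
    table = al.alignments_to_frame(rows)
    filtered = al.filter_min_subjects(table, config.min_subjects)
    multimapped = (
        table.groupby(["subject", "sequence"])["precursor_id"].nunique() > 1
    ).mean() if not table.empty else 0.0
    stats = {
        "unique_sequences": len(unique_seqs),
        **status_counts,
        "alignment_rows": int(len(table)),
        "rows_after_subject_filter": int(len(filtered)),
        "multimapping_fraction": float(multimapped),
        "n_snps_selected": len(snps),
    }
    return filtered, snps, stats


def analyze_cohort(
    bundle,
    min_subjects: int = 10,
    window: int = 8,
    fdr: float = 0.05,
    min_informative_subjects: int = 10,
    allele_aware: bool = True,
    max_trim_rounds: int = 5,
    run_assoc: bool = True,
) -> dict:
    """Run the analysis cascade directly on an in-memory synthetic cohort.

    Identical logic to :func:`run_pipeline` minus the file plumbing and
    adaptor stage (the bundle stores adaptor-free inserts; the FASTQ path
    exercises trimming).  Returns alignments, classified table,
    composition and association results.
    """
    references = {p.id: p.sequence for p in bundle.precursors}
    alt_refs = (
        aa.build_personalized_references(bundle.precursors, bundle.snps)
        if allele_aware and bundle.snps
        else {}
    )
    per_seq: dict[str, list] = {}
    for seq in sorted(bundle.reads["sequence"].unique()):
        hits, _ = aa.align_read_allele_aware(
            seq, references, alt_refs, bundle.decoys, max_trim_rounds
        )
        if hits:
            per_seq[seq] = hits
    rows = [
        (rec.subject, int(rec.count), hit)
        for rec in bundle.reads.itertuples(index=False)
        for hit in per_seq.get(rec.sequence, [])
    ]
    alignments = al.filter_min_subjects(al.alignments_to_frame(rows), min_subjects)
    classified = cl.classify_table(alignments, bundle.matures)
    comp_long = cp.compose_5prime(classified, window)
    association = pd.DataFrame()
    if run_assoc and bundle.snps:
        snp_to_matures = {
            s.rsid: sorted(m.id for m in bundle.matures if m.precursor_id == s.precursor_id)
            for s in bundle.snps
        }
        strata = bundle.metadata.set_index("subject")["population"]
        association = asn.run_association(
            comp_long, bundle.genotypes, snp_to_matures, strata,
            fdr=fdr, min_informative_subjects=min_informative_subjects,
        )
    return {
        "alignments": alignments,
        "classified": classified,
        "composition_long": comp_long,
        "association": association,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and write the run directory.

    Returns a dict with the main in-memory results and the path map.
    Stage failures abort with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def _log(msg: str):
        log.append(msg)

    collapsed, pp_stats = preprocess_stage(config)
    _log(f"preprocess: {len(pp_stats)} subjects, {int(collapsed['count'].sum())} reads, "
         f"{len(collapsed)} collapsed rows")
    write_tsv(out / "collapsed.tsv", collapsed)

    precursors, matures, genome = load_references(config)
    _log(f"references: {len(precursors)} precursors, {len(matures)} matures")

    metadata = read_tsv(config.metadata) if config.metadata else None
    dosages = None
    if config.vcf and metadata is not None:
        dosages = aa.dosage_frame_from_vcf(config.vcf, list(metadata["subject"]))

    alignments, snps, al_stats = align_stage(
        collapsed, precursors, genome, config, dosages, metadata
    )
    _log(f"align: {al_stats}")
    write_tsv(out / "alignments.tsv", alignments)

    classified = cl.classify_table(alignments, matures)
    census = cl.subtype_census(classified)
    _log(
        f"classify: {census['n_isomirs']} distinct isomiRs, "
        f"fractions {census['sequence_weighted']}"
    )
    write_tsv(out / "classified.tsv", classified)

    comp_long = cp.compose_5prime(classified, config.window, config.pseudocount_mode)
    write_tsv(out / "composition_long.tsv", comp_long)
    wide = cp.composition_wide(comp_long)
    wide.reset_index().rename(columns={"index": "subject"}).pipe(
        lambda f: write_tsv(out / "composition_wide.tsv", f)
    )
    _log(f"compose: {len(comp_long)} cells, {wide.shape[1] if not wide.empty else 0} columns")

    association = pd.DataFrame()
    if dosages is not None and snps and metadata is not None:
        snp_to_matures = {
            s.rsid: sorted(m.id for m in matures if m.precursor_id == s.precursor_id)
            for s in snps
        }
        strata = metadata.set_index("subject")[config.strata_column]
        association = asn.run_association(
            comp_long, dosages, snp_to_matures, strata,
            fdr=config.fdr, min_informative_subjects=config.min_informative_subjects,
        )
        _log(f"associate: {len(association)} tests, "
             f"{int(association['significant'].sum()) if not association.empty else 0} significant")
        write_tsv(out / "association.tsv", association)

    summary = {
        "preprocess": pp_stats,
        "align": al_stats,
        "census": {
            "n_isomirs": census["n_isomirs"],
            "n_new": census["n_new"],
            "sequence_weighted": census["sequence_weighted"],
            "read_weighted": census["read_weighted"],
        },
        "n_association_tests": int(len(association)),
        "n_significant": int(association["significant"].sum()) if not association.empty else 0,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    )
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return {
        "collapsed": collapsed,
        "alignments": alignments,
        "classified": classified,
        "composition_long": comp_long,
        "composition_wide": wide,
        "association": association,
        "census": census,
        "summary": summary,
        "out_dir": out,
    }
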