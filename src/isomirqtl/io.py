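"""Readers, writers and coordinate conversions shared by all stages.

All sequences are normalised to the DNA alphabet (U -> T, uppercase) on
ingest.  Internally every span is 0-based half-open in precursor-local
transcript coordinates; GFF3 and VCF coordinates (1-based, genomic) are
converted at this boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_READ = re.compile(r"^[ACGTN]*$")


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_read(seq: str) -> str:
    s = normalize_seq(seq)
    if not _VALID_READ.match(s):
        raise InputError(f"read contains non-ACGTN characters: {seq!r}")
    return s


@dataclass(frozen=True)
class PrecursorRecord:
    """One hairpin precursor in transcript orientation plus its genomic placement.

    ``start``/``end`` are 1-based inclusive genomic coordinates (GFF3
    convention); the genomic span length equals the sequence length.
    """

    id: str
    sequence: str
    chrom: str = "."
    start: int = 1
    end: int = 0
    strand: str = "+"

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if self.end - self.start + 1 != len(self.sequence):
            raise InputError(
                f"precursor {self.id}: genomic span length "
                f"{self.end - self.start + 1} != sequence length {len(self.sequence)}"
            )

    def genomic_to_local(self, gpos: int) -> int:
        """1-based genomic position -> 0-based transcript-local offset."""
        if self.strand == "+":
            return gpos - self.start
        return self.end - gpos

    def local_to_genomic(self, lpos: int) -> int:
        if self.strand == "+":
            return self.start + lpos
        return self.end - lpos


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA's span on its precursor (0-based half-open, local).

    The seed is mature positions 2-7 (1-based within the mature), the
    primary determinant of mRNA target recognition.
    """

    id: str
    precursor_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def seed_span(self) -> tuple[int, int]:
        """Precursor-local half-open span of mature positions 2-7."""
        return self.start + 1, self.start + 7


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: DNA sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_seq(str(rec.seq))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], rna: bool = False) -> None:
    recs = []
    for rid, seq in records:
        s = seq.upper()
        if rna:
            s = s.replace("T", "U")
        recs.append(SeqRecord(Seq(s), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read raw read sequences (normalised to DNA) from a FASTQ file."""
    return [normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs as Phred+33 FASTQ with constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3, miRBase dialect
# ---------------------------------------------------------------------------

def _parse_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise InputError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_mirbase_gff3(
    path: str | Path, precursor_seqs: dict[str, str]
) -> tuple[list[PrecursorRecord], list[MatureAnnotation]]:
    """Parse a miRBase-style GFF3 into precursor records and local mature spans.

    Precursor rows are ``miRNA_primary_transcript`` with ``ID``/``Name``;
    mature rows are ``miRNA`` with ``Derives_from`` pointing at the
    precursor.  Mature genomic spans are converted to precursor-local
    0-based half-open coordinates, strand-aware.
    """
    precursors: dict[str, PrecursorRecord] = {}
    mature_rows: list[tuple[dict[str, str], int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            attributes = _parse_attributes(attrs)
            if ftype == "miRNA_primary_transcript":
                name = attributes.get("Name", attributes["ID"])
                if name not in precursor_seqs:
                    raise InputError(f"{path}:{lineno}: precursor {name} absent from FASTA")
                precursors[attributes["ID"]] = PrecursorRecord(
                    id=name,
                    sequence=precursor_seqs[name],
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            elif ftype == "miRNA":
                mature_rows.append((attributes, int(start), int(end)))
    matures: list[MatureAnnotation] = []
    for attributes, gstart, gend in mature_rows:
        parent_key = attributes["Derives_from"]
        if parent_key not in precursors:
            raise InputError(f"mature {attributes.get('Name')} Derives_from unknown {parent_key}")
        prec = precursors[parent_key]
        if prec.strand == "+":
            lstart, lend = gstart - prec.start, gend - prec.start + 1
        else:
            lstart, lend = prec.end - gend, prec.end - gstart + 1
        matures.append(
            MatureAnnotation(
                id=attributes.get("Name", attributes["ID"]),
                precursor_id=prec.id,
                start=lstart,
                end=lend,
            )
        )
    return list(precursors.values()), matures


def write_mirbase_gff3(
    path: str | Path, precursors: list[PrecursorRecord], matures: list[MatureAnnotation]
) -> None:
    by_id = {p.id: p for p in precursors}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, prec in enumerate(precursors):
            pid = f"MI{i:07d}"
            fh.write(
                f"{prec.chrom}\t.\tmiRNA_primary_transcript\t{prec.start}\t{prec.end}"
                f"\t.\t{prec.strand}\t.\tID={pid};Name={prec.id}\n"
            )
            for j, mat in enumerate(m for m in matures if m.precursor_id == prec.id):
                p = by_id[mat.precursor_id]
                if p.strand == "+":
                    gstart, gend = p.start + mat.start, p.start + mat.end - 1
                else:
                    gstart, gend = p.end - mat.end + 1, p.end - mat.start
                fh.write(
                    f"{p.chrom}\t.\tmiRNA\t{gstart}\t{gend}\t.\t{p.strand}\t.\t"
                    f"ID=MIMAT{i:05d}{j};Name={mat.id};Derives_from={pid}\n"
                )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    path: str | Path,
    variants: list[dict],
    subjects: list[str],
    genotypes,
) -> None:
    """Write a minimal plain-text VCF v4.2 with GT-only genotype columns.

    ``variants`` is a list of dicts with keys chrom, pos (1-based), id,
    ref, alt; ``genotypes`` is indexable as ``genotypes.loc[subject,
    variant_id]`` giving the ALT dosage in {0, 1, 2}.
    """
    gt_string = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v["chrom"] for v in variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects) + "\n")
        for v in sorted(variants, key=lambda v: (v["chrom"], v["pos"])):
            gts = "\t".join(gt_string[int(genotypes.loc[s, v["id"]])] for s in subjects)
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
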