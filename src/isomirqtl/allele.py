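"""Allele-aware alignment via personalised (alternative-allele) references.

Aligning against reference precursors alone biases against reads carrying
the alternative allele of a precursor SNP: a canonical-length read from
the alt allele scores as a one-mismatch "substitution isomiR" (or goes
unmapped entirely).  The fix is to build one extra reference per SNP with
the single alternative base substituted, align against both sets with the
same round cascade, and keep — per read — the placement(s) from the
earliest round across the two sets.  On equal rounds the canonical
reference wins (the read is then uninformative about its allele of
origin, which is logged rather than split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import ROUND_RANK, IsomiRAlignment, align_read
from .errors import ConsistencyError, DegenerateDataError
from .io import PrecursorRecord

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SNPRecord:
    """A bi-allelic precursor-region SNP with strand-resolved local alleles.

    ``pos`` is the 1-based genomic position (VCF convention);
    ``local_pos`` is 0-based on the precursor transcript.  For
    minus-strand precursors the local alleles are the complements of the
    genomic ones.
    """

    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    precursor_id: str
    local_pos: int
    local_ref: str
    local_alt: str


def dosage_frame_from_vcf(vcf_path: str, subjects: list[str]) -> pd.DataFrame:
    """Read ALT-allele dosages (subjects x variants) from a VCF with GT calls.

    Missing genotypes become NaN.  Only the requested subjects, in the
    requested order, are returned.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    missing = [s for s in subjects if s not in sample_idx]
    if missing:
        raise ConsistencyError(f"subjects absent from VCF: {missing[:5]}")
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, tuple] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        types = np.asarray(var.gt_types)
        dos = np.where(types == 0, 0.0, np.where(types == 1, 1.0, np.where(types == 3, 2.0, np.nan)))
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        cols[vid] = np.array([dos[sample_idx[s]] for s in subjects])
        meta[vid] = (var.CHROM, var.POS, var.REF, var.ALT[0])
    frame = pd.DataFrame(cols, index=subjects)
    frame.attrs["variant_meta"] = meta
    return frame


def select_snps(
    dosages: pd.DataFrame,
    precursors: list[PrecursorRecord],
    maf_min: float = 0.01,
) -> list[SNPRecord]:
    """Select bi-allelic SNVs inside precursor spans with cohort MAF > ``maf_min``.

    ``dosages`` is the output of :func:`dosage_frame_from_vcf` (its
    ``variant_meta`` attr supplies CHROM/POS/REF/ALT).  Alleles longer
    than one base (indels) are skipped.  Local coordinates and alleles
    are strand-resolved.
    """
    meta = dosages.attrs["variant_meta"]
    out: list[SNPRecord] = []
    for vid, (chrom, pos, ref, alt) in meta.items():
        if len(ref) != 1 or len(alt) != 1:
            continue
        col = dosages[vid].dropna()
        if col.empty:
            continue
        af = float(col.mean() / 2.0)
        maf = min(af, 1.0 - af)
        if maf <= maf_min:
            continue
        for prec in precursors:
            if prec.chrom == chrom and prec.start <= pos <= prec.end:
                local = prec.genomic_to_local(pos)
                if prec.strand == "+":
                    lref, lalt = ref, alt
                else:
                    lref, lalt = _COMPL[ref], _COMPL[alt]
                if prec.sequence[local] != lref:
                    raise ConsistencyError(
                        f"SNP {vid}: precursor {prec.id} base {prec.sequence[local]} "
                        f"at local {local} != VCF REF {lref}"
                    )
                out.append(
                    SNPRecord(
                        rsid=vid, chrom=chrom, pos=pos, ref=ref, alt=alt, maf=maf,
                        precursor_id=prec.id, local_pos=local,
                        local_ref=lref, local_alt=lalt,
                    )
                )
    return out


def build_personalized_references(
    precursors: list[PrecursorRecord], snps: list[SNPRecord]
) -> dict[str, str]:
    """One alternative-allele reference per SNP, keyed ``"rsID|precursor"``.

    The originals are untouched; each personalised sequence differs from
    its precursor by exactly the one local base.
    """
    by_id = {p.id: p for p in precursors}
    alt_refs: dict[str, str] = {}
    for snp in snps:
        prec = by_id[snp.precursor_id]
        seq = prec.sequence
        if seq[snp.local_pos] != snp.local_ref:
            raise ConsistencyError(
                f"SNP {snp.rsid}: local ref {snp.local_ref} disagrees with "
                f"precursor {prec.id} base {seq[snp.local_pos]}"
            )
        alt_refs[f"{snp.rsid}|{prec.id}"] = (
            seq[: snp.local_pos] + snp.local_alt + seq[snp.local_pos + 1 :]
        )
    return alt_refs


def _strip_alt_tag(aln: IsomiRAlignment) -> IsomiRAlignment:
    rsid, precursor_id = aln.precursor_id.split("|", 1)
    return IsomiRAlignment(
        sequence=aln.sequence, precursor_id=precursor_id, start=aln.start,
        end=aln.end, round=aln.round, prefix=aln.prefix, suffix=aln.suffix,
        sub_pos=aln.sub_pos, sub_ref=aln.sub_ref, sub_read=aln.sub_read,
        allele_origin=rsid,
    )


def merge_allele_alignments(
    canonical_hits: list[IsomiRAlignment], alt_hits: list[IsomiRAlignment]
) -> list[IsomiRAlignment]:
    """Keep the earliest-round placement(s) across both reference sets.

    Equal rounds prefer the canonical reference.  Alt-kept placements are
    re-keyed onto their underlying precursor with ``allele_origin`` set to
    the rsID.  Idempotent and order-independent in its inputs.
    """
    if not canonical_hits and not alt_hits:
        return []
    can_rank = min((ROUND_RANK[a.round] for a in canonical_hits), default=len(ROUND_RANK))
    alt_rank = min((ROUND_RANK[a.round] for a in alt_hits), default=len(ROUND_RANK))
    if can_rank <= alt_rank:
        return [a for a in canonical_hits if ROUND_RANK[a.round] == can_rank]
    kept = [a for a in alt_hits if ROUND_RANK[a.round] == alt_rank]
    return [_strip_alt_tag(a) if "|" in a.precursor_id else a for a in kept]


def align_read_allele_aware(
    read: str,
    references,
    alt_references: dict[str, str],
    genome=None,
    max_trim_rounds: int = 5,
) -> tuple[list[IsomiRAlignment], str]:
    """Round cascade against canonical and personalised references, merged."""
    can_hits, can_status = align_read(read, references, genome, max_trim_rounds)
    alt_hits, alt_status = align_read(read, alt_references, genome, max_trim_rounds) if alt_references else ([], "unaligned")
    merged = merge_allele_alignments(can_hits, alt_hits)
    if merged:
        return merged, "aligned"
    status = can_status if can_status != "unaligned" else alt_status
    return [], status


def allele_specific_counts(
    merged: pd.DataFrame,
    dosages: pd.DataFrame,
    snp: SNPRecord,
) -> pd.DataFrame:
    """Per-genotype, per-allele read counts over one SNP position.

    Only reads whose templated span covers the SNP's local position are
    tallied.  Rows: genotype class (0/1/2 copies of ALT); columns: reads
    attributed to the reference vs the alternative allele.
    """
    if snp.rsid not in dosages.columns:
        raise DegenerateDataError(f"SNP {snp.rsid} absent from genotype matrix")
    sel = merged[
        (merged["precursor_id"] == snp.precursor_id)
        & (merged["start"] <= snp.local_pos)
        & (merged["end"] > snp.local_pos)
    ]
    out = pd.DataFrame(
        0.0, index=pd.Index([0, 1, 2], name="genotype"), columns=["ref_reads", "alt_reads"]
    )
    if sel.empty:
        import warnings

        warnings.warn(f"no reads overlap SNP {snp.rsid}; empty allele tally")
        return out
    dos = dosages[snp.rsid]
    for row in sel.itertuples(index=False):
        d = dos.get(row.subject)
        if d is None or np.isnan(d):
            continue
        is_alt = row.allele_origin == snp.rsid
        # a one-mismatch placement whose substitution sits on the SNP and
        # reads the alt base is also alt-origin evidence
        if not is_alt and int(row.sub_pos) == snp.local_pos and row.sub_read == snp.local_alt:
            is_alt = True
        out.loc[int(d), "alt_reads" if is_alt else "ref_reads"] += row.count
    return out
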