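"""Personalised-reference alignment: SNP selection, merge precedence, bias removal."""

import numpy as np
import pandas as pd
import pytest

from isomirqtl.align import align_read
from isomirqtl.allele import (
    SNPRecord,
    align_read_allele_aware,
    allele_specific_counts,
    build_personalized_references,
    dosage_frame_from_vcf,
    merge_allele_alignments,
    select_snps,
)
from isomirqtl.errors import ConsistencyError
from isomirqtl.io import PrecursorRecord, revcomp, write_vcf


def _make_dosages(variants, subjects, geno_rows):
    frame = pd.DataFrame(geno_rows, index=subjects, columns=[v["id"] for v in variants])
    frame.attrs["variant_meta"] = {
        v["id"]: (v["chrom"], v["pos"], v["ref"], v["alt"]) for v in variants
    }
    return frame


class TestSelectSnps:
    def test_minus_strand_alleles_complemented(self):
        # genomic T/G SNP on a minus-strand precursor reads as local A/C
        local_seq = "ACGTACGTACGTAACCGGTTACGT"
        gpos = 104  # 1-based on chr1; precursor spans 101..124
        prec = PrecursorRecord(id="p", sequence=local_seq, chrom="chr1",
                               start=101, end=124, strand="-")
        local = prec.genomic_to_local(gpos)  # = 124 - 104 = 20
        assert local_seq[local] == "A"  # genomic base there is T (minus strand)
        dosages = _make_dosages(
            [{"id": "rsX", "chrom": "chr1", "pos": gpos, "ref": "T", "alt": "G"}],
            ["S1", "S2"], [[1.0], [1.0]],
        )
        snps = select_snps(dosages, [prec], maf_min=0.01)
        assert len(snps) == 1
        assert (snps[0].local_ref, snps[0].local_alt) == ("A", "C")
        assert snps[0].local_pos == local

    def test_snp_outside_span_excluded(self):
        prec = PrecursorRecord(id="p", sequence="ACGT" * 6, chrom="chr1", start=101, strand="+")
        dosages = _make_dosages(
            [{"id": "rsY", "chrom": "chr1", "pos": 100, "ref": "A", "alt": "C"}],
            ["S1", "S2"], [[1.0], [1.0]],
        )
        assert select_snps(dosages, [prec]) == []

    def test_low_maf_excluded(self):
        prec = PrecursorRecord(id="p", sequence="A" * 30, chrom="chr1", start=1, strand="+")
        n = 1000
        geno = np.zeros((n, 1))
        geno[:18, 0] = 1  # cohort MAF 0.9%
        dosages = _make_dosages(
            [{"id": "rsZ", "chrom": "chr1", "pos": 5, "ref": "A", "alt": "G"}],
            [f"S{i}" for i in range(n)], geno,
        )
        assert select_snps(dosages, [prec], maf_min=0.01) == []

    def test_indel_skipped(self):
        prec = PrecursorRecord(id="p", sequence="A" * 30, chrom="chr1", start=1, strand="+")
        dosages = _make_dosages(
            [{"id": "rsI", "chrom": "chr1", "pos": 5, "ref": "AT", "alt": "A"}],
            ["S1", "S2"], [[1.0], [1.0]],
        )
        assert select_snps(dosages, [prec]) == []


class TestVcfRoundTrip:
    def test_gt_dialects_and_dosages(self, tmp_path):
        variants = [{"chrom": "chr1", "pos": 10, "id": "rs1", "ref": "A", "alt": "G"}]
        subjects = ["S1", "S2", "S3"]
        geno = pd.DataFrame({"rs1": [0, 1, 2]}, index=subjects)
        path = tmp_path / "t.vcf"
        write_vcf(path, variants, subjects, geno)
        # phased and unphased GT separators both parse to the same dosage
        text = path.read_text().replace("0/1", "0|1")
        path.write_text(text)
        frame = dosage_frame_from_vcf(str(path), subjects)
        assert list(frame["rs1"]) == [0.0, 1.0, 2.0]
        assert frame.attrs["variant_meta"]["rs1"] == ("chr1", 10, "A", "G")


class TestPersonalizedReferences:
    PREC = PrecursorRecord(id="p", sequence="ACGTACGTACGTACGTACGTACGT", chrom="c", start=1)

    def _snp(self, pos, ref, alt, rsid="rs1"):
        return SNPRecord(rsid=rsid, chrom="c", pos=pos + 1, ref=ref, alt=alt, maf=0.2,
                         precursor_id="p", local_pos=pos, local_ref=ref, local_alt=alt)

    def test_single_base_edit(self):
        alt = build_personalized_references([self.PREC], [self._snp(2, "G", "A")])
        assert alt == {"rs1|p": "ACATACGTACGTACGTACGTACGT"}

    def test_zero_snps_empty_set(self):
        assert build_personalized_references([self.PREC], []) == {}

    def test_two_snps_two_references_one_edit_each(self):
        alt = build_personalized_references(
            [self.PREC], [self._snp(2, "G", "A", "rs1"), self._snp(5, "C", "T", "rs2")]
        )
        assert len(alt) == 2
        for seq in alt.values():
            diffs = sum(a != b for a, b in zip(seq, self.PREC.sequence))
            assert diffs == 1

    def test_ref_mismatch_raises(self):
        with pytest.raises(ConsistencyError):
            build_personalized_references([self.PREC], [self._snp(2, "T", "A")])


class TestMerge:
    REF = "AAACCCGGGTTTAAACCGGTAAAT"
    SNP_POS = 7  # G -> A alternative

    def _refs(self):
        canonical = {"p": self.REF}
        alt = {"rs9|p": self.REF[:7] + "A" + self.REF[8:]}
        return canonical, alt

    def test_alt_read_recovered_as_perfect_match(self):
        canonical, alt = self._refs()
        read = self.REF[3:7] + "A" + self.REF[8:19]  # carries alt allele at local 7
        can_hits, _ = align_read(read, canonical)
        assert can_hits and can_hits[0].round == "R1"
        merged, status = align_read_allele_aware(read, canonical, alt)
        assert status == "aligned"
        assert all(h.round == "R0" for h in merged)
        assert all(h.sub_pos is None for h in merged)
        assert all(h.allele_origin == "rs9" for h in merged)
        assert all(h.precursor_id == "p" for h in merged)

    def test_equal_round_tie_prefers_canonical(self):
        canonical, alt = self._refs()
        read = self.REF[8:24]  # downstream of SNP: identical in both references
        merged, _ = align_read_allele_aware(read, canonical, alt)
        assert all(h.allele_origin == "canonical" for h in merged)

    def test_merge_idempotent_and_order_independent(self):
        canonical, alt = self._refs()
        read = self.REF[3:7] + "A" + self.REF[8:19]
        can_hits, _ = align_read(read, canonical)
        alt_hits, _ = align_read(read, alt)
        once = merge_allele_alignments(can_hits, alt_hits)
        assert merge_allele_alignments(once, []) == once

    def test_unmapped_in_both_absent(self):
        canonical, alt = self._refs()
        merged, status = align_read_allele_aware("ACGT" * 5, canonical, alt)
        assert merged == [] and status == "unaligned"


class TestBiasRemoval:
    """The motivating invariant: alt-homozygote canonical reads must not be
    called substitution isomiRs once personalised references are in play."""

    def test_canonical_only_vs_merged(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list("ACGT"), size=70))
        prec = PrecursorRecord(id="p", sequence=ref, chrom="c", start=1)
        pos = 20
        alt_base = next(b for b in "ACGT" if b != ref[pos])
        snp = SNPRecord(rsid="rs5", chrom="c", pos=pos + 1, ref=ref[pos], alt=alt_base,
                        maf=0.3, precursor_id="p", local_pos=pos,
                        local_ref=ref[pos], local_alt=alt_base)
        alt_refs = build_personalized_references([prec], [snp])
        # canonical-length read from the alt allele, spanning the SNP
        read = (ref[:pos] + alt_base + ref[pos + 1 :])[10:32]
        can_hits, _ = align_read(read, {"p": ref})
        assert all(h.round == "R1" and h.sub_pos is not None for h in can_hits)
        merged, _ = align_read_allele_aware(read, {"p": ref}, alt_refs)
        assert all(h.round == "R0" and h.sub_pos is None for h in merged)


class TestAlleleSpecificCounts:
    def test_het_alt_fraction_recovered(self):
        # 50 heterozygous subjects emitting 100 reads each, 90% from the alt allele
        rng = np.random.default_rng(11)
        snp = SNPRecord(rsid="rs7", chrom="c", pos=21, ref="A", alt="G", maf=0.5,
                        precursor_id="p", local_pos=20, local_ref="A", local_alt="G")
        subjects = [f"S{i}" for i in range(50)]
        rows = []
        for s in subjects:
            n_alt = rng.binomial(100, 0.9)
            rows.append({"subject": s, "precursor_id": "p", "start": 10, "end": 32,
                         "count": n_alt, "allele_origin": "rs7", "sub_pos": -1, "sub_read": ""})
            rows.append({"subject": s, "precursor_id": "p", "start": 10, "end": 32,
                         "count": 100 - n_alt, "allele_origin": "canonical",
                         "sub_pos": -1, "sub_read": ""})
        merged = pd.DataFrame(rows)
        dosages = pd.DataFrame({"rs7": [1.0] * 50}, index=subjects)
        tally = allele_specific_counts(merged, dosages, snp)
        het = tally.loc[1]
        frac = het["alt_reads"] / (het["alt_reads"] + het["ref_reads"])
        assert abs(frac - 0.9) < 0.02

    def test_hom_ref_subjects_have_zero_alt(self):
        snp = SNPRecord(rsid="rs7", chrom="c", pos=21, ref="A", alt="G", maf=0.5,
                        precursor_id="p", local_pos=20, local_ref="A", local_alt="G")
        merged = pd.DataFrame(
            [{"subject": "S0", "precursor_id": "p", "start": 10, "end": 32,
              "count": 40, "allele_origin": "canonical", "sub_pos": -1, "sub_read": ""}]
        )
        dosages = pd.DataFrame({"rs7": [0.0]}, index=["S0"])
        tally = allele_specific_counts(merged, dosages, snp)
        assert tally.loc[0, "alt_reads"] == 0
        assert tally.loc[0, "ref_reads"] == 40

    def test_no_overlapping_reads_warns_empty(self):
        snp = SNPRecord(rsid="rs7", chrom="c", pos=21, ref="A", alt="G", maf=0.5,
                        precursor_id="p", local_pos=20, local_ref="A", local_alt="G")
        merged = pd.DataFrame(
            [{"subject": "S0", "precursor_id": "p", "start": 30, "end": 50,
              "count": 5, "allele_origin": "canonical", "sub_pos": -1, "sub_read": ""}]
        )
        dosages = pd.DataFrame({"rs7": [2.0]}, index=["S0"])
        with pytest.warns(UserWarning):
            tally = allele_specific_counts(merged, dosages, snp)
        assert tally.to_numpy().sum() == 0
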