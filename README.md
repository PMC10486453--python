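# isomirqtl

Identification of miRNA sequence isoforms (isomiRs) from small-RNA
sequencing reads and association of cis-acting SNPs with 5′-isomiR
composition.

## Who this is for

IsomiRs arise when Drosha/Dicer cleave a precursor hairpin at shifted
positions, when nucleotides are substituted, or when non-templated bases
are added at a terminus. Because the 5′ end sets the seed (mature
positions 2–7), 5′-shifted isomiRs can retarget a miRNA entirely.
`isomirqtl` is a library for asking whether germline variation in the
precursor shifts the *composition* of these isoforms: it identifies and
classifies isomiRs from raw reads, removes reference-allele alignment
bias with personalised references, and tests precursor SNPs against
per-subject composition ratios. A synthetic-cohort generator with full
ground truth makes every stage testable without any external data.

## The method

1. **Preprocess** — exact 3′-adaptor trimming (`TGGAATTCTCGGGTGCCAAGGAACTC`
   by default), reads < 16 nt discarded, collapsing to unique sequences
   per subject.
2. **Multi-round alignment** onto hairpin precursors, earliest round
   wins: perfect match (R0) → genome-decoy filter (perfect hit on either
   strand elsewhere ⇒ discard) → one-mismatch (R1) → up to five
   single-base end-trimming rounds (T1–T5) exposing non-templated
   terminal additions. Only reads of 16–28 nt are placed.
3. **Allele-aware merge** — for each bi-allelic precursor SNP with cohort
   MAF > 1%, one personalised reference carrying the alternative base is
   added; per read the earliest-round placement across both reference
   sets is kept (ties prefer the canonical reference). This turns
   "substitution isomiRs" that are really germline alleles back into
   perfect matches.
4. **Classification** against the most-overlapping mature annotation
   (< 10 bases overlap ⇒ new isomiR): signed 5′/3′ shifts (trim −k /
   extension +k), additions add(m), and substitution classes 5Sub, 5sSub
   (seed), 5mSub, Sub, 3Sub, 3mSub.
5. **Composition** — per subject and mature miRNA, reads with a 5′
   terminus within ±8 bases of the canonical end are binned into
   categories and converted to pseudocounted ratios
   `(count + 0.5) / (total + 0.5)`.
6. **Association** — additively coded minor-allele dosage (0/1/2) vs
   ratio with Kendall's tau-b (tie-corrected normal-approximation
   p-values), BH adjustment run separately over the whole cohort and
   within each ancestry stratum, and a dual significance criterion:
   FDR < 0.05 overall *and* within at least one stratum.
7. **Group comparison** — RPM normalisation, aggregation of isomiRs
   sharing a 5′ variation, pooled-variance Student's t (Welch optional).

## Worked example

```python
from isomirqtl import run_association, simulate_association_study

dosages, composition, strata, snp_to_matures, planted = simulate_association_study(
    seed=7, n_subjects=435, maf=0.33, shift=-0.8, reads_per_subject=200
)
res = run_association(composition, dosages, snp_to_matures, strata)
print(res.iloc[0][["snp_id", "mature_id", "category", "tau_ALL", "fdr_ALL"]])
```

prints (see `examples/04_composition_qtl.py` for the full script):

```
56 SNP x miRNA x category tests, 2 significant at FDR < 0.05
top pair: rs_t001 x miR-t001-3p [ext+2]  tau=-0.701  p=2.21e-73  FDR=1.24e-71
strata:   EUR tau=-0.700 (FDR 5.50e-57), AFR tau=-0.706 (FDR 2.85e-14)
```

The planted SNP lowers the 2-base 5′-extension ratio of its 3p mature by
−0.8 log-odds per alt allele; the scan recovers it as the top-ranked
pair with a negative tau in the full cohort and in both strata. The
other `examples/` scripts walk through cohort simulation, alignment and
taxonomy, allele-bias removal (100% → 0% spurious substitution calls),
and the tumour-vs-normal comparison.

There is also a thin CLI: `isomirqtl simulate --out cohort/` writes a
synthetic cohort (FASTA/GFF3/VCF/FASTQ/TSV), and
`isomirqtl run-all --config pipeline.yaml` runs the file-based pipeline,
writing each stage's TSV plus a summary to the run directory.

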