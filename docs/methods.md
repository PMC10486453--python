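# Methods

## Problem and model

A mature miRNA is excised from a hairpin precursor by Drosha and Dicer.
Imprecise cleavage, internal substitution and non-templated terminal
addition produce sequence isoforms (isomiRs). The package models the
hypothesis that a SNP inside the precursor changes cleavage behaviour and
therefore the *composition* of 5′ isoforms: per subject *i*, mature
miRNA *m* and 5′ category *c*, the composition ratio is

    r_imc = (n_imc + 0.5) / (N_im + 0.5)

where `n_imc` counts in-window reads of category *c* and `N_im` all
in-window reads of *m*. The association of `r_imc` with the additively
coded minor-allele dosage of a same-precursor SNP is measured with
Kendall's tau-b.

## Alignment cascade and its consequences

Placement rounds run in strict precedence: perfect substring match on the
hairpin (forward strand only — matures come from the transcript), a
genome-decoy filter (perfect hit elsewhere on either strand discards the
read), Hamming-distance-1 placement, then trimming rounds k = 1..5 that
remove i bases from the 5′ end and j from the 3′ end (i + j = k) and
require the remaining core to match exactly. The earliest productive
round terminates the search; within it, all placements are reported and
the multi-mapping rate is logged. Trimmed cores are matched with zero
mismatches so that substitution and addition evidence never compound.

Round precedence has one structural consequence worth stating plainly: a
**single**-base non-templated addition whose extended placement stays
inside the precursor is indistinguishable from a templated extension
carrying a terminal substitution, and the cascade reports it at R1. Only
additions of two or more bases (or additions beyond the hairpin
boundary) reach the trimming rounds and are labelled `add(m)`. The
synthetic generator therefore plants 2-base additions; the taxonomy
itself remains exhaustive and mutually exclusive for every alignment the
cascade can emit.

## Taxonomy rules

Classification is relative to the mature annotation with the largest
templated-span overlap; an overlap below 10 bases makes the read a *new*
isomiR. Signed 5′ shift = mature start − templated start (+k extension,
−k trim); the 3′ side mirrors. A non-templated 5′ prefix that occupies
positions upstream of the mature start is an addition `add(m)`; a prefix
replacing mature bases is a terminal substitution run (5Sub single-base,
5mSub multi-base) — this positional rule is a package decision where the
add-vs-multi-substitution boundary is genuinely open, chosen because it
is deterministic and testable. An R1 substitution is graded by mature
position: 1 → 5Sub, 2–7 (seed) → 5sSub, final templated base → 3Sub,
otherwise Sub. An internal substitution beyond the seed leaves the 5′
terminus intact, so such reads count as 5′-canonical in the composition
analysis; seed-region and 5′-terminal substitutions form the
`sub` category.

## Allele-aware alignment

For every bi-allelic precursor SNV with cohort MAF > 1% (computed from
the VCF genotypes of the analysed subjects, indels skipped,
strand-resolved to transcript-local alleles) one personalised reference
with the single alternative base is added. Reads are aligned against
both reference sets with identical round logic and, per read, the
earliest-round placement across the two sets is kept. Equal rounds
prefer the canonical reference — such reads do not overlap the SNP
informatively, and a stable single-origin attribution was preferred over
splitting; the tie is a package decision, logged not split. Multi-SNP
haplotype references are out of scope (one reference per SNP).

## Association testing

Dosage codes the cohort-minor allele (flipping when ALT is major).
Tau-b uses the tie-corrected normalisation; p-values use the normal
approximation on S with tie-corrected variance and a continuity
correction, standard practice at cohort scale where exact enumeration is
infeasible (a permutation fallback exists for small n; at n = 20 the
approximation agrees with a 10^5-permutation estimate to ~0.01).
The test family is every SNP × same-precursor mature × category whose
raw count is positive in ≥ 10 subjects; missing composition cells (a
subject with zero in-window reads for a mature) are excluded pairwise
rather than imputed — 0.5/0.5 = 1 would fabricate signal.
Benjamini–Hochberg runs separately within the full cohort and within
each ancestry stratum across that analysis's full test list, and a pair
is significant iff FDR < 0.05 overall and within at least one stratum.
Genotype PCA (mean-imputed, column-centred, scikit-learn SVD) is
provided for visualising stratification.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* Precursors are i.i.d. uniform ACGT, 60–110 nt (70–110 in the standard
  cohort so both arms always fit), with 5p/3p matures of 20–23 nt set
  8 nt in from each end; a rejection step forces every mature's 16-mer
  prefix to be unique across all references and decoys, guaranteeing
  unambiguous placement for truth-based tests without modelling hairpin
  thermodynamics.
* Genotypes are Hardy–Weinberg draws at per-population allele
  frequencies specified directly per SNP (no Fst model — the simplest
  structure sufficient to exercise stratified association). At most one
  SNP per precursor is simulated; the personalised-reference builder
  itself handles any number.
* Per-subject 5′-category probabilities are a softmax of baseline
  log-odds shifted by `shift × dosage` per configured effect. The
  baseline (canonical 0.55, trim-1 0.10, trim-2 0.08, ext+1 0.07,
  ext+2 0.08, add+2 0.07, seed-sub 0.05; 3′ side canonical 0.60,
  trim-1 0.20, ext+1 0.15, add+2 0.05) puts most mass on the canonical
  cleavage site with trims dominating the variants, as in real
  small-RNA libraries.
* Reads are precursor substrings modified per their sampled labels, with
  non-templated bases forced to differ from the templated base at the
  position they occupy, the adaptor appended verbatim and constant
  Q40 qualities ("I") — the pipeline does no quality filtering, so
  modelling base quality would test nothing.
* Seed-substitution reads never also carry an addition (the combination
  is outside the recoverable taxonomy), and the planted substitution
  never sits on a SNP position with the alt base (it would *be* the alt
  allele). Heterozygous subjects emit reads from each allele with a
  configurable fraction (default 0.5).

What passing tests therefore show: the pipeline exactly inverts its own
generative model wherever inversion is information-theoretically
possible, and reports the ambiguous remainder. What they do not show:
robustness to sequencing error, adaptor synthesis errors, hairpin
secondary structure, linkage disequilibrium between SNPs, or the
U-enriched base composition of real miRNAs.

## Numerical and engineering choices

* All sequences are normalised to DNA (U→T, uppercase) on ingest;
  terminal-base summaries are reported in RNA letters.
* Coordinates are 0-based half-open and transcript-local internally;
  GFF3/VCF 1-based genomic coordinates are converted at the I/O
  boundary, complementing alleles on minus-strand precursors.
* Adaptor matching is exact with a minimum 3′-overlap of 3; exact
  matching keeps the stage deterministic and matches the generator,
  which appends the adaptor verbatim. Untrimmed reads are retained
  (only a length rule excludes reads). Removing a full adaptor can
  expose an insert suffix that equals a short adaptor prefix, so the
  trimmer is not idempotent on adversarial inputs; the tests pin the
  weaker guarantees that hold (no full adaptor in output; fixed points
  for reads with no qualifying suffix).
* The pseudocount is applied as `(count + 0.5) / (total + 0.5)` so each
  ratio is monotone in its own count; a per-category-pseudocount mode
  (ratios summing to 1) is available as a switch. The in-window total is
  the denominator; out-of-window and new isomiRs are excluded from both
  numerator and denominator.
* Student's t is pooled-variance by default with a Welch switch, since
  equal variances are an assumption, not a finding.
* Every simulation consumes a single integer seed; pipeline outputs
  contain no timestamps, so equal seeds give byte-identical runs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the aligner-oracle
comparison on 10^4 (tests) / 3×10^3 (script) random instances, the
round trip on the standard cohort (20 precursors, 40 matures, 200
subjects, 200 reads/subject/miRNA ≈ 1.6 M reads), and the
study-scale association checks at n = 435 subjects with 40/20 detection
replicates and 150/60 null replicates respectively — sizes chosen so the
full suite completes in a few minutes on one CPU while keeping every
binomial error bar small enough for the stated thresholds.

## Known limitations

Indels, multi-substitution isomiRs, quality-aware alignment, A-to-I
editing inference, trans-QTLs, covariate-adjusted association models and
LD pruning are out of scope. 3′-composition ratios are deliberately not
produced: adaptor trimming corrupts 3′-variant calls, so only 5′
composition enters the association stage. The exact-match genome filter
and the canonical-preference tie rule are declared decisions where the
underlying choice is genuinely open.
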