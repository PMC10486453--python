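"""Show the reference-allele bias and its removal by personalised references.

A subject homozygous for the alternative allele of a precursor SNP emits
canonical-length reads that differ from the reference hairpin by one
base.  Aligned against the reference alone they are miscalled as
substitution isomiRs; adding one personalised (alt-allele) reference per
SNP and keeping the earliest-round placement removes the bias entirely.
"""

from isomirqtl import SimulationConfig, SNPSpec, simulate_cohort
from isomirqtl.pipeline import analyze_cohort

cfg = SimulationConfig(
    n_subjects=24, n_precursors=2, precursor_length_range=(70, 100),
    reads_per_subject_per_mirna=40, populations=[("EUR", 1.0)],
    snps=[SNPSpec("rs_exonic", "pre-001", 12, {"EUR": 0.5})],
    baseline_composition={"canonical": 1.0}, baseline_three_prime={"canonical": 1.0},
    seed=5,
)
bundle = simulate_cohort(cfg)
snp = bundle.snps[0]
alt_homs = bundle.genotypes.index[bundle.genotypes[snp.rsid] == 2.0]
target = next(m.id for m in bundle.matures
              if m.precursor_id == snp.precursor_id and m.start <= snp.local_pos < m.end)
print(f"SNP {snp.rsid} at local position {snp.local_pos} inside {target}; "
      f"{len(alt_homs)} alt-homozygous subjects")

for label, aware in [("reference-only", False), ("personalised", True)]:
    cls = analyze_cohort(bundle, min_subjects=1, allele_aware=aware, run_assoc=False)["classified"]
    rows = cls[cls["subject"].isin(alt_homs) & (cls["mature_id"] == target)]
    frac = rows.loc[rows["substitution_class"] != "none", "count"].sum() / rows["count"].sum()
    print(f"{label:15s}: {100 * frac:5.1f}% of alt-homozygote reads called substitution isomiRs")
# reference-only reports 100.0%, personalised 0.0% — every apparent
# "substitution" was the subject's own germline allele.
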