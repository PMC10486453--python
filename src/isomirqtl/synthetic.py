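"""Synthetic small-RNA cohorts with known isomiR ground truth.

The generator emulates the statistical structure the downstream analysis
assumes — hairpin precursors with 5p/3p mature annotations, bi-allelic
precursor SNPs with population-differentiated allele frequencies,
genotype-dependent 5'-isomiR composition, and reads carrying trims,
templated extensions, non-templated additions and seed substitutions with
a fixed 3' adaptor appended — so that every pipeline stage can be tested
against ground truth without any external download.

Model summary:

* Precursor sequences are i.i.d. uniform over {A, C, G, T} with a
  rejection step guaranteeing that each mature miRNA's 16-mer prefix is
  unique across all references and decoys, so truth-based round-trip
  tests are unambiguous by construction.
* Genotypes are drawn under Hardy-Weinberg within each population at that
  population's allele frequency.
* Per-subject 5'-category probabilities follow a logit (softmax) model:
  the baseline composition's log-odds are shifted by ``shift x dosage``
  for every configured effect, mirroring an additive cis-QTL acting on
  cleavage-site choice.
* Reads are precursor substrings modified per their sampled category,
  with non-templated bases forced to differ from the templated base at
  the position they occupy, the adaptor appended verbatim, and a constant
  quality string ("I", Q40).

Single-base non-templated additions are deliberately absent from the
default composition: under the aligner's round precedence a 1-base
addition inside precursor bounds is indistinguishable from a templated
extension carrying a terminal substitution, so the generator plants
2-base additions, which the trimming rounds recover unambiguously.
For the same reason a seed-substitution read never also carries an
addition (the combination is outside the recoverable taxonomy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allele import SNPRecord
from .errors import ConfigurationError, GenerationError
from .io import (
    MatureAnnotation,
    PrecursorRecord,
    revcomp,
    write_fasta,
    write_fastq,
    write_mirbase_gff3,
    write_tsv,
    write_vcf,
)
from .preprocess import DEFAULT_ADAPTOR

BASES = "ACGT"
_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Baseline 5'-category composition (genotype dosage 0).  Chosen to put
#: most mass on the canonical cleavage site with trims dominating the
#: variant classes, as in small-RNA libraries.
DEFAULT_BASELINE_5P = {
    "canonical": 0.55,
    "trim-1": 0.10,
    "trim-2": 0.08,
    "ext+1": 0.07,
    "ext+2": 0.08,
    "add+2": 0.07,
    "sub": 0.05,
}

#: Baseline 3'-end modification mixture, sampled independently of the 5'
#: category (3' variation is more frequent than 5' in real libraries).
DEFAULT_BASELINE_3P = {
    "canonical": 0.60,
    "trim-1": 0.20,
    "ext+1": 0.15,
    "add+2": 0.05,
}

#: 5' upstream / 3' downstream flanking margin between a mature span and
#: the precursor end, leaving room for extensions and additions.
MATURE_MARGIN = 8


@dataclass(frozen=True)
class SNPSpec:
    """A planted bi-allelic SNP inside a precursor.

    ``ref``/``alt`` are transcript-local bases; ``ref=None`` takes the
    generated precursor base, ``alt=None`` samples a differing base.
    ``freq`` maps population label -> alt-allele frequency.
    """

    snp_id: str
    precursor_id: str
    position: int  # 0-based, precursor-local
    freq: dict[str, float]
    ref: str | None = None
    alt: str | None = None


@dataclass(frozen=True)
class EffectSpec:
    """Per-alt-allele log-odds shift of one 5' category of one mature miRNA."""

    snp_id: str
    mature_id: str
    category: str
    shift: float


@dataclass
class SimulationConfig:
    n_subjects: int = 200
    n_precursors: int = 20
    precursor_length_range: tuple[int, int] = (60, 110)
    mature_length_range: tuple[int, int] = (20, 23)
    populations: list[tuple[str, float]] = field(
        default_factory=lambda: [("EUR", 0.8), ("AFR", 0.2)]
    )
    snps: list[SNPSpec] = field(default_factory=list)
    composition_effects: list[EffectSpec] = field(default_factory=list)
    reads_per_subject_per_mirna: int = 200
    adaptor: str = DEFAULT_ADAPTOR
    seed: int = 0
    genome_decoy_count: int = 5
    baseline_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_5P)
    )
    baseline_three_prime: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_3P)
    )
    het_alt_read_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_precursors < 1:
            raise ConfigurationError("n_precursors must be >= 1")
        for name in ("precursor_length_range", "mature_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a positive (lo, hi) range")
        total = sum(f for _, f in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("populations: fractions must sum to 1")
        pop_labels = {label for label, _ in self.populations}
        for snp in self.snps:
            if set(snp.freq) != pop_labels:
                raise ConfigurationError(
                    f"snps: {snp.snp_id} must give a frequency for every population"
                )
            for pop, f in snp.freq.items():
                if not 0.0 < f < 1.0:
                    raise ConfigurationError(
                        f"snps: {snp.snp_id} frequency for {pop} must be in (0,1)"
                    )
        seen_prec = set()
        for snp in self.snps:
            if snp.precursor_id in seen_prec:
                raise ConfigurationError(
                    "snps: at most one SNP per precursor in simulation"
                )
            seen_prec.add(snp.precursor_id)
        snp_ids = {s.snp_id for s in self.snps}
        for eff in self.composition_effects:
            if eff.snp_id not in snp_ids:
                raise ConfigurationError(f"composition_effects: unknown SNP {eff.snp_id}")
            if eff.category not in self.baseline_composition:
                raise ConfigurationError(
                    f"composition_effects: {eff.category!r} not a baseline 5' category"
                )
            if not np.isfinite(eff.shift):
                raise ConfigurationError("composition_effects: shift must be finite")
        if self.reads_per_subject_per_mirna < 1:
            raise ConfigurationError("reads_per_subject_per_mirna must be >= 1")
        if abs(sum(self.baseline_composition.values()) - 1.0) > 1e-9:
            raise ConfigurationError("baseline_composition must sum to 1")
        if abs(sum(self.baseline_three_prime.values()) - 1.0) > 1e-9:
            raise ConfigurationError("baseline_three_prime must sum to 1")
        if not 0.0 <= self.het_alt_read_fraction <= 1.0:
            raise ConfigurationError("het_alt_read_fraction must be in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("precursor_length_range", "mature_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "populations" in raw:
            raw["populations"] = [(p["label"], float(p["fraction"])) for p in raw["populations"]]
        raw["snps"] = [SNPSpec(**s) for s in raw.get("snps", [])]
        raw["composition_effects"] = [EffectSpec(**e) for e in raw.get("composition_effects", [])]
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class IsomiRLabel:
    """A generative isomiR label: signed templated shifts, additions, substitution.

    ``five_shift`` follows the classifier's convention (+k templated
    extension upstream, -k trim); ``add5``/``add3`` count non-templated
    terminal bases; ``sub`` is (1-based mature position, base or None to
    sample).
    """

    five_shift: int = 0
    add5: int = 0
    three_shift: int = 0
    add3: int = 0
    sub: tuple[int, str | None] | None = None


def build_read_from_label(
    precursor_seq: str, mature: MatureAnnotation, label: IsomiRLabel, rng: np.random.Generator
) -> str:
    """Realise one read from its label on (an allele of) a precursor.

    Non-templated bases are sampled to differ from the templated base at
    the position they would occupy, making them recoverable as additions.
    Raises :class:`GenerationError` when the label leaves the precursor.
    """
    start = mature.start - label.five_shift
    end = mature.end + label.three_shift
    if start < 0 or end > len(precursor_seq) or start >= end:
        raise GenerationError(
            f"templated span [{start},{end}) outside precursor of length {len(precursor_seq)}"
        )
    if start - label.add5 < 0 or end + label.add3 > len(precursor_seq):
        raise GenerationError("non-templated addition would leave precursor bounds")
    core = list(precursor_seq[start:end])
    if label.sub is not None:
        pos1, base = label.sub
        idx = mature.start + pos1 - 1 - start
        if not 0 <= idx < len(core):
            raise GenerationError(f"substitution at mature position {pos1} outside the read")
        templated = core[idx]
        if base is None:
            base = rng.choice([b for b in BASES if b != templated])
        elif base == templated:
            raise GenerationError("substitution base equals the templated base")
        core[idx] = base
    prefix = "".join(
        rng.choice([b for b in BASES if b != precursor_seq[start - label.add5 + i]])
        for i in range(label.add5)
    )
    suffix = "".join(
        rng.choice([b for b in BASES if b != precursor_seq[end + i]])
        for i in range(label.add3)
    )
    return prefix + "".join(core) + suffix


def _concrete_variants(
    template: str, mature: MatureAnnotation, label: IsomiRLabel
) -> list[str]:
    """Enumerate every read string realisable from a label with fixed sub base.

    The templated core is deterministic; non-templated positions each have
    three admissible bases (anything but the templated one), so a label
    with a additions has 3^a concrete variants, enumerated in a stable
    order.  ``label.sub`` must carry an explicit base.
    """
    from itertools import product

    start = mature.start - label.five_shift
    end = mature.end + label.three_shift
    if start < 0 or end > len(template) or start >= end:
        raise GenerationError("templated span outside precursor")
    if start - label.add5 < 0 or end + label.add3 > len(template):
        raise GenerationError("non-templated addition would leave precursor bounds")
    core = list(template[start:end])
    if label.sub is not None:
        pos1, base = label.sub
        idx = mature.start + pos1 - 1 - start
        if base is None:
            raise GenerationError("_concrete_variants needs an explicit substitution base")
        core[idx] = base
    core_s = "".join(core)
    prefix_opts = [
        [b for b in BASES if b != template[start - label.add5 + i]] for i in range(label.add5)
    ]
    suffix_opts = [[b for b in BASES if b != template[end + i]] for i in range(label.add3)]
    out = []
    for pre in product(*prefix_opts) if prefix_opts else [()]:
        for suf in product(*suffix_opts) if suffix_opts else [()]:
            out.append("".join(pre) + core_s + "".join(suf))
    return out


def _label_for_categories(c5: str, c3: str, seed_sub_pos: int) -> IsomiRLabel:
    """Translate (5' category, 3' category) strings to a generative label."""
    kw = {}
    if c5 == "sub":
        kw["sub"] = (seed_sub_pos, None)
    elif c5.startswith("trim-"):
        kw["five_shift"] = -int(c5.split("-")[1])
    elif c5.startswith("ext+"):
        kw["five_shift"] = int(c5.split("+")[1])
    elif c5.startswith("add+"):
        kw["add5"] = int(c5.split("+")[1])
    elif c5 != "canonical":
        raise ConfigurationError(f"unknown 5' category {c5!r}")
    if c3.startswith("trim-"):
        kw["three_shift"] = -int(c3.split("-")[1])
    elif c3.startswith("ext+"):
        kw["three_shift"] = int(c3.split("+")[1])
    elif c3.startswith("add+"):
        kw["add3"] = int(c3.split("+")[1])
    elif c3 != "canonical":
        raise ConfigurationError(f"unknown 3' category {c3!r}")
    return IsomiRLabel(**kw)


def category_probabilities(
    baseline: dict[str, float], effects: list[tuple[str, float]], dosage: float
) -> dict[str, float]:
    """Softmax of baseline log-odds shifted by ``shift x dosage`` per effect.

    ``effects`` lists (category, per-allele log-odds shift) pairs acting
    on this mature miRNA.
    """
    cats = list(baseline)
    logits = np.log(np.array([baseline[c] for c in cats], dtype=float))
    for cat, shift in effects:
        logits[cats.index(cat)] += shift * dosage
    w = np.exp(logits - logits.max())
    w /= w.sum()
    return dict(zip(cats, w))


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """In-memory synthetic cohort: references, annotations, genotypes, reads, truth."""

    config: SimulationConfig
    precursors: list[PrecursorRecord]
    matures: list[MatureAnnotation]
    decoys: dict[str, str]
    snps: list[SNPRecord]
    genotypes: pd.DataFrame  # subjects x snp ALT dosage
    metadata: pd.DataFrame  # subject, population
    reads: pd.DataFrame  # subject, sequence (insert, no adaptor), count
    truth: pd.DataFrame  # one row per (subject, sequence, label)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the standard file bundle; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "precursor_fasta": out / "precursors.fa",
            "decoy_fasta": out / "genome_decoys.fa",
            "gff3": out / "annotation.gff3",
            "vcf": out / "variants.vcf",
            "metadata": out / "metadata.tsv",
            "truth": out / "truth.tsv",
            "fastq_dir": out / "reads",
        }
        write_fasta(paths["precursor_fasta"], [(p.id, p.sequence) for p in self.precursors], rna=True)
        write_fasta(paths["decoy_fasta"], sorted(self.decoys.items()))
        write_mirbase_gff3(paths["gff3"], self.precursors, self.matures)
        variants = [
            {"chrom": s.chrom, "pos": s.pos, "id": s.rsid, "ref": s.ref, "alt": s.alt}
            for s in self.snps
        ]
        write_vcf(paths["vcf"], variants, list(self.genotypes.index), self.genotypes)
        write_tsv(paths["metadata"], self.metadata)
        write_tsv(paths["truth"], self.truth)
        paths["fastq_dir"].mkdir(exist_ok=True)
        for subject, grp in self.reads.groupby("subject"):
            recs = []
            i = 0
            for row in grp.itertuples(index=False):
                full = row.sequence + self.config.adaptor
                for _ in range(int(row.count)):
                    recs.append((f"{subject}_r{i}", full))
                    i += 1
            write_fastq(paths["fastq_dir"] / f"{subject}.fastq", recs)
        return paths


def _sample_precursors(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[list[PrecursorRecord], list[MatureAnnotation], dict[str, str]]:
    decoys = {
        f"decoy_{i+1:03d}": "".join(rng.choice(list(BASES), size=150))
        for i in range(cfg.genome_decoy_count)
    }
    decoy_blob = " ".join(list(decoys.values()) + [revcomp(s) for s in decoys.values()])
    lo, hi = cfg.precursor_length_range
    mlo, mhi = cfg.mature_length_range
    precursors: list[PrecursorRecord] = []
    matures: list[MatureAnnotation] = []
    all_seqs: list[str] = []
    prefixes: list[str] = []
    chrom_offset: dict[str, int] = {}
    for i in range(cfg.n_precursors):
        pid = f"pre-{i+1:03d}"
        for _attempt in range(200):
            plen = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(list(BASES), size=plen))
            l5 = int(rng.integers(mlo, mhi + 1))
            l3 = int(rng.integers(mlo, mhi + 1))
            spans = []
            if plen >= 2 * MATURE_MARGIN + l5 + l3:
                spans = [("5p", MATURE_MARGIN, MATURE_MARGIN + l5),
                         ("3p", plen - MATURE_MARGIN - l3, plen - MATURE_MARGIN)]
            else:
                spans = [("5p", MATURE_MARGIN, MATURE_MARGIN + l5)]
            cand_prefixes = [seq[s:s + 16] for _, s, _ in spans]
            blob = " ".join(all_seqs + [seq])
            ok = all(blob.count(p) == 1 and p not in decoy_blob for p in cand_prefixes)
            ok = ok and all(p not in seq for p in prefixes)
            if ok:
                break
        else:
            raise GenerationError(f"could not sample a unique precursor for {pid}")
        chrom = f"chr{(i % 5) + 1}"
        offset = chrom_offset.get(chrom, 0)
        start = offset + 1001
        chrom_offset[chrom] = offset + plen + 1000
        strand = "+" if i % 2 == 0 else "-"
        precursors.append(
            PrecursorRecord(id=pid, sequence=seq, chrom=chrom, start=start,
                            end=start + plen - 1, strand=strand)
        )
        all_seqs.append(seq)
        prefixes.extend(cand_prefixes)
        for arm, s, e in spans:
            matures.append(
                MatureAnnotation(id=f"miR-{i+1:03d}-{arm}", precursor_id=pid, start=s, end=e)
            )
    return precursors, matures, decoys


def _assign_populations(cfg: SimulationConfig) -> list[str]:
    """Deterministic largest-remainder assignment of subjects to populations."""
    n = cfg.n_subjects
    counts = {label: int(np.floor(frac * n)) for label, frac in cfg.populations}
    remainder = n - sum(counts.values())
    by_frac = sorted(cfg.populations, key=lambda lf: -(lf[1] * n - np.floor(lf[1] * n)))
    for label, _ in by_frac[:remainder]:
        counts[label] += 1
    labels: list[str] = []
    for label, _ in cfg.populations:
        labels.extend([label] * counts[label])
    return labels


def simulate_cohort(config: SimulationConfig, out_dir: str | Path | None = None) -> CohortBundle:
    """Generate the full synthetic cohort; optionally write the file bundle.

    All randomness flows from ``config.seed``; identical configs give
    byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    precursors, matures, decoys = _sample_precursors(config, rng)
    prec_by_id = {p.id: p for p in precursors}
    matures_by_prec: dict[str, list[MatureAnnotation]] = {}
    for m in matures:
        matures_by_prec.setdefault(m.precursor_id, []).append(m)
    mature_ids = {m.id for m in matures}
    for eff in config.composition_effects:
        if eff.mature_id not in mature_ids:
            raise ConfigurationError(f"composition_effects: unknown mature {eff.mature_id}")

    # resolve SNPs against the generated sequences
    snps: list[SNPRecord] = []
    for spec in config.snps:
        if spec.precursor_id not in prec_by_id:
            raise ConfigurationError(f"snps: unknown precursor {spec.precursor_id}")
        prec = prec_by_id[spec.precursor_id]
        if not 0 <= spec.position < len(prec.sequence):
            raise ConfigurationError(
                f"snps: {spec.snp_id} position {spec.position} outside {prec.id}"
            )
        local_ref = prec.sequence[spec.position]
        if spec.ref is not None and spec.ref != local_ref:
            raise ConfigurationError(
                f"snps: {spec.snp_id} ref {spec.ref} != precursor base {local_ref}"
            )
        local_alt = spec.alt or str(rng.choice([b for b in BASES if b != local_ref]))
        if local_alt == local_ref:
            raise ConfigurationError(f"snps: {spec.snp_id} ref == alt")
        gpos = prec.local_to_genomic(spec.position)
        if prec.strand == "+":
            gref, galt = local_ref, local_alt
        else:
            gref, galt = _COMPL[local_ref], _COMPL[local_alt]
        snps.append(
            SNPRecord(
                rsid=spec.snp_id, chrom=prec.chrom, pos=gpos, ref=gref, alt=galt,
                maf=float("nan"), precursor_id=prec.id, local_pos=spec.position,
                local_ref=local_ref, local_alt=local_alt,
            )
        )

    # subjects, populations, genotypes under Hardy-Weinberg
    pops = _assign_populations(config)
    subjects = [f"S{i+1:04d}" for i in range(config.n_subjects)]
    metadata = pd.DataFrame({"subject": subjects, "population": pops})
    geno = {}
    for spec, snp in zip(config.snps, snps):
        af = np.array([spec.freq[p] for p in pops])
        geno[snp.rsid] = rng.binomial(2, af).astype(float)
    genotypes = pd.DataFrame(geno, index=subjects)
    # cohort MAF becomes known only now
    snps = [
        replace(
            s,
            maf=float(min(genotypes[s.rsid].mean() / 2.0, 1 - genotypes[s.rsid].mean() / 2.0)),
        )
        for s in snps
    ]
    snp_by_prec = {s.precursor_id: s for s in snps}

    # per-mature effect lists and fixed seed-substitution positions
    effects_by_mature: dict[str, list[tuple[str, str, float]]] = {}
    for eff in config.composition_effects:
        effects_by_mature.setdefault(eff.mature_id, []).append(
            (eff.snp_id, eff.category, eff.shift)
        )
    # one fixed seed substitution per mature: position in 2..7 and a base
    # differing from the reference base there (sampled once, cohort-wide).
    # Never planted on a SNP position: a substitution reading the alt base
    # there would be indistinguishable from an alt-allele canonical read.
    seed_sub: dict[str, tuple[int, str]] = {}
    for m in matures:
        snp = snp_by_prec.get(m.precursor_id)
        choices = [
            p for p in range(2, 8)
            if snp is None or m.start + p - 1 != snp.local_pos
        ]
        pos1 = int(rng.choice(choices))
        ref_base = prec_by_id[m.precursor_id].sequence[m.start + pos1 - 1]
        seed_sub[m.id] = (pos1, str(rng.choice([b for b in BASES if b != ref_base])))

    c3_cats = list(config.baseline_three_prime)
    c3_probs = np.array([config.baseline_three_prime[c] for c in c3_cats])
    # seed-substitution reads never carry an addition (unrecoverable combo)
    c3_safe = np.array(
        [0.0 if c.startswith("add") else config.baseline_three_prime[c] for c in c3_cats]
    )
    c3_safe = c3_safe / c3_safe.sum()

    read_counts: dict[tuple[str, str], int] = {}
    truth_rows: list[dict] = []
    c5_cats = list(config.baseline_composition)
    for si, subject in enumerate(subjects):
        for mat in matures:
            prec = prec_by_id[mat.precursor_id]
            snp = snp_by_prec.get(prec.id)
            dosage = float(genotypes.loc[subject, snp.rsid]) if snp else 0.0
            effects = [
                (cat, shift)
                for snp_id, cat, shift in effects_by_mature.get(mat.id, [])
                if snp and snp_id == snp.rsid
            ]
            probs = category_probabilities(config.baseline_composition, effects, dosage)
            n5 = rng.multinomial(
                config.reads_per_subject_per_mirna, [probs[c] for c in c5_cats]
            )
            for c5, k5 in zip(c5_cats, n5):
                if k5 == 0:
                    continue
                pvec = c3_safe if c5 == "sub" else c3_probs
                n3 = rng.multinomial(k5, pvec)
                for c3, k in zip(c3_cats, n3):
                    if k == 0:
                        continue
                    if snp is None or dosage == 0:
                        n_alt = 0
                    elif dosage == 2:
                        n_alt = k
                    else:
                        n_alt = int(rng.binomial(k, config.het_alt_read_fraction))
                    for allele, kk in (("ref", k - n_alt), ("alt", n_alt)):
                        if kk == 0:
                            continue
                        template = prec.sequence
                        if allele == "alt":
                            template = (
                                template[: snp.local_pos]
                                + snp.local_alt
                                + template[snp.local_pos + 1 :]
                            )
                        pos1, sub_base = seed_sub[mat.id]
                        label = _label_for_categories(c5, c3, pos1)
                        if label.sub is not None:
                            # on the alt template the reference base may differ;
                            # keep the planted base unless it became templated
                            if template[mat.start + pos1 - 1] == sub_base:
                                alt_choices = [
                                    b for b in BASES if b != template[mat.start + pos1 - 1]
                                ]
                                label = replace(label, sub=(pos1, alt_choices[0]))
                            else:
                                label = replace(label, sub=(pos1, sub_base))
                        variants = _concrete_variants(template, mat, label)
                        if len(variants) == 1:
                            alloc = [kk]
                        else:
                            alloc = rng.multinomial(kk, [1.0 / len(variants)] * len(variants))
                        for seq, cnt in zip(variants, alloc):
                            if cnt == 0:
                                continue
                            read_counts[(subject, seq)] = (
                                read_counts.get((subject, seq), 0) + int(cnt)
                            )
                            truth_rows.append(
                                {
                                    "subject": subject,
                                    "sequence": seq,
                                    "precursor_id": prec.id,
                                    "mature_id": mat.id,
                                    "five_category": c5,
                                    "three_category": c3,
                                    "allele": allele,
                                    "templated_start": mat.start - label.five_shift,
                                    "templated_end": mat.end + label.three_shift,
                                    "count": int(cnt),
                                }
                            )

    reads = (
        pd.DataFrame(
            [(s, q, c) for (s, q), c in read_counts.items()],
            columns=["subject", "sequence", "count"],
        )
        .sort_values(["subject", "sequence"])
        .reset_index(drop=True)
    )
    truth = (
        pd.DataFrame(truth_rows)
        .groupby(
            [
                "subject", "sequence", "precursor_id", "mature_id", "five_category",
                "three_category", "allele", "templated_start", "templated_end",
            ],
            as_index=False,
        )["count"]
        .sum()
        .sort_values(["subject", "sequence", "mature_id", "five_category", "three_category"])
        .reset_index(drop=True)
    )
    bundle = CohortBundle(
        config=config, precursors=precursors, matures=matures, decoys=decoys,
        snps=snps, genotypes=genotypes, metadata=metadata, reads=reads, truth=truth,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def simulate_association_study(
    seed: int,
    n_subjects: int = 435,
    maf: float = 0.33,
    shift: float = -0.8,
    target_category: str = "ext+2",
    n_snps: int = 4,
    reads_per_subject: int = 200,
    populations: list[tuple[str, float]] | None = None,
    baseline: dict[str, float] | None = None,
):
    """Genotypes and composition counts for an association study, no reads.

    Skips sequence-level simulation: category counts are drawn directly
    from the genotype-dependent softmax model, which is exactly what the
    downstream association scan sees after alignment and classification.
    One SNP (``rs_t001``) carries a per-alt-allele log-odds ``shift`` on
    ``target_category`` of its 3p mature; the remaining ``n_snps - 1``
    SNPs are null.  Returns ``(dosages, composition_long, strata,
    snp_to_matures, planted)`` where ``planted`` is the (snp, mature,
    category) triple of the true effect.

    With ``shift=0`` every SNP is null (the global-null design for
    false-discovery-rate calibration).
    """
    rng = np.random.default_rng(seed)
    populations = populations or [("EUR", 0.8), ("AFR", 0.2)]
    baseline = baseline or dict(DEFAULT_BASELINE_5P)
    cats = list(baseline)
    base_logit = np.log(np.array([baseline[c] for c in cats]))

    n = n_subjects
    counts_per_pop = {label: int(np.floor(frac * n)) for label, frac in populations}
    counts_per_pop[populations[0][0]] += n - sum(counts_per_pop.values())
    pops = [label for label, _ in populations for _ in range(counts_per_pop[label])]
    subjects = [f"S{i+1:04d}" for i in range(n)]
    strata = pd.Series(pops, index=subjects, name="population")

    snp_ids = [f"rs_t{i+1:03d}" for i in range(n_snps)]
    dosages = pd.DataFrame(
        {sid: rng.binomial(2, maf, size=n).astype(float) for sid in snp_ids},
        index=subjects,
    )
    snp_to_matures = {
        sid: [f"miR-t{i+1:03d}-5p", f"miR-t{i+1:03d}-3p"] for i, sid in enumerate(snp_ids)
    }
    planted = (snp_ids[0], snp_to_matures[snp_ids[0]][1], target_category)

    rows = []
    t_idx = cats.index(target_category)
    for sid, matures_for_snp in snp_to_matures.items():
        dos = dosages[sid].to_numpy()
        for mid in matures_for_snp:
            logits = np.tile(base_logit, (n, 1))
            if shift != 0 and (sid, mid) == (planted[0], planted[1]):
                logits[:, t_idx] += shift * dos
            w = np.exp(logits - logits.max(axis=1, keepdims=True))
            w /= w.sum(axis=1, keepdims=True)
            counts = np.array([rng.multinomial(reads_per_subject, w[i]) for i in range(n)])
            totals = counts.sum(axis=1)
            for j, cat in enumerate(cats):
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": subjects,
                            "mature_id": mid,
                            "category": cat,
                            "count": counts[:, j],
                            "total": totals,
                            "ratio": (counts[:, j] + 0.5) / (totals + 0.5),
                        }
                    )
                )
    composition_long = pd.concat(rows, ignore_index=True)
    return dosages, composition_long, strata, snp_to_matures, planted


def standard_cohort_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The reference study design the tests and examples run on.

    20 precursors (two mature arms each where length permits), 200
    subjects in two populations (EUR 80% / AFR 20%), 200 reads per
    subject per mature miRNA, four precursor SNPs with
    population-differentiated alt frequencies — one with a negative
    per-allele log-odds effect (-0.8) on the 2-base 5'-extension of its
    3p mature, one inside a mature span (exercising allele-aware
    alignment), two null.
    """
    snps = [
        SNPSpec("rs1001", "pre-001", 5, {"EUR": 0.30, "AFR": 0.60}),
        SNPSpec("rs1002", "pre-002", 12, {"EUR": 0.25, "AFR": 0.45}),
        SNPSpec("rs1003", "pre-003", 5, {"EUR": 0.40, "AFR": 0.35}),
        SNPSpec("rs1004", "pre-004", 5, {"EUR": 0.20, "AFR": 0.30}),
    ]
    effects = [EffectSpec("rs1001", "miR-001-3p", "ext+2", -0.8)]
    # precursors of >= 70 nt always fit both arms plus flanking margins,
    # so the standard cohort has exactly two matures per precursor
    kwargs = {"snps": snps, "composition_effects": effects,
              "precursor_length_range": (70, 110)}
    kwargs.update(overrides)
    if not kwargs["snps"]:
        kwargs["composition_effects"] = [
            e for e in kwargs["composition_effects"]
            if e.snp_id in {s.snp_id for s in kwargs["snps"]}
        ]
    cfg = SimulationConfig(seed=seed, **kwargs)
    if "baseline_composition" in overrides:
        # effects must target an existing baseline category
        kwargs["composition_effects"] = [
            e for e in kwargs["composition_effects"]
            if e.category in cfg.baseline_composition
        ]
        cfg.composition_effects = kwargs["composition_effects"]
    cfg.validate()
    return cfg
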