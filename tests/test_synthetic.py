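"""Synthetic cohort generator: determinism, Hardy-Weinberg, the logit model,
read construction, config validation."""

import numpy as np
import pandas as pd
import pytest

from isomirqtl.errors import ConfigurationError, GenerationError
from isomirqtl.io import MatureAnnotation
from isomirqtl.synthetic import (
    EffectSpec,
    IsomiRLabel,
    SimulationConfig,
    SNPSpec,
    build_read_from_label,
    category_probabilities,
    simulate_cohort,
    standard_cohort_config,
)

PREC = "AAAGCTTACGGATCCGTTAGCGTACCGGTTAACCGATCGGATTACGCTAGCATGCAAGCTTGGA"
MAT = MatureAnnotation(id="m", precursor_id="p", start=10, end=32)


class TestBuildRead:
    def test_canonical_label_returns_mature_subsequence(self):
        rng = np.random.default_rng(0)
        assert build_read_from_label(PREC, MAT, IsomiRLabel(), rng) == PREC[10:32]

    def test_trim_two_removes_first_two_bases(self):
        rng = np.random.default_rng(0)
        out = build_read_from_label(PREC, MAT, IsomiRLabel(five_shift=-2), rng)
        assert out == PREC[12:32]

    def test_addition_base_differs_from_templated_upstream_base(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = build_read_from_label(PREC, MAT, IsomiRLabel(add5=1), rng)
            assert out[1:] == PREC[10:32]
            assert out[0] != PREC[9]

    def test_substitution_base_differs_from_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = build_read_from_label(PREC, MAT, IsomiRLabel(sub=(4, None)), rng)
            assert out[3] != PREC[13]
            assert out[:3] == PREC[10:13] and out[4:] == PREC[14:32]

    def test_out_of_bounds_label_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(GenerationError):
            build_read_from_label(PREC, MAT, IsomiRLabel(five_shift=11), rng)
        with pytest.raises(GenerationError):
            build_read_from_label(
                PREC, MatureAnnotation(id="m", precursor_id="p", start=1, end=23),
                IsomiRLabel(add5=2), rng,
            )


class TestLogitModel:
    def test_zero_shift_recovers_baseline(self):
        base = {"canonical": 0.6, "trim-1": 0.4}
        probs = category_probabilities(base, [], dosage=2)
        assert probs["canonical"] == pytest.approx(0.6)

    def test_negative_shift_strictly_decreasing_in_dosage(self):
        base = {"canonical": 0.55, "ext+2": 0.08, "trim-1": 0.37}
        p = [category_probabilities(base, [("ext+2", -1.0)], d)["ext+2"] for d in (0, 1, 2)]
        assert p[0] > p[1] > p[2]
        # analytic check at dosage 1: softmax of shifted logits
        logits = np.log([0.55, 0.08, 0.37])
        logits[1] -= 1.0
        expected = np.exp(logits)[1] / np.exp(logits).sum()
        assert p[1] == pytest.approx(expected)

    def test_mean_simulated_probability_decreases_with_dosage(self):
        # the generator's composition follows the logit model
        cfg = standard_cohort_config(seed=21, n_subjects=60, n_precursors=4,
                                     reads_per_subject_per_mirna=400)
        bundle = simulate_cohort(cfg)
        truth = bundle.truth
        target = truth[truth["mature_id"] == "miR-001-3p"]
        frac = (
            target.groupby("subject")
            .apply(
                lambda g: g.loc[g["five_category"] == "ext+2", "count"].sum()
                / g["count"].sum(),
                include_groups=False,
            )
        )
        dosage = bundle.genotypes["rs1001"]
        means = frac.groupby(dosage.loc[frac.index]).mean()
        assert means.loc[0.0] > means.loc[1.0] > means.loc[2.0]


class TestHardyWeinberg:
    def test_dosage_mean_converges_to_twice_allele_frequency(self):
        cfg = SimulationConfig(
            n_subjects=1000, n_precursors=2, reads_per_subject_per_mirna=1,
            populations=[("EUR", 1.0)],
            snps=[SNPSpec("rs1", "pre-001", 5, {"EUR": 0.3})],
            seed=5,
        )
        bundle = simulate_cohort(cfg)
        dos = bundle.genotypes["rs1"]
        se = np.sqrt(2 * 0.3 * 0.7 / 1000)
        assert abs(dos.mean() - 0.6) < 3 * se
        # genotype class frequencies consistent with HWE
        counts = dos.value_counts(normalize=True)
        assert counts.get(2.0, 0) == pytest.approx(0.09, abs=0.03)


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        cfg = standard_cohort_config(seed=9, n_subjects=6, n_precursors=4,
                                     reads_per_subject_per_mirna=30)
        p1 = simulate_cohort(cfg, tmp_path / "a").write(tmp_path / "a")
        p2 = simulate_cohort(cfg, tmp_path / "b").write(tmp_path / "b")
        for key in ["precursor_fasta", "decoy_fasta", "gff3", "vcf", "metadata", "truth"]:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
        for fq in sorted((tmp_path / "a" / "reads").iterdir()):
            assert fq.read_bytes() == (tmp_path / "b" / "reads" / fq.name).read_bytes()

    def test_different_seed_different_cohort(self):
        a = simulate_cohort(standard_cohort_config(seed=1, n_subjects=4, n_precursors=4,
                                                   reads_per_subject_per_mirna=20))
        b = simulate_cohort(standard_cohort_config(seed=2, n_subjects=4, n_precursors=4,
                                                   reads_per_subject_per_mirna=20))
        assert not a.reads.equals(b.reads)


class TestNullModel:
    def test_zero_effects_give_tau_centered_at_zero(self):
        # no composition effect: dosage-ratio correlation is null by construction
        from isomirqtl.association import kendall_tau_b
        from isomirqtl.synthetic import simulate_association_study

        taus = []
        for seed in range(30):
            dosages, comp, _, s2m, planted = simulate_association_study(
                seed=seed, n_subjects=80, shift=0.0, n_snps=1, reads_per_subject=100
            )
            cell = comp[(comp["mature_id"] == planted[1]) & (comp["category"] == planted[2])]
            y = cell.set_index("subject")["ratio"]
            x = dosages[planted[0]]
            taus.append(kendall_tau_b(x.to_numpy(), y.loc[x.index].to_numpy()))
        assert abs(np.mean(taus)) < 3 * np.std(taus) / np.sqrt(len(taus)) + 0.02


class TestTruthCoverage:
    def test_every_read_has_a_truth_record(self, small_cohort):
        reads_total = small_cohort.reads["count"].sum()
        truth_total = small_cohort.truth["count"].sum()
        assert reads_total == truth_total
        per_seq_reads = small_cohort.reads.groupby(["subject", "sequence"])["count"].sum()
        per_seq_truth = small_cohort.truth.groupby(["subject", "sequence"])["count"].sum()
        assert per_seq_reads.equals(per_seq_truth)


class TestConfigValidation:
    def test_population_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="populations"):
            SimulationConfig(populations=[("EUR", 0.5), ("AFR", 0.2)]).validate()

    def test_effect_on_unknown_snp_rejected(self):
        with pytest.raises(ConfigurationError, match="composition_effects"):
            SimulationConfig(
                composition_effects=[EffectSpec("rs_nope", "m", "ext+2", -1.0)]
            ).validate()

    def test_snp_frequency_must_be_open_interval(self):
        with pytest.raises(ConfigurationError, match="frequency"):
            SimulationConfig(
                snps=[SNPSpec("rs1", "pre-001", 5, {"EUR": 1.0, "AFR": 0.5})]
            ).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg_path = tmp_path / "sim.yaml"
        cfg_path.write_text(
            "n_subjects: 8\nn_precursors: 4\nreads_per_subject_per_mirna: 20\n"
            "seed: 3\npopulations:\n  - {label: EUR, fraction: 1.0}\n"
            "snps:\n  - {snp_id: rs1, precursor_id: pre-001, position: 5, freq: {EUR: 0.4}}\n"
        )
        cfg = SimulationConfig.from_yaml(cfg_path)
        assert cfg.n_subjects == 8 and cfg.snps[0].snp_id == "rs1"
        bundle = simulate_cohort(cfg)
        assert len(bundle.metadata) == 8
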