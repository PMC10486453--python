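"""IsomiR taxonomy: mature assignment, end-shift classes, census, round trip."""

import numpy as np
import pandas as pd
import pytest

from isomirqtl.align import IsomiRAlignment
from isomirqtl.classify import (
    assign_mature,
    classify_alignment,
    classify_isomir,
    subtype_census,
    terminal_base_frequencies,
)
from isomirqtl.errors import ConfigurationError
from isomirqtl.io import MatureAnnotation

MATURE = MatureAnnotation(id="miR-x-5p", precursor_id="p", start=10, end=32)  # 22 nt


def _aln(start, end, prefix="", suffix="", sub_pos=None, sub_read=None, round_=None):
    if round_ is None:
        round_ = "R1" if sub_pos is not None else ("R0" if not (prefix or suffix) else "T" + str(len(prefix) + len(suffix)))
    return IsomiRAlignment(
        sequence="N", precursor_id="p", start=start, end=end, round=round_,
        prefix=prefix, suffix=suffix, sub_pos=sub_pos,
        sub_ref="A" if sub_pos is not None else None, sub_read=sub_read,
    )


class TestAssignMature:
    M2 = MatureAnnotation(id="miR-x-3p", precursor_id="p", start=40, end=62)

    def test_exact_span_assigned(self):
        assert assign_mature(_aln(10, 32), [MATURE, self.M2]) == "miR-x-5p"

    @pytest.mark.parametrize("overlap,expect", [(9, "NEW"), (10, "miR-x-3p")])
    def test_new_isomir_threshold(self, overlap, expect):
        # templated span ending inside the 3p mature with the stated overlap
        aln = _aln(40 + overlap - 20, 40 + overlap)
        assert assign_mature(aln, [self.M2]) == expect

    def test_no_matures_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            assign_mature(_aln(10, 32), [])


class TestClassifyIsomir:
    def test_canonical_identity(self):
        cls = classify_isomir(_aln(10, 32), MATURE)
        assert cls.is_canonical
        assert cls.five_category == "canonical" and cls.three_prime == "canonical"

    def test_five_prime_extension_plus_two(self):
        cls = classify_isomir(_aln(8, 32), MATURE)
        assert cls.five_prime == "ext+2" and cls.five_shift == 2
        assert cls.five_category == "ext+2"

    def test_five_prime_trim_minus_two(self):
        cls = classify_isomir(_aln(12, 32), MATURE)
        assert cls.five_prime == "trim-2" and cls.five_shift == -2

    def test_seed_substitution_is_5sSub(self):
        # substitution at mature position 4 -> precursor-local 13
        cls = classify_isomir(_aln(10, 32, sub_pos=13, sub_read="G"), MATURE)
        assert cls.substitution_class == "5sSub"
        assert cls.five_category == "sub"

    def test_first_base_substitution_is_5Sub(self):
        cls = classify_isomir(_aln(10, 32, sub_pos=10, sub_read="G"), MATURE)
        assert cls.substitution_class == "5Sub"

    def test_final_base_substitution_is_3Sub(self):
        cls = classify_isomir(_aln(10, 32, sub_pos=31, sub_read="G"), MATURE)
        assert cls.substitution_class == "3Sub"
        assert cls.five_category == "canonical"  # 5' terminus untouched

    def test_internal_substitution_is_Sub(self):
        cls = classify_isomir(_aln(10, 32, sub_pos=20, sub_read="G"), MATURE)
        assert cls.substitution_class == "Sub"

    def test_upstream_prefix_is_addition(self):
        cls = classify_isomir(_aln(10, 32, prefix="GG"), MATURE)
        assert cls.five_prime == "add+2" and cls.five_category == "add+2"

    def test_prefix_replacing_mature_bases_is_terminal_substitution_run(self):
        # templated span starts 2 into the mature; 2-base prefix sits on
        # mature positions 1-2 -> multi-base 5' substitution
        cls = classify_isomir(_aln(12, 32, prefix="GG"), MATURE)
        assert cls.substitution_class == "5mSub"
        assert cls.five_category == "sub"

    def test_single_base_prefix_on_mature_position_one_is_5Sub(self):
        cls = classify_isomir(_aln(11, 32, prefix="G"), MATURE)
        assert cls.substitution_class == "5Sub"

    def test_downstream_suffix_is_3p_addition(self):
        cls = classify_isomir(_aln(10, 32, suffix="GG"), MATURE)
        assert cls.three_prime == "add+2"

    def test_antisymmetry_of_signed_shifts(self):
        ext = classify_isomir(_aln(8, 32), MATURE)
        trim = classify_isomir(_aln(12, 32), MATURE)
        assert ext.five_shift == -trim.five_shift == 2


class TestTaxonomyExhaustive:
    def test_every_alignment_gets_exactly_one_class(self):
        matures = [MATURE]
        rng = np.random.default_rng(5)
        for _ in range(300):
            start = int(rng.integers(2, 20))
            end = start + int(rng.integers(16, 25))
            if end > 60:
                continue
            kind = rng.integers(0, 3)
            if kind == 0:
                aln = _aln(start, end)
            elif kind == 1:
                aln = _aln(start, end, prefix="G" * int(rng.integers(1, 3)))
            else:
                aln = _aln(start, end, sub_pos=int(rng.integers(start, end)), sub_read="G")
            cls = classify_alignment(aln, matures)
            assert cls.mature_id in {"miR-x-5p", "NEW"}
            if not cls.is_new:
                assert cls.five_category in {
                    "canonical", "sub",
                    *{f"trim-{k}" for k in range(1, 20)},
                    *{f"ext+{k}" for k in range(1, 20)},
                    *{f"add+{m}" for m in range(1, 6)},
                }


class TestTerminalBaseFrequencies:
    def _frame(self, seqs, canonical=True):
        return pd.DataFrame(
            {
                "sequence": seqs,
                "is_canonical": canonical,
                "substitution_class": "none" if canonical else "5sSub",
                "count": 1,
            }
        )

    def test_counting_over_distinct_sequences(self):
        frame = self._frame(["TAGCAAGCTT", "TGGACCATGG", "AAGCTTCCAA"])
        freq = terminal_base_frequencies(frame, "canonical")
        assert freq["U"] == pytest.approx(2 / 3)
        assert freq["A"] == pytest.approx(1 / 3)

    def test_frequencies_sum_to_one(self):
        frame = self._frame(["AAGG", "CAGG", "GAGG", "TAGG", "TCGG"])
        assert terminal_base_frequencies(frame, "canonical").sum() == pytest.approx(1.0)

    def test_empty_group_warns_empty(self):
        frame = self._frame(["TAGCAAGCTT"])
        assert terminal_base_frequencies(frame, "five_sub").empty


class TestCensus:
    def test_fraction_with_three_prime_variation(self):
        frame = pd.DataFrame(
            {
                "sequence": ["s1", "s2", "s3", "s4"],
                "precursor_id": "p",
                "count": [10, 5, 5, 5],
                "five_category": ["canonical"] * 4,
                "three_prime": ["canonical", "trim-1", "ext+1", "add+2"],
                "substitution_class": "none",
                "is_canonical": [True, False, False, False],
                "is_new": False,
            }
        )
        census = subtype_census(frame)
        assert census["sequence_weighted"]["frac_3p"] == pytest.approx(0.75)
        assert census["n_isomirs"] == 4

    def test_all_canonical_zero_fractions(self):
        frame = pd.DataFrame(
            {
                "sequence": ["s1"], "precursor_id": "p", "count": [3],
                "five_category": ["canonical"], "three_prime": ["canonical"],
                "substitution_class": "none", "is_canonical": [True], "is_new": False,
            }
        )
        census = subtype_census(frame)
        assert census["sequence_weighted"] == {"frac_5p": 0.0, "frac_3p": 0.0, "frac_both": 0.0}


class TestRoundTripWithGenerator:
    def test_recovers_generated_labels(self, small_cohort, small_analysis):
        truth = small_cohort.truth
        classified = small_analysis["classified"]
        # unambiguous rows: a single placement per (subject, sequence)
        placements = classified.groupby(["subject", "sequence"]).size()
        unique_keys = placements[placements == 1].index
        obs = classified.set_index(["subject", "sequence"]).loc[unique_keys]
        merged = truth.merge(
            obs.reset_index(), on=["subject", "sequence"], suffixes=("", "_obs")
        )
        assert len(merged) > 1000
        assert (merged["five_category_obs"] == merged["five_category"]).all()
        assert (merged["three_prime"] == merged["three_category"]).all()
        assert (merged["mature_id_obs"] == merged["mature_id"]).all()
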