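"""IsomiR taxonomy relative to the nearest annotated mature miRNA.

Each aligned read is compared with the mature miRNA on its precursor that
it overlaps most.  Variations are described per terminus:

* trimming (shorter templated 5'/3' end, signed shift -k),
* templated extension (longer templated end, +k) — both align perfectly
  to the hairpin,
* non-templated addition (terminal bases absent from the precursor at the
  position they occupy),
* substitutions: 5Sub (first base), 5sSub (single base in the seed,
  mature positions 2-7), 5mSub (multi-base 5' run), Sub (internal),
  3Sub (final base), 3mSub (multi-base 3' run),
* canonical (identical to the mature sequence), and
* NEW — fewer than 10 bases overlapping any annotated mature.

The 5'-category column drives the downstream composition analysis:
``canonical``, ``sub`` (any seed-region/5'-terminal substitution),
``trim-k``, ``ext+k`` or ``add+m``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import IsomiRAlignment
from .errors import ClassificationError, ConfigurationError
from .io import MatureAnnotation

NEW_OVERLAP_THRESHOLD = 10

FIVE_SUB_CLASSES = {"5Sub", "5sSub", "5mSub"}


@dataclass(frozen=True)
class IsomiRClass:
    """Taxonomy label and signed end-shifts for one aligned read."""

    mature_id: str  # or "NEW"
    five_shift: int = 0  # mature.start - templated.start; +k ext, -k trim
    three_shift: int = 0  # templated.end - mature.end; +k ext, -k trim
    five_prime: str = "canonical"  # canonical | trim-k | ext+k | add+m | sub
    three_prime: str = "canonical"
    substitution_class: str = "none"  # none | 5Sub | 5sSub | 5mSub | Sub | 3Sub | 3mSub
    is_canonical: bool = False
    is_new: bool = False

    @property
    def five_category(self) -> str:
        """Composition category of the 5' end (substitutions collapse to 'sub')."""
        if self.is_new:
            return "new"
        if self.substitution_class in FIVE_SUB_CLASSES:
            return "sub"
        return self.five_prime

    @property
    def has_five_variation(self) -> bool:
        return (not self.is_new) and (
            self.five_prime != "canonical" or self.substitution_class in FIVE_SUB_CLASSES
        )

    @property
    def has_three_variation(self) -> bool:
        return (not self.is_new) and (
            self.three_prime != "canonical" or self.substitution_class in {"3Sub", "3mSub"}
        )


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def assign_mature(alignment: IsomiRAlignment, matures: list[MatureAnnotation]) -> str:
    """Pick the mature annotation the templated span overlaps most.

    Overlap below 10 bases means the read is a new isomiR ("NEW").  Ties
    are broken by the smaller |5' shift|, then lexicographic mature id.
    """
    candidates = [m for m in matures if m.precursor_id == alignment.precursor_id]
    if not candidates:
        raise ConfigurationError(
            f"precursor {alignment.precursor_id} has no mature annotation"
        )
    scored = sorted(
        candidates,
        key=lambda m: (
            -_overlap(alignment.start, alignment.end, m.start, m.end),
            abs(m.start - alignment.start),
            m.id,
        ),
    )
    best = scored[0]
    if _overlap(alignment.start, alignment.end, best.start, best.end) < NEW_OVERLAP_THRESHOLD:
        return "NEW"
    return best.id


def classify_isomir(alignment: IsomiRAlignment, mature: MatureAnnotation) -> IsomiRClass:
    """Classify one alignment against its assigned mature miRNA.

    A non-templated 5' prefix counts as an addition when it occupies
    positions upstream of the mature 5' end (templated start at or before
    mature start); a prefix that replaces mature bases is a terminal
    substitution run (5Sub if single-base, 5mSub otherwise).  The 3' side
    mirrors this.  An R1 internal substitution is graded by its mature
    position: 1 -> 5Sub, 2-7 (seed) -> 5sSub, final templated base ->
    3Sub, otherwise Sub.
    """
    if alignment.sub_pos is not None and alignment.round != "R1":
        raise ClassificationError("internal substitution outside round R1")
    if len(alignment.prefix) + len(alignment.suffix) > 5:
        raise ClassificationError("more than 5 non-templated terminal bases")

    s5 = mature.start - alignment.start
    s3 = alignment.end - mature.end

    sub_class = "none"
    if alignment.sub_pos is not None:
        pos1 = alignment.sub_pos - mature.start + 1  # 1-based within the mature
        if alignment.sub_pos == alignment.end - 1:
            sub_class = "3Sub"
        elif pos1 == 1:
            sub_class = "5Sub"
        elif 2 <= pos1 <= 7:
            sub_class = "5sSub"
        else:
            sub_class = "Sub"

    if alignment.prefix:
        if alignment.start <= mature.start:
            five = f"add+{len(alignment.prefix)}"
        else:
            five = "sub"
            sub_class = "5Sub" if len(alignment.prefix) == 1 else "5mSub"
    elif s5 > 0:
        five = f"ext+{s5}"
    elif s5 < 0:
        five = f"trim-{-s5}"
    else:
        five = "canonical"

    if alignment.suffix:
        if alignment.end >= mature.end:
            three = f"add+{len(alignment.suffix)}"
        else:
            three = "sub"
            sub_class = "3Sub" if len(alignment.suffix) == 1 else "3mSub"
    elif s3 > 0:
        three = f"ext+{s3}"
    elif s3 < 0:
        three = f"trim-{-s3}"
    else:
        three = "canonical"

    is_canonical = (
        five == "canonical" and three == "canonical" and sub_class == "none"
    )
    return IsomiRClass(
        mature_id=mature.id,
        five_shift=s5,
        three_shift=s3,
        five_prime=five,
        three_prime=three,
        substitution_class=sub_class,
        is_canonical=is_canonical,
    )


def classify_alignment(
    alignment: IsomiRAlignment, matures: list[MatureAnnotation]
) -> IsomiRClass:
    mid = assign_mature(alignment, matures)
    if mid == "NEW":
        return IsomiRClass(mature_id="NEW", is_new=True, five_prime="new", three_prime="new")
    mature = next(m for m in matures if m.id == mid)
    return classify_isomir(alignment, mature)


def classify_table(alignments: pd.DataFrame, matures: list[MatureAnnotation]) -> pd.DataFrame:
    """Classify every row of an alignment table; adds the taxonomy columns.

    Classification depends only on (sequence, precursor, span, prefix,
    suffix, substitution), so identical placements across subjects are
    classified once and broadcast.
    """
    if alignments.empty:
        cols = list(alignments.columns) + [
            "mature_id", "five_shift", "three_shift", "five_prime", "three_prime",
            "substitution_class", "five_category", "is_canonical", "is_new",
        ]
        return pd.DataFrame(columns=cols)
    key_cols = ["sequence", "precursor_id", "start", "end", "prefix", "suffix",
                "sub_pos", "sub_read", "round"]
    uniq = alignments[key_cols].drop_duplicates()
    records = []
    for row in uniq.itertuples(index=False):
        aln = IsomiRAlignment(
            sequence=row.sequence,
            precursor_id=row.precursor_id,
            start=int(row.start),
            end=int(row.end),
            round=row.round,
            prefix=row.prefix if isinstance(row.prefix, str) else "",
            suffix=row.suffix if isinstance(row.suffix, str) else "",
            sub_pos=None if int(row.sub_pos) < 0 else int(row.sub_pos),
            sub_read=row.sub_read if isinstance(row.sub_read, str) and row.sub_read else None,
        )
        cls = classify_alignment(aln, matures)
        records.append(
            {
                **{k: getattr(row, k) for k in key_cols},
                "mature_id": cls.mature_id,
                "five_shift": cls.five_shift,
                "three_shift": cls.three_shift,
                "five_prime": cls.five_prime,
                "three_prime": cls.three_prime,
                "substitution_class": cls.substitution_class,
                "five_category": cls.five_category,
                "is_canonical": cls.is_canonical,
                "is_new": cls.is_new,
            }
        )
    return alignments.merge(pd.DataFrame(records), on=key_cols, how="left")


def terminal_base_frequencies(classified: pd.DataFrame, group: str) -> pd.Series:
    """Frequency of A/C/G/U at the 5'-terminal base of a sequence group.

    ``group`` is ``"canonical"`` or ``"five_sub"`` (5'-substitution
    isomiRs).  Computed over distinct sequences, not read-weighted, and
    reported in the RNA alphabet.
    """
    if group == "canonical":
        sel = classified[classified["is_canonical"]]
    elif group == "five_sub":
        sel = classified[classified["substitution_class"].isin(FIVE_SUB_CLASSES)]
    else:
        raise ConfigurationError(f"unknown terminal-base group {group!r}")
    seqs = sel["sequence"].drop_duplicates()
    if seqs.empty:
        return pd.Series(dtype=float)
    first = seqs.str[0].replace({"T": "U"})
    return first.value_counts(normalize=True).sort_index()


def subtype_census(classified: pd.DataFrame) -> dict:
    """Distinct-isomiR counts per precursor and end-variation fractions.

    Fractions are reported both over distinct isomiR sequences (the unit
    of discovery) and weighted by read counts.
    """
    body = classified[~classified["is_new"]]
    uniq = body.drop_duplicates(subset=["sequence", "precursor_id"]).copy()
    uniq["var5"] = (uniq["five_category"] != "canonical")
    uniq["var3"] = (uniq["three_prime"] != "canonical") | uniq[
        "substitution_class"].isin({"3Sub", "3mSub"})
    per_precursor = uniq.groupby("precursor_id")["sequence"].nunique()

    def _fractions(frame: pd.DataFrame, weights: np.ndarray) -> dict:
        total = weights.sum()
        if total == 0:
            return {"frac_5p": 0.0, "frac_3p": 0.0, "frac_both": 0.0}
        return {
            "frac_5p": float(weights[frame["var5"].to_numpy()].sum() / total),
            "frac_3p": float(weights[frame["var3"].to_numpy()].sum() / total),
            "frac_both": float(
                weights[(frame["var5"] & frame["var3"]).to_numpy()].sum() / total
            ),
        }

    seq_frac = _fractions(uniq, np.ones(len(uniq)))
    body2 = body.copy()
    body2["var5"] = body2["five_category"] != "canonical"
    body2["var3"] = (body2["three_prime"] != "canonical") | body2[
        "substitution_class"].isin({"3Sub", "3mSub"})
    read_frac = _fractions(body2, body2["count"].to_numpy().astype(float))
    return {
        "per_precursor_counts": per_precursor,
        "sequence_weighted": seq_frac,
        "read_weighted": read_frac,
        "n_isomirs": int(len(uniq)),
        "n_new": int(classified["is_new"].sum()),
    }
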