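"""Multi-round placement of small-RNA reads onto hairpin precursor references.

The rounds, in strict precedence order:

* **R0** — perfect substring match to a precursor (forward strand only:
  mature miRNAs are excised from the hairpin transcript, so reverse-strand
  hits are artefacts).
* genome filter — reads failing R0 that match a genomic (decoy) sequence
  perfectly on either strand originate elsewhere and are discarded.
* **R1** — placement with exactly one base substitution (Hamming distance
  1); reads with more than one substitution are not considered.
* **T1..T5** — up to five rounds of single-base end trimming.  Round *k*
  removes *i* bases from the 5' end and *j* from the 3' end with
  *i + j = k*; the trimmed core must match a precursor exactly.  The
  removed bases are recorded as non-templated terminal additions.  The
  first round with any hit terminates the search.

Every emitted alignment reconstructs its read exactly:
``prefix + reference[start:end] (with the substitution applied) + suffix``.
Multi-mapping placements within the winning round are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PrecursorRecord, revcomp

MIN_LEN = 16
MAX_LEN = 28
MAX_TRIM_ROUNDS = 5

ROUND_ORDER = ["R0", "R1", "T1", "T2", "T3", "T4", "T5"]
ROUND_RANK = {r: i for i, r in enumerate(ROUND_ORDER)}


@dataclass(frozen=True)
class IsomiRAlignment:
    """A read's resolved placement on one precursor.

    ``start``/``end`` delimit the templated span in 0-based half-open
    precursor-local coordinates.  ``prefix``/``suffix`` are the
    non-templated terminal bases (empty for templated placements).
    ``sub_pos`` is the precursor-local position of the single internal
    substitution (R1 only), with its reference and read bases.
    ``allele_origin`` is "canonical" or the rsID of the personalised
    reference the read was recovered from.
    """

    sequence: str
    precursor_id: str
    start: int
    end: int
    round: str
    prefix: str = ""
    suffix: str = ""
    sub_pos: int | None = None
    sub_ref: str | None = None
    sub_read: str | None = None
    allele_origin: str = "canonical"

    def reconstruct(self, references: dict[str, str]) -> str:
        core = list(references[self.precursor_id][self.start : self.end])
        if self.sub_pos is not None:
            core[self.sub_pos - self.start] = self.sub_read
        return self.prefix + "".join(core) + self.suffix


def _as_ref_dict(references) -> dict[str, str]:
    if isinstance(references, dict):
        return references
    return {r.id: r.sequence for r in references}


def _exact_offsets(read: str, ref: str) -> list[int]:
    """All forward-strand offsets where ``read`` occurs in ``ref``."""
    out, i = [], ref.find(read)
    while i != -1:
        out.append(i)
        i = ref.find(read, i + 1)
    return out


def align_perfect(read: str, references) -> list[IsomiRAlignment]:
    """Round 0: every exact occurrence of the read on every reference."""
    if not (MIN_LEN <= len(read) <= MAX_LEN):
        return []
    refs = _as_ref_dict(references)
    hits = []
    for rid, seq in refs.items():
        for off in _exact_offsets(read, seq):
            hits.append(
                IsomiRAlignment(
                    sequence=read, precursor_id=rid, start=off, end=off + len(read), round="R0"
                )
            )
    return hits


def matches_genome(read: str, genome) -> bool:
    """True if the read occurs perfectly in any genome sequence, either strand."""
    rc = revcomp(read)
    for seq in _as_ref_dict(genome).values():
        if read in seq or rc in seq:
            return True
    return False


def genome_filter(reads: list[str], genome) -> tuple[list[str], list[str]]:
    """Split R0-failing reads into (retained, genome-matched excluded)."""
    retained, excluded = [], []
    for r in reads:
        (excluded if matches_genome(r, genome) else retained).append(r)
    return retained, excluded


def align_one_mismatch(read: str, references) -> list[IsomiRAlignment]:
    """Round 1: all placements at Hamming distance exactly 1.

    Vectorised over offsets: each reference is byte-encoded and compared
    against the read in a sliding window.
    """
    if not (MIN_LEN <= len(read) <= MAX_LEN):
        return []
    refs = _as_ref_dict(references)
    m = len(read)
    q = np.frombuffer(read.encode(), dtype=np.uint8)
    hits = []
    for rid, seq in refs.items():
        if len(seq) < m:
            continue
        enc = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(enc, m)
        mismatch = windows != q
        n_mm = mismatch.sum(axis=1)
        for off in np.flatnonzero(n_mm == 1):
            pos = int(np.flatnonzero(mismatch[off])[0])
            hits.append(
                IsomiRAlignment(
                    sequence=read,
                    precursor_id=rid,
                    start=int(off),
                    end=int(off) + m,
                    round="R1",
                    sub_pos=int(off) + pos,
                    sub_ref=seq[off + pos],
                    sub_read=read[pos],
                )
            )
    return hits


def trim_rounds(
    read: str, references, max_rounds: int = MAX_TRIM_ROUNDS, min_core: int = MIN_LEN
) -> list[IsomiRAlignment]:
    """Rounds T1..Tmax: strip (i, j) terminal bases, i + j = k, match the core exactly.

    The earliest round with >= 1 hit wins; within it all (i, j) splits and
    all placements are reported.  Cores shorter than ``min_core`` are not
    attempted.
    """
    if not (MIN_LEN <= len(read) <= MAX_LEN):
        return []
    refs = _as_ref_dict(references)
    n = len(read)
    for k in range(1, max_rounds + 1):
        hits = []
        for i in range(k + 1):
            j = k - i
            if n - k < min_core:
                continue
            core = read[i : n - j] if j else read[i:]
            for rid, seq in refs.items():
                for off in _exact_offsets(core, seq):
                    hits.append(
                        IsomiRAlignment(
                            sequence=read,
                            precursor_id=rid,
                            start=off,
                            end=off + len(core),
                            round=f"T{k}",
                            prefix=read[:i],
                            suffix=read[n - j :] if j else "",
                        )
                    )
        if hits:
            return hits
    return []


def align_read(
    read: str,
    references,
    genome=None,
    max_trim_rounds: int = MAX_TRIM_ROUNDS,
) -> tuple[list[IsomiRAlignment], str]:
    """Run the full round cascade for one read.

    Returns ``(alignments, status)`` where status is one of ``aligned``,
    ``length``, ``genome`` or ``unaligned``.  Every aligned read carries
    exactly one round label (earliest-round precedence is total).
    """
    if not (MIN_LEN <= len(read) <= MAX_LEN):
        return [], "length"
    hits = align_perfect(read, references)
    if hits:
        return hits, "aligned"
    if genome is not None and matches_genome(read, genome):
        return [], "genome"
    hits = align_one_mismatch(read, references)
    if hits:
        return hits, "aligned"
    hits = trim_rounds(read, references, max_trim_rounds)
    if hits:
        return hits, "aligned"
    return [], "unaligned"


def alignments_to_frame(rows: list[tuple[str, int, IsomiRAlignment]]) -> pd.DataFrame:
    """Flatten (subject, count, alignment) triples to the inter-stage table."""
    records = []
    for subject, count, a in rows:
        records.append(
            {
                "subject": subject,
                "sequence": a.sequence,
                "count": count,
                "precursor_id": a.precursor_id,
                "start": a.start,
                "end": a.end,
                "round": a.round,
                "prefix": a.prefix,
                "suffix": a.suffix,
                "sub_pos": -1 if a.sub_pos is None else a.sub_pos,
                "sub_ref": a.sub_ref or "",
                "sub_read": a.sub_read or "",
                "allele_origin": a.allele_origin,
            }
        )
    frame = pd.DataFrame(
        records,
        columns=[
            "subject", "sequence", "count", "precursor_id", "start", "end",
            "round", "prefix", "suffix", "sub_pos", "sub_ref", "sub_read",
            "allele_origin",
        ],
    )
    return frame.sort_values(["subject", "sequence", "precursor_id", "start"]).reset_index(drop=True)


def filter_min_subjects(table: pd.DataFrame, min_subjects: int = 10) -> pd.DataFrame:
    """Keep isomiRs (sequence x precursor) observed in >= ``min_subjects`` subjects."""
    if table.empty:
        return table
    n_subj = table.groupby(["sequence", "precursor_id"])["subject"].transform("nunique")
    return table[n_subj >= min_subjects].reset_index(drop=True)
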