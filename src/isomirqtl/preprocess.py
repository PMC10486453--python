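"""Adaptor trimming, length filtering and read collapsing.

Small-RNA libraries sequence through the insert into the 3' ligation
adaptor, so the adaptor (or a prefix of it, when the insert is long) must
be removed before alignment.  Matching is exact: the synthetic cohorts
this package analyses append the adaptor verbatim, and exact search keeps
the stage deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError
from .io import validate_read

#: 3' ligation adaptor of the small-RNA protocol this pipeline targets.
DEFAULT_ADAPTOR = "TGGAATTCTCGGGTGCCAAGGAACTC"

#: Shortest mature miRNA; reads below this after trimming carry no signal.
MIN_READ_LENGTH = 16


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its per-subject multiplicity."""

    sequence: str
    count: int
    subject: str


def trim_adaptor(read: str, adaptor: str = DEFAULT_ADAPTOR, min_overlap: int = 3) -> str:
    """Remove the 3' adaptor from a read.

    The leftmost exact occurrence of the full adaptor — or, failing that,
    of an adaptor prefix of length >= ``min_overlap`` terminating at the
    read's 3' end — is removed together with everything after it.  Reads
    with no qualifying occurrence are returned unchanged.
    """
    if not adaptor:
        raise InputError("adaptor must be non-empty")
    if min_overlap < 1:
        raise InputError("min_overlap must be >= 1")
    read = validate_read(read)
    idx = read.find(adaptor)
    if idx >= 0:
        return read[:idx]
    # adaptor prefix at the 3' end: the longest such prefix is the leftmost
    max_len = min(len(adaptor) - 1, len(read))
    for n in range(max_len, min_overlap - 1, -1):
        if read.endswith(adaptor[:n]):
            return read[: len(read) - n]
    return read


def filter_min_length(reads: list[str], min_length: int = MIN_READ_LENGTH) -> tuple[list[str], int]:
    """Drop reads shorter than ``min_length``; returns (kept, n_dropped)."""
    kept = [r for r in reads if len(r) >= min_length]
    return kept, len(reads) - len(kept)


def collapse_reads(reads: list[str], subject: str) -> pd.DataFrame:
    """Collapse one subject's reads to unique sequences with counts.

    Total mass is conserved: the count column sums to ``len(reads)``.
    """
    if not reads:
        return pd.DataFrame(columns=["subject", "sequence", "count"])
    counts = pd.Series(reads).value_counts().sort_index()
    return pd.DataFrame(
        {"subject": subject, "sequence": counts.index, "count": counts.to_numpy()}
    )


def preprocess_reads(
    raw_reads: list[str],
    subject: str,
    adaptor: str = DEFAULT_ADAPTOR,
    min_overlap: int = 3,
    min_length: int = MIN_READ_LENGTH,
) -> tuple[pd.DataFrame, dict]:
    """Trim, length-filter and collapse one subject's raw reads.

    Returns the collapsed table and a small stats dict (input reads,
    dropped-short count, unique sequences).
    """
    trimmed = [trim_adaptor(r, adaptor, min_overlap) for r in raw_reads]
    kept, dropped = filter_min_length(trimmed, min_length)
    table = collapse_reads(kept, subject)
    stats = {
        "subject": subject,
        "n_input": len(raw_reads),
        "n_dropped_short": dropped,
        "n_unique": len(table),
    }
    return table, stats
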