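"""Per-subject 5'-end isomiR composition ratios.

For each (subject, mature miRNA) the reads whose 5' terminus lies within
±``window`` bases of the canonical 5' end are grouped into categories —
5'-canonical, 5'-substitution, trim(k), ext(k), add(m) — and converted to
pseudocounted ratios::

    ratio = (count + 0.5) / (total + 0.5)

where ``total`` is the in-window read count for that mature miRNA.  The
pseudocount keeps every ratio in (0, 1] and strictly monotone in its own
count.  Cells with zero in-window reads are left missing rather than set
to 0.5/0.5 = 1, which would fabricate signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

DEFAULT_WINDOW = 8
PSEUDOCOUNT = 0.5
MAX_ADD = 5  # additions cannot exceed the number of trim rounds


def in_window_categories(window: int = DEFAULT_WINDOW, max_add: int = MAX_ADD) -> list[str]:
    cats = ["canonical", "sub"]
    cats += [f"trim-{k}" for k in range(1, window + 1)]
    cats += [f"ext+{k}" for k in range(1, window + 1)]
    cats += [f"add+{m}" for m in range(1, max_add + 1)]
    return cats


def _five_terminus_shift(row) -> int:
    """Signed offset of the read's 5' terminus from the canonical 5' end.

    Positive means the read starts upstream of the mature start (extension
    or addition), negative downstream (trimming).  Non-templated prefix
    bases extend the terminus upstream of the templated span.
    """
    prefix_len = len(row.prefix) if isinstance(row.prefix, str) else 0
    return int(row.five_shift) + prefix_len


def compose_5prime(
    classified: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    pseudocount_mode: str = "shared",
) -> pd.DataFrame:
    """Build the long composition table: one row per (subject, mature, category).

    ``pseudocount_mode``:

    * ``"shared"`` (default) — ratio = (count + 0.5) / (total + 0.5); each
      ratio is a monotone function of its own count.
    * ``"per_category"`` — ratio = (count + 0.5) / (total + 0.5 * n_categories);
      ratios sum to 1 across categories.

    Reads whose 5' terminus shift exceeds the window, and NEW isomiRs,
    are excluded from both the counts and the totals.
    """
    if pseudocount_mode not in {"shared", "per_category"}:
        raise ConfigurationError(f"unknown pseudocount_mode {pseudocount_mode!r}")
    body = classified[~classified["is_new"]].copy()
    if body.empty:
        return pd.DataFrame(columns=["subject", "mature_id", "category", "count", "total", "ratio"])
    shifts = np.array([_five_terminus_shift(r) for r in body.itertuples(index=False)])
    body = body[np.abs(shifts) <= window]
    valid = set(in_window_categories(window))
    body = body[body["five_category"].isin(valid)]
    counts = (
        body.groupby(["subject", "mature_id", "five_category"])["count"]
        .sum()
        .rename("count")
        .reset_index()
        .rename(columns={"five_category": "category"})
    )
    totals = counts.groupby(["subject", "mature_id"])["count"].sum().rename("total")
    counts = counts.join(totals, on=["subject", "mature_id"])
    if pseudocount_mode == "shared":
        denom = counts["total"] + PSEUDOCOUNT
    else:
        denom = counts["total"] + PSEUDOCOUNT * len(valid)
    counts["ratio"] = (counts["count"] + PSEUDOCOUNT) / denom
    return counts.sort_values(["subject", "mature_id", "category"]).reset_index(drop=True)


def composition_wide(long_table: pd.DataFrame, value: str = "ratio") -> pd.DataFrame:
    """Pivot the long table to subjects x 'mature|category' columns.

    Absent cells (no in-window reads for that subject and mature) stay
    NaN and are excluded pairwise downstream.
    """
    if long_table.empty:
        return pd.DataFrame()
    wide = long_table.pivot_table(
        index="subject",
        columns=long_table["mature_id"] + "|" + long_table["category"],
        values=value,
        aggfunc="first",
    )
    # a category unobserved for a subject who *does* have in-window reads is
    # a genuine zero count, not missing: fill from that subject's total
    if value == "ratio":
        totals = long_table.pivot_table(index="subject", columns="mature_id", values="total", aggfunc="first")
        for col in wide.columns:
            mature = col.split("|", 1)[0]
            if mature in totals.columns:
                tot = totals[mature]
                fill = PSEUDOCOUNT / (tot + PSEUDOCOUNT)
                wide[col] = wide[col].fillna(fill.where(tot.notna()))
    wide.columns.name = None
    return wide.sort_index()


def canonical_dominance_summary(
    classified: pd.DataFrame,
    min_subjects: int = 5,
    min_reads: int = 20,
) -> pd.DataFrame:
    """Per-miRNA dominance of non-canonical isomiRs over the canonical form.

    A mature miRNA is *eligible* when at least ``min_subjects`` subjects
    carry ``min_reads`` or more of its reads.  For each eligible miRNA the
    summary reports, over total reads across subjects:

    * ``seq_dominant`` — some single non-canonical isomiR sequence
      out-reads the canonical sequence;
    * ``cat5_dominant`` — same after grouping isomiRs by shared 5'-end
      variation (3' differences pooled);
    * ``subject_fraction`` — fraction of subjects in whom the best
      non-canonical sequence out-reads the canonical.
    """
    body = classified[~classified["is_new"]]
    if body.empty:
        return pd.DataFrame(
            columns=["mature_id", "eligible", "seq_dominant", "cat5_dominant", "subject_fraction"]
        )
    per_subj = body.groupby(["mature_id", "subject"])["count"].sum()
    eligible_ids = (
        per_subj[per_subj >= min_reads].groupby("mature_id").size().loc[lambda s: s >= min_subjects].index
    )
    rows = []
    for mid, grp in body.groupby("mature_id"):
        canon_total = grp.loc[grp["is_canonical"], "count"].sum()
        seq_totals = grp[~grp["is_canonical"]].groupby("sequence")["count"].sum()
        best_seq = seq_totals.max() if not seq_totals.empty else 0
        cat_totals = grp[grp["five_category"] != "canonical"].groupby("five_category")["count"].sum()
        canon5_total = grp.loc[grp["five_category"] == "canonical", "count"].sum()
        best_cat = cat_totals.max() if not cat_totals.empty else 0
        # per-subject comparison of best non-canonical sequence vs canonical
        n_dom = 0
        subjects = grp["subject"].unique()
        for s in subjects:
            sg = grp[grp["subject"] == s]
            c = sg.loc[sg["is_canonical"], "count"].sum()
            nc = sg[~sg["is_canonical"]].groupby("sequence")["count"].sum()
            if not nc.empty and nc.max() > c:
                n_dom += 1
        rows.append(
            {
                "mature_id": mid,
                "eligible": mid in eligible_ids,
                "seq_dominant": bool(best_seq > canon_total),
                "cat5_dominant": bool(best_cat > canon5_total),
                "subject_fraction": n_dom / len(subjects) if len(subjects) else 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values("mature_id").reset_index(drop=True)
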