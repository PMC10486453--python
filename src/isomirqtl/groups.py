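"""Group comparison of isomiR expression (e.g. tumour vs normal).

Counts are normalised to reads per million miRNA-mapped reads (RPM),
isomiRs sharing the same 5'-end variation are aggregated regardless of
their 3' differences, and group differences are tested per (miRNA, 5'
variation) row with a two-sample t-test — pooled-variance Student by
default, with a Welch switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError


def rpm_normalize(counts: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """counts / per-sample total x 1e6.

    ``counts`` is rows x samples; ``totals`` gives each sample's
    miRNA-mapped read total.  Zero-total samples are dropped with a
    warning.
    """
    totals = totals.reindex(counts.columns)
    bad = totals[(totals <= 0) | totals.isna()].index
    if len(bad):
        import warnings

        warnings.warn(f"samples with zero mapped total excluded: {list(bad)}")
        counts = counts.drop(columns=bad)
        totals = totals.drop(bad)
    return counts.div(totals, axis=1) * 1e6


def aggregate_by_5prime(expression: pd.DataFrame) -> pd.DataFrame:
    """Sum expression rows sharing (mature_id, five_category), pooling 3' variants.

    ``expression`` must carry ``mature_id`` and ``five_category`` columns;
    all remaining numeric columns are treated as samples.  Per-sample
    totals are conserved.
    """
    value_cols = [c for c in expression.columns if c not in {"mature_id", "five_category"}
                  and pd.api.types.is_numeric_dtype(expression[c])]
    return (
        expression.groupby(["mature_id", "five_category"])[value_cols]
        .sum()
        .reset_index()
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    df: float


def two_sample_t(group_a, group_b, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test; pooled-variance Student by default, Welch optional."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("two_sample_t needs n >= 2 per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise DegenerateDataError("two_sample_t: both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return TTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        se_a=float(a.std(ddof=1) / np.sqrt(len(a))),
        se_b=float(b.std(ddof=1) / np.sqrt(len(b))),
        df=float(df),
    )


def compare_groups(
    aggregated: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """t-test every (mature, 5' variation) row between two sample groups.

    ``groups`` maps sample -> group label.  Rows with degenerate variance
    are reported with NaN statistics rather than dropped.
    """
    samples_a = [s for s in aggregated.columns if groups.get(s) == group_a]
    samples_b = [s for s in aggregated.columns if groups.get(s) == group_b]
    if not samples_a or not samples_b:
        raise DegenerateDataError(f"empty group: {group_a if not samples_a else group_b}")
    rows = []
    for rec in aggregated.itertuples(index=False):
        row = rec._asdict()
        a = np.array([row[s] for s in samples_a], dtype=float)
        b = np.array([row[s] for s in samples_b], dtype=float)
        out = {
            "mature_id": row["mature_id"],
            "five_category": row["five_category"],
            f"mean_{group_a}": a.mean(),
            f"mean_{group_b}": b.mean(),
        }
        try:
            res = two_sample_t(a, b, equal_var=equal_var)
            out.update({"t": res.t, "p": res.p})
        except DegenerateDataError:
            out.update({"t": np.nan, "p": np.nan})
        rows.append(out)
    frame = pd.DataFrame(rows)
    return frame.sort_values("p", na_position="last").reset_index(drop=True)
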