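"""Genotype / 5'-isomiR-composition association.

The association statistic is Kendall's rank correlation tau-b between the
additively coded minor-allele dosage (0/1/2) and the pseudocounted
composition ratio.  Dosages are heavily tied, so the tie-corrected tau-b
and the tie-corrected normal approximation for the p-value (on the S
statistic, with continuity correction) are used.  Population
stratification is handled by running the scan on all subjects and within
each ancestry stratum, adjusting with Benjamini-Hochberg separately
within each analysis, and calling a pair significant only when it passes
the FDR threshold overall *and* within at least one stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError


# ---------------------------------------------------------------------------
# Kendall tau-b
# ---------------------------------------------------------------------------

def _tie_groups(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1]


def _kendall_s(x: np.ndarray, y: np.ndarray) -> float:
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(len(x), 1)
    return float((dx[iu] * dy[iu]).sum())


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall tau-b.

    tau_b = S / sqrt((n0 - n1)(n0 - n2)) with S the concordant-minus-
    discordant pair count, n0 = n(n-1)/2 and n1, n2 the tied-pair counts
    in x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateDataError("kendall_tau_b needs >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("kendall_tau_b undefined for a constant vector")
    n = len(x)
    n0 = n * (n - 1) / 2.0
    tx = _tie_groups(x)
    ty = _tie_groups(y)
    n1 = float((tx * (tx - 1) / 2.0).sum())
    n2 = float((ty * (ty - 1) / 2.0).sum())
    return _kendall_s(x, y) / np.sqrt((n0 - n1) * (n0 - n2))


def kendall_pvalue(x, y, method: str = "asymptotic", n_perm: int = 10000, rng=None) -> float:
    """Two-sided p-value for Kendall's S.

    ``asymptotic`` (default): normal approximation with the tie-corrected
    variance of S and a continuity correction — standard practice at
    cohort-scale n where exact enumeration is infeasible.  ``permutation``
    is the small-n fallback: the proportion of y-permutations with
    |S| >= |S_observed| (add-one estimator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("kendall_pvalue undefined on degenerate input")
    s = _kendall_s(x, y)
    if method == "permutation":
        rng = np.random.default_rng(rng)
        count = 0
        for _ in range(n_perm):
            if abs(_kendall_s(x, rng.permutation(y))) >= abs(s):
                count += 1
        return (count + 1) / (n_perm + 1)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    n = len(x)
    tx = _tie_groups(x)
    ty = _tie_groups(y)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((tx * (tx - 1) * (2 * tx + 5)).sum())
    vu = float((ty * (ty - 1) * (2 * ty + 5)).sum())
    v1 = float((tx * (tx - 1)).sum()) * float((ty * (ty - 1)).sum()) / (2.0 * n * (n - 1))
    v2 = (
        float((tx * (tx - 1) * (tx - 2)).sum())
        * float((ty * (ty - 1) * (ty - 2)).sum())
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        raise DegenerateDataError("kendall_pvalue: zero variance of S")
    z = (abs(s) - 1.0) / np.sqrt(var_s)  # continuity correction
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


# ---------------------------------------------------------------------------
# BH, additive coding, PCA
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def additive_coding(dosages: pd.DataFrame, snp_id: str) -> pd.Series:
    """Dosage of the cohort-minor allele in {0, 1, 2}; NaN for missing GTs.

    The VCF stores ALT dosages; when ALT is the cohort-major allele the
    coding flips so the rare allele is counted, matching the additive
    genetic model (0/1/2 copies of the minor allele).
    """
    col = dosages[snp_id]
    af = col.mean(skipna=True) / 2.0
    if af > 0.5:
        return 2.0 - col
    return col.copy()


def minor_allele(dosages: pd.DataFrame, snp_id: str, ref: str, alt: str) -> str:
    af = dosages[snp_id].mean(skipna=True) / 2.0
    return ref if af > 0.5 else alt


def genotype_pca(dosages: pd.DataFrame, n_components: int = 2):
    """PCA of the dosage matrix for visualising population stratification.

    Missing dosages are mean-imputed per SNP; columns are centered.
    Returns (scores DataFrame indexed by subject, explained variance
    ratios).
    """
    from sklearn.decomposition import PCA

    x = dosages.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise DegenerateDataError("genotype_pca needs >= 2 subjects and >= 2 SNPs")
    col_means = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_means, inds[1])
    if np.allclose(x.std(axis=0), 0):
        raise DegenerateDataError("genotype_pca: all SNPs constant")
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x - x.mean(axis=0))
    frame = pd.DataFrame(
        scores, index=dosages.index, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    return frame, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# The association scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationTest:
    snp_id: str
    mature_id: str
    category: str


def _stratum_stats(x: pd.Series, y: pd.Series, min_pairs: int = 3):
    pair = pd.concat([x, y], axis=1, join="inner").dropna()
    n = len(pair)
    if n < min_pairs:
        return n, np.nan, np.nan
    xv, yv = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
    try:
        tau = kendall_tau_b(xv, yv)
        p = kendall_pvalue(xv, yv)
    except DegenerateDataError:
        return n, np.nan, np.nan
    return n, tau, p


def run_association(
    composition_long: pd.DataFrame,
    dosages: pd.DataFrame,
    snp_to_matures: dict[str, list[str]],
    strata: pd.Series,
    fdr: float = 0.05,
    min_informative_subjects: int = 10,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Cis scan: every SNP x same-precursor mature x 5' category with support.

    A category enters the test family when its raw count is positive in at
    least ``min_informative_subjects`` subjects for that mature miRNA.
    Kendall tau-b and its p-value are computed on all subjects (``ALL``)
    and within each stratum of ``strata`` (a subject -> population label
    series); missing composition cells are removed pairwise.  BH runs
    separately within ALL and within each stratum across that analysis's
    full test list.  A pair is significant iff FDR_ALL < ``fdr`` and the
    smallest stratum FDR < ``fdr``.
    """
    strata = strata.dropna()
    stratum_labels = sorted(strata.unique())
    ratio_cell = composition_long.set_index(["subject", "mature_id", "category"])["ratio"]

    tests: list[AssociationTest] = []
    support = (
        composition_long[composition_long["count"] > 0]
        .groupby(["mature_id", "category"])["subject"]
        .nunique()
    )
    for snp_id, matures in snp_to_matures.items():
        if snp_id not in dosages.columns:
            continue
        for mid in matures:
            cats = support.loc[mid] if mid in support.index.get_level_values(0) else pd.Series(dtype=int)
            for cat, n_sup in cats.items():
                if n_sup >= min_informative_subjects:
                    tests.append(AssociationTest(snp_id, mid, cat))

    rows = []
    for t in tests:
        x = additive_coding(dosages, t.snp_id)
        y = ratio_cell.loc[
            ratio_cell.index.get_level_values("mature_id") == t.mature_id
        ]
        y = y[y.index.get_level_values("category") == t.category]
        y = y.droplevel(["mature_id", "category"])
        row = {"snp_id": t.snp_id, "mature_id": t.mature_id, "category": t.category}
        n, tau, p = _stratum_stats(x, y, min_pairs)
        row.update({"n_ALL": n, "tau_ALL": tau, "p_ALL": p})
        for label in stratum_labels:
            subj = strata.index[strata == label]
            n, tau, p = _stratum_stats(x.loc[x.index.intersection(subj)], y, min_pairs)
            row.update({f"n_{label}": n, f"tau_{label}": tau, f"p_{label}": p})
        rows.append(row)

    result = pd.DataFrame(rows)
    if result.empty:
        return result
    for label in ["ALL"] + stratum_labels:
        pcol, fcol = f"p_{label}", f"fdr_{label}"
        result[fcol] = np.nan
        mask = result[pcol].notna()
        if mask.any():
            result.loc[mask, fcol] = bh_adjust(result.loc[mask, pcol].to_numpy())
    stratum_fdr_cols = [f"fdr_{label}" for label in stratum_labels]
    min_stratum = result[stratum_fdr_cols].min(axis=1) if stratum_fdr_cols else np.nan
    result["significant"] = (result["fdr_ALL"] < fdr) & (min_stratum < fdr)
    return result.sort_values(["fdr_ALL", "p_ALL"]).reset_index(drop=True)
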