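"""Pairwise differential-expression calls between sample groups.

A gene is a DEG for contrast A vs B when FDR < 0.05 and |log2 fold
change| > 1 (strict inequalities).  Fold changes are differences of
group means on the log2 scale; p-values come from Welch's unequal-
variance t-test on log2(CPM + 1); FDR is Benjamini-Hochberg across all
tested genes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NormalizedMatrix
from .normalize import log_transform

DEG_COLUMNS = (
    "gene_id",
    "contrast",
    "log2fc",
    "p_value",
    "fdr",
    "is_deg",
    "direction",
)


def welch_t(values_a, values_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test.

    Both groups constant and equal is treated as "no evidence of
    difference" (t=0, p=1); constant but different means p=0, keeping the
    result defined for degenerate genes.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch tests with the same degenerate-gene conventions as
    :func:`welch_t`."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        diff = a.mean(axis=1) - b.mean(axis=1)
        t[bad] = np.where(diff[bad] == 0, 0.0, np.sign(diff[bad]) * np.inf)
        p[bad] = np.where(diff[bad] == 0, 1.0, 0.0)
    return t, p


def call_degs(
    norm: NormalizedMatrix,
    group_a: str,
    group_b: str,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    genes: list[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One DEGRecord row per tested gene for the contrast group_a vs group_b.

    ``genes`` restricts the analysis (e.g. to the candidate-filtered set);
    by default all genes in the matrix are tested.  A linear-scale matrix
    is log2(x + pseudocount)-transformed first so fold changes are log2
    differences of group means.
    """
    cols_a = norm.samples_in_group(group_a)
    cols_b = norm.samples_in_group(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (got {len(cols_a)} {group_a}, "
            f"{len(cols_b)} {group_b})"
        )
    if not norm.is_log_scale:
        norm = log_transform(norm, pseudocount)
    if genes is not None:
        values = norm.values.loc[list(genes)]
    else:
        values = norm.values
    contrast = f"{group_a}_vs_{group_b}"
    if values.shape[0] == 0:
        return pd.DataFrame(columns=DEG_COLUMNS)
    a = values[cols_a].to_numpy(dtype=float)
    b = values[cols_b].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    _, p = _welch_matrix(a, b)
    fdr = bh_adjust(p)
    is_deg = (fdr < fdr_threshold) & (np.abs(log2fc) > lfc_threshold)
    direction = np.where(~is_deg, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "gene_id": values.index,
            "contrast": contrast,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "is_deg": is_deg,
            "direction": direction,
        },
        columns=list(DEG_COLUMNS),
    ).reset_index(drop=True)


def deg_sets(deg_table: pd.DataFrame) -> dict[str, set[str]]:
    """Gene-id sets of all / up / down DEGs from one contrast's table."""
    deg = deg_table[deg_table["is_deg"]]
    return {
        "all": set(deg["gene_id"]),
        "up": set(deg.loc[deg["direction"] == "up", "gene_id"]),
        "down": set(deg.loc[deg["direction"] == "down", "gene_id"]),
    }


def venn_overlap(set_a: set, set_b: set, set_c: set) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a 3-set Venn diagram.

    Keys: "A", "B", "C" (exclusive to one set), "AB", "AC", "BC" (exactly
    two), "ABC" (all three).  Region counts sum to |A u B u C|.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    return {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - abc),
        "AC": len((a & c) - abc),
        "BC": len((b & c) - abc),
        "ABC": len(abc),
    }
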