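"""Inheritance-mode classification of candidate genes in an F1 cross.

The procedure, per tissue:

1. keep genes expressed (raw count > 0) in at least half of the tissue's
   samples ("candidate genes");
2. normalize to CPM and (by default) align the F1 columns to the
   mid-parent under the median-gene-is-additive assumption;
3. for every candidate gene compute the mid-parent value
   MPV = (mean_P1 + mean_P2)/2 on the linear CPM scale, then test
   (a) F1 vs MPV, (b) F1 vs the higher-expressing parent, and (c) F1 vs
   the lower-expressing parent; the tests run on log2(CPM + pc) values
   by default, with the MPV carried over as log2(MPV + pc);
4. apply the Benjamini-Yekutieli step-up correction separately within
   each of the three test families, across all candidate genes;
5. classify: non-significant vs MPV -> additive; otherwise over- or
   under-dominant when the F1 is significantly beyond the high (resp.
   low) parent, enhancing/suppressing dominance when it matches one
   parent but differs from the other, and unclassified_nonadditive when
   the q-value pattern fits none of the named classes.

Per-gene variances may be moderated (empirical-Bayes shrinkage, see
:mod:`hybridexpr.moderation`); this is the default because with ~6
replicates the raw t-test is severely underpowered.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, NormalizedMatrix
from .moderation import squeeze_variances, total_df
from .normalize import align_f1_to_midparent, log_transform, normalize_cpm

CATEGORIES = (
    "additive",
    "enhancing_dominance",
    "suppressing_dominance",
    "over_dominance",
    "under_dominance",
    "unclassified_nonadditive",
    "not_testable",
)

PATTERN_COLUMNS = (
    "gene_id",
    "mpv",
    "mean_p1",
    "mean_p2",
    "mean_f1",
    "high_parent",
    "p_mpv",
    "q_mpv",
    "p_high",
    "q_high",
    "p_low",
    "q_low",
    "category",
)


def filter_candidates(cm: CountMatrix, tissue: str) -> list[str]:
    """Genes with count > 0 in at least ceil(n/2) of the tissue's samples."""
    samples = list(cm.meta.index[cm.meta["tissue"] == tissue])
    if not samples:
        raise ValueError(f"unknown tissue {tissue!r}")
    if len(samples) < 2:
        raise ValueError(f"tissue {tissue!r} has fewer than 2 samples")
    expressed = (cm.counts[samples] > 0).sum(axis=1)
    threshold = math.ceil(len(samples) / 2)
    return list(cm.counts.index[expressed >= threshold])


def mid_parent_value(norm: NormalizedMatrix, gene_id: str) -> float:
    """(mean over P1 samples + mean over P2 samples) / 2, on the matrix scale."""
    p1 = norm.samples_in_group("P1")
    p2 = norm.samples_in_group("P2")
    if not p1 or not p2:
        raise ValueError("both parental groups must be present")
    row = norm.values.loc[gene_id]
    return float((row[p1].mean() + row[p2].mean()) / 2.0)


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    BH with the extra harmonic-sum factor c(m) = sum_{i<=m} 1/i, valid
    under arbitrary dependence; clipped to 1, order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def test_vs_mpv(f1_values, mpv: float) -> tuple[float, float]:
    """One-sample two-sided t-test of the F1 values against the scalar MPV.

    Constant F1 values equal to the MPV give (0, 1); constant but
    different give (+-inf, 0).
    """
    x = np.asarray(f1_values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 F1 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if x.var(ddof=1) == 0:
        if x.mean() == mpv:
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - mpv), 0.0
    res = stats.ttest_1samp(x, mpv)
    return float(res.statistic), float(res.pvalue)


def classify_gene(
    q_mpv: float,
    q_high: float,
    q_low: float,
    mean_f1: float,
    mean_high: float,
    mean_low: float,
    high_parent: str = "P1",
    alpha: float = 0.05,
) -> str:
    """Assign one inheritance-mode category from the adjusted p-values.

    The decision tree (evaluated in order) makes the classes mutually
    exclusive, with over/under-dominance taking precedence over the
    dominance calls.  A parental tie makes every dominance category
    unreachable, and q-value patterns fitting no named class fall to
    unclassified_nonadditive — the four named non-additive classes are
    not exhaustive.
    """
    if any(not np.isfinite(q) for q in (q_mpv, q_high, q_low)):
        return "not_testable"
    if q_mpv >= alpha:
        return "additive"
    if high_parent == "tie":
        return "unclassified_nonadditive"
    if q_high < alpha and mean_f1 > mean_high:
        return "over_dominance"
    if q_low < alpha and mean_f1 < mean_low:
        return "under_dominance"
    if q_high >= alpha and q_low < alpha:
        return "enhancing_dominance"
    if q_low >= alpha and q_high < alpha:
        return "suppressing_dominance"
    return "unclassified_nonadditive"


def _one_sample_tests(
    values: np.ndarray, popmean: np.ndarray, moderate: bool
) -> np.ndarray:
    """Row-wise one-sample two-sided p-values against per-row popmeans."""
    n = values.shape[1]
    if moderate:
        s2, d0, _ = squeeze_variances(values.var(axis=1, ddof=1), n - 1)
        dft = total_df(n - 1, d0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (values.mean(axis=1) - popmean) / np.sqrt(s2 / n)
        p = 2.0 * stats.t.sf(np.abs(t), dft)
        diff = values.mean(axis=1) - popmean
        p[~np.isfinite(t)] = np.where(diff[~np.isfinite(t)] == 0, 1.0, 0.0)
        return p
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.asarray(
            stats.ttest_1samp(values, popmean[:, None], axis=1).pvalue, dtype=float
        )
    bad = ~np.isfinite(p)
    if bad.any():
        diff = values.mean(axis=1) - popmean
        p[bad] = np.where(diff[bad] == 0, 1.0, 0.0)
    return p


def _two_sample_tests(a: np.ndarray, b: np.ndarray, moderate: bool) -> np.ndarray:
    """Row-wise two-sample (Welch-style) p-values."""
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    if moderate:
        va, d0a, _ = squeeze_variances(a.var(axis=1, ddof=1), na - 1)
        vb, d0b, _ = squeeze_variances(b.var(axis=1, ddof=1), nb - 1)
        dfa, dfb = total_df(na - 1, d0a), total_df(nb - 1, d0b)
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(se2)
            # Welch-Satterthwaite on the moderated variances
            dft = se2**2 / ((va / na) ** 2 / dfa + (vb / nb) ** 2 / dfb)
        p = 2.0 * stats.t.sf(np.abs(t), dft)
        p[~np.isfinite(t)] = np.where(diff[~np.isfinite(t)] == 0, 1.0, 0.0)
        return p
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.asarray(
            stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue, dtype=float
        )
    bad = ~np.isfinite(p)
    if bad.any():
        p[bad] = np.where(diff[bad] == 0, 1.0, 0.0)
    return p


def classify_matrix(
    norm: NormalizedMatrix,
    alpha: float = 0.05,
    scale: str = "log",
    mpv_test: str = "one-sample",
    moderate: bool = True,
    align: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Classify every gene of a linear-scale NormalizedMatrix.

    Group means, MPV and the high/low-parent assignment are always
    reported on the linear scale (so mpv = (mean_p1 + mean_p2)/2 holds
    exactly); ``scale`` selects the scale the t-tests run on ("log":
    log2(x + pseudocount) values against log2(MPV + pseudocount),
    the variance-stabilized default; "linear": raw normalized values
    against the MPV).
    """
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")
    if mpv_test not in ("one-sample", "two-sample"):
        raise ValueError("mpv_test must be 'one-sample' or 'two-sample'")
    if norm.is_log_scale:
        raise ValueError("classify_matrix expects a linear-scale matrix")
    cols = {g: norm.samples_in_group(g) for g in ("P1", "P2", "F1")}
    for g, c in cols.items():
        if len(c) < 2:
            raise ValueError(f"group {g} needs >= 2 samples (got {len(c)})")
    if norm.values.shape[0] == 0:
        return pd.DataFrame(columns=PATTERN_COLUMNS)

    if align:
        norm, _ = align_f1_to_midparent(norm, pseudocount)

    mean_p1 = norm.values[cols["P1"]].mean(axis=1).to_numpy()
    mean_p2 = norm.values[cols["P2"]].mean(axis=1).to_numpy()
    mean_f1 = norm.values[cols["F1"]].mean(axis=1).to_numpy()
    mpv = (mean_p1 + mean_p2) / 2.0
    p1_high = mean_p1 > mean_p2
    tie = mean_p1 == mean_p2
    high_parent = np.where(tie, "tie", np.where(p1_high, "P1", "P2"))
    mean_high = np.where(p1_high, mean_p1, mean_p2)
    mean_low = np.where(p1_high, mean_p2, mean_p1)

    if scale == "log":
        analysis = log_transform(norm, pseudocount)
        popmean = np.log2(mpv + pseudocount)
    else:
        analysis = norm
        popmean = mpv
    f1 = analysis.values[cols["F1"]].to_numpy(dtype=float)
    vp1 = analysis.values[cols["P1"]].to_numpy(dtype=float)
    vp2 = analysis.values[cols["P2"]].to_numpy(dtype=float)
    # ties resolve to P1 = "high" here; classify_gene ignores the parent
    # tests for tied genes, so the choice is inert
    high = np.where(p1_high[:, None], vp1, vp2)
    low = np.where(p1_high[:, None], vp2, vp1)

    if mpv_test == "one-sample":
        p_mpv = _one_sample_tests(f1, popmean, moderate)
    else:
        # sensitivity variant: Welch of F1 against the pooled parental
        # values re-centered onto the MPV
        pooled = np.concatenate([vp1, vp2], axis=1)
        recentered = pooled - pooled.mean(axis=1, keepdims=True) + popmean[:, None]
        p_mpv = _two_sample_tests(f1, recentered, moderate)
    p_high = _two_sample_tests(f1, high, moderate)
    p_low = _two_sample_tests(f1, low, moderate)

    q_mpv = by_adjust(p_mpv)
    q_high = by_adjust(p_high)
    q_low = by_adjust(p_low)

    category = [
        classify_gene(
            q_mpv[i], q_high[i], q_low[i],
            mean_f1[i], mean_high[i], mean_low[i],
            high_parent[i], alpha,
        )
        for i in range(len(mpv))
    ]
    return pd.DataFrame(
        {
            "gene_id": norm.values.index,
            "mpv": mpv,
            "mean_p1": mean_p1,
            "mean_p2": mean_p2,
            "mean_f1": mean_f1,
            "high_parent": high_parent,
            "p_mpv": p_mpv,
            "q_mpv": q_mpv,
            "p_high": p_high,
            "q_high": q_high,
            "p_low": p_low,
            "q_low": q_low,
            "category": category,
        },
        columns=list(PATTERN_COLUMNS),
    ).reset_index(drop=True)


def run_pattern_analysis(
    cm: CountMatrix,
    tissue: str,
    alpha: float = 0.05,
    scale: str = "log",
    mpv_test: str = "one-sample",
    moderate: bool = True,
    align: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-tissue analysis: filter, normalize, test, correct, classify.

    Returns one GenePatternRecord row per candidate gene.  Deterministic
    for fixed input.
    """
    candidates = filter_candidates(cm, tissue)
    samples = list(cm.meta.index[cm.meta["tissue"] == tissue])
    sub = cm.subset_samples(samples)
    for g in ("P1", "P2", "F1"):
        if (sub.meta["group"] == g).sum() < 2:
            raise ValueError(f"tissue {tissue!r} needs >= 2 samples in group {g}")
    if not candidates:
        return pd.DataFrame(columns=PATTERN_COLUMNS)
    norm = normalize_cpm(sub)  # library sizes from all genes, not candidates
    norm = NormalizedMatrix(
        norm.values.loc[candidates], norm.meta, norm.method_tag
    )
    return classify_matrix(
        norm,
        alpha=alpha,
        scale=scale,
        mpv_test=mpv_test,
        moderate=moderate,
        align=align,
        pseudocount=pseudocount,
    )
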