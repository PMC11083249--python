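"""Reporting layer: pattern-count summaries, top-N genes, PCA QC."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import NormalizedMatrix
from .normalize import log_transform
from .patterns import CATEGORIES


def format_percent(fraction: float) -> str:
    """Render a fraction as a percent with one decimal, half away from zero."""
    pct = Decimal(repr(float(fraction) * 100.0)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return f"{pct}%"


@dataclass
class PatternSummary:
    tissue: str
    n_candidates: int
    counts: dict[str, int]
    fraction_additive: float
    fraction_nonadditive: float

    def render(self) -> str:
        lines = [
            f"tissue: {self.tissue}",
            f"candidate genes: {self.n_candidates}",
        ]
        for cat in CATEGORIES:
            lines.append(f"  {cat}: {self.counts.get(cat, 0)}")
        lines.append(f"additive fraction: {format_percent(self.fraction_additive)}")
        lines.append(
            f"non-additive fraction: {format_percent(self.fraction_nonadditive)}"
        )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        row = {"tissue": self.tissue, "n_candidates": self.n_candidates}
        for cat in CATEGORIES:
            row[cat] = self.counts.get(cat, 0)
        row["fraction_additive"] = self.fraction_additive
        row["fraction_nonadditive"] = self.fraction_nonadditive
        row["pct_additive"] = format_percent(self.fraction_additive)
        row["pct_nonadditive"] = format_percent(self.fraction_nonadditive)
        return pd.DataFrame([row])


def summarize_patterns(records: pd.DataFrame, tissue: str = "") -> PatternSummary:
    """Category counts and additive/non-additive fractions over testable genes.

    ``records`` needs only a ``category`` column.  Fractions are computed
    over testable candidates (excluding not_testable) and sum to 1.
    """
    counts = {cat: 0 for cat in CATEGORIES}
    if len(records):
        observed = records["category"].value_counts().to_dict()
        unknown = sorted(set(observed) - set(CATEGORIES))
        if unknown:
            raise ValueError(f"unknown category value(s) {unknown}")
        counts.update(observed)
    n_candidates = int(len(records))
    testable = n_candidates - counts["not_testable"]
    if testable > 0:
        frac_add = counts["additive"] / testable
        frac_non = (testable - counts["additive"]) / testable
    else:
        frac_add = frac_non = 0.0
    return PatternSummary(tissue, n_candidates, counts, frac_add, frac_non)


def top_genes(
    norm: NormalizedMatrix, sample_ids: list[str], n: int = 10
) -> pd.DataFrame:
    """Top-n genes by summed expression over a sample set.

    Ties are broken by gene_id (lexicographic), and asking for more genes
    than exist returns all of them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not sample_ids:
        raise ValueError("sample_set must be non-empty")
    missing = [s for s in sample_ids if s not in norm.values.columns]
    if missing:
        raise ValueError(f"unknown sample(s) {missing}")
    totals = norm.values[list(sample_ids)].sum(axis=1)
    order = (
        pd.DataFrame({"gene_id": totals.index, "total_expression": totals.to_numpy()})
        .sort_values(
            ["total_expression", "gene_id"], ascending=[False, True], kind="mergesort"
        )
        .head(n)
        .reset_index(drop=True)
    )
    order["rank"] = np.arange(1, len(order) + 1)
    return order


def pca_qc(norm: NormalizedMatrix, pseudocount: float = 1.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the first two principal components.

    Runs on gene-centered log-scale values (a linear matrix is log2
    transformed first).  The sign of each component is fixed by making
    its largest-magnitude gene loading positive, so coordinates are
    reproducible bit-for-bit.  Returns (coordinates, variance-explained
    fractions).
    """
    if norm.values.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if norm.values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 genes")
    if not norm.is_log_scale:
        norm = log_transform(norm, pseudocount)
    x = norm.values.to_numpy(dtype=float).T  # samples x genes
    n_comp = min(2, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    for k in range(n_comp):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            coords[:, k] = -coords[:, k]
    frame = pd.DataFrame(
        coords,
        index=norm.values.columns,
        columns=[f"PC{k + 1}" for k in range(n_comp)],
    )
    frame.index.name = "sample_id"
    return frame, pca.explained_variance_ratio_.copy()


def deg_count_table(deg_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Up/down/total DEG counts per contrast (one row per contrast table)."""
    rows = []
    for table in deg_tables:
        contrast = table["contrast"].iloc[0] if len(table) else ""
        deg = table[table["is_deg"]] if len(table) else table
        n_up = int((deg["direction"] == "up").sum()) if len(table) else 0
        n_down = int((deg["direction"] == "down").sum()) if len(table) else 0
        rows.append(
            {
                "contrast": contrast,
                "n_deg": int(len(deg)),
                "n_up": n_up,
                "n_down": n_down,
            }
        )
    return pd.DataFrame(rows, columns=["contrast", "n_deg", "n_up", "n_down"])
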