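"""Synthetic two-parent/F1 count data with known inheritance modes.

Emulates the study design the pipeline targets: three groups (paternal
line P1, maternal line P2, F1 cross) with a handful of biological
replicates each, gene-level negative-binomial counts, and per-sample
library-size variation.  Every gene carries a ground-truth inheritance
mode, so classifier recovery can be measured exactly.

The noise model is the standard bulk RNA-seq one: counts ~ NB with
variance = mean + dispersion * mean^2.  Library-size factors are
log-normal with mean 1 and a configurable coefficient of variation.
The higher-expressing parent alternates gene-by-gene between P1 and P2
so "high parent" is never confounded with one line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix

#: inheritance modes the generator (and classifier) know about.
#: null_equal (all three groups share one mean) is generated to measure the
#: false-non-additive rate; its correct classification is "additive".
MODES = (
    "additive",
    "enhancing_dominance",
    "suppressing_dominance",
    "over_dominance",
    "under_dominance",
    "null_equal",
)


@dataclass
class SimConfig:
    """Generative parameters for :func:`simulate_cross`.

    n_genes_per_mode
        genes to draw for each inheritance mode (missing modes mean 0).
    n_per_group
        biological replicates per group (default 6, the study design).
    base_mean
        expected count of the low parent (and of null_equal genes).
    effect_log2
        parental log2 expression difference (high parent = base * 2**effect).
    overshoot_log2
        F1 excess beyond the high parent (over-dominance) or deficit below
        the low parent (under-dominance), in log2 units.
    dispersion
        NB dispersion; variance = mean + dispersion * mean**2.
    libsize_cv
        coefficient of variation of per-sample library-size factors.
    """

    n_genes_per_mode: Mapping[str, int] = field(
        default_factory=lambda: {m: 100 for m in MODES}
    )
    n_per_group: int = 6
    base_mean: float = 100.0
    effect_log2: float = 2.0
    overshoot_log2: float = 1.0
    dispersion: float = 0.1
    libsize_cv: float = 0.1
    seed: int = 0
    tissue: str = "breast_muscle"

    def validate(self) -> None:
        unknown = sorted(set(self.n_genes_per_mode) - set(MODES))
        if unknown:
            raise ValueError(f"unknown mode(s) {unknown}; allowed: {list(MODES)}")
        for mode, n in self.n_genes_per_mode.items():
            if int(n) != n or n < 0:
                raise ValueError(f"gene count for {mode} must be a non-negative integer")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (t-tests need replicates)")
        for name in ("base_mean", "effect_log2", "overshoot_log2", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.libsize_cv < 0:
            raise ValueError("libsize_cv must be >= 0")


def nb_draw(mean: float, dispersion: float, rng: np.random.Generator) -> int:
    """One negative-binomial draw with variance = mean + dispersion*mean**2."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    size_r = 1.0 / dispersion
    return int(rng.negative_binomial(size_r, size_r / (size_r + mean)))


def _nb_sample(means: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    size_r = 1.0 / dispersion
    return rng.negative_binomial(size_r, size_r / (size_r + means))


def _library_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Log-normal factors with mean exactly 1 and sd/mean = cv; cv=0 -> all 1."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)


def _mode_means(mode: str, mu_low: float, mu_high: float, high_is_p1: bool,
                overshoot_log2: float) -> tuple[float, float, float]:
    if mode == "null_equal":
        return mu_low, mu_low, mu_low
    mu_p1, mu_p2 = (mu_high, mu_low) if high_is_p1 else (mu_low, mu_high)
    if mode == "additive":
        mu_f1 = (mu_p1 + mu_p2) / 2.0
    elif mode == "enhancing_dominance":
        mu_f1 = max(mu_p1, mu_p2)
    elif mode == "suppressing_dominance":
        mu_f1 = min(mu_p1, mu_p2)
    elif mode == "over_dominance":
        mu_f1 = max(mu_p1, mu_p2) * 2.0**overshoot_log2
    elif mode == "under_dominance":
        mu_f1 = min(mu_p1, mu_p2) / 2.0**overshoot_log2
    else:  # pragma: no cover - guarded by SimConfig.validate
        raise ValueError(f"unknown mode {mode!r}")
    return mu_p1, mu_p2, mu_f1


def _make_meta(config: SimConfig) -> pd.DataFrame:
    rows = []
    for group in ("P1", "P2", "F1"):
        for i in range(config.n_per_group):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1}",
                    "group": group,
                    "tissue": config.tissue,
                    # balanced sexes within each group, as in a designed cross
                    "sex": "M" if i % 2 == 0 else "F",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_cross(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a CountMatrix and its gene-level truth table.

    The truth table has columns gene_id, mode, mu_p1, mu_p2, mu_f1 (the
    generative means before library-size scaling).  Identical configs
    (including seed) produce byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _make_meta(config)
    n = config.n_per_group

    mu_low = float(config.base_mean)
    mu_high = mu_low * 2.0**config.effect_log2

    truth_rows = []
    gene_index = 0
    for mode in MODES:
        for _ in range(int(config.n_genes_per_mode.get(mode, 0))):
            high_is_p1 = gene_index % 2 == 0
            mu_p1, mu_p2, mu_f1 = _mode_means(
                mode, mu_low, mu_high, high_is_p1, config.overshoot_log2
            )
            truth_rows.append(
                {
                    "gene_id": f"g{gene_index:06d}",
                    "mode": mode,
                    "mu_p1": mu_p1,
                    "mu_p2": mu_p2,
                    "mu_f1": mu_f1,
                }
            )
            gene_index += 1
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "mode", "mu_p1", "mu_p2", "mu_f1"]
    )

    factors = _library_factors(rng, 3 * n, config.libsize_cv)
    if truth.empty:
        counts = pd.DataFrame(
            np.zeros((0, 3 * n), dtype=np.int64), columns=meta.index
        )
        counts.index.name = "gene_id"
        return CountMatrix(counts, meta), truth

    mus = truth[["mu_p1", "mu_p2", "mu_f1"]].to_numpy()  # G x 3
    mean_mat = np.repeat(mus, n, axis=1) * factors  # G x 3n, sample-major per group
    draws = _nb_sample(mean_mat, config.dispersion, rng)
    counts = pd.DataFrame(
        draws.astype(np.int64), index=truth["gene_id"].to_numpy(), columns=meta.index
    )
    counts.index.name = "gene_id"
    return CountMatrix(counts, meta), truth
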