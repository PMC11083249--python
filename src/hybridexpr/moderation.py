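"""Empirical-Bayes variance moderation for per-gene t-tests.

With a handful of replicates per group, per-gene sample variances are
noisy and the resulting t-tests lose power.  Following the standard
hierarchical model for gene-wise variances (scaled inverse-chi-square
prior with ``d0`` prior degrees of freedom and prior value ``s02``), the
posterior variance

    s2_post = (d0 * s02 + df * s2) / (d0 + df)

replaces the raw sample variance and the t-statistic gains ``d0`` extra
degrees of freedom.  ``d0`` and ``s02`` are estimated from the observed
variance distribution by the trigamma method of moments: under the model,
log(s2) has variance trigamma(df/2) + trigamma(d0/2), so the excess
spread of log-variances over the pure-chi-square expectation identifies
d0.  Homogeneous variances give d0 = inf (complete pooling); strongly
heterogeneous variances give small d0 (little pooling), recovering the
ordinary t-test.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def inverse_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration).

    trigamma is strictly decreasing on (0, inf) with range (0, inf);
    x <= 0 maps to +inf.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    # starting value with correct asymptotics (trigamma(y) ~ 1/y for large y)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s02) of the inverse-chi-square variance prior.

    ``s2`` are per-gene sample variances on ``df`` degrees of freedom.
    Zero variances are excluded from the fit.  Returns d0 = inf and the
    arithmetic mean variance when the observed spread does not exceed the
    chi-square expectation (variances look homogeneous).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(s2.mean()) if len(s2) else 1.0
    z = np.log(s2)
    excess = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * inverse_trigamma(excess)
    log_s0 = (
        float(np.mean(z))
        - float(special.polygamma(0, df / 2.0))
        + np.log(df / 2.0)
        + float(special.polygamma(0, d0 / 2.0))
        - np.log(d0 / 2.0)
    )
    return d0, float(np.exp(log_s0))


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene variances toward the fitted prior.

    Returns (posterior variances, d0, s02).  With d0 = inf every posterior
    variance equals s02.
    """
    s2 = np.asarray(s2, dtype=float)
    d0, s02 = fit_variance_prior(s2, df)
    if np.isinf(d0):
        return np.full_like(s2, s02), d0, s02
    return (d0 * s02 + df * s2) / (d0 + df), d0, s02


def total_df(df: float, d0: float, cap: float = 1e6) -> float:
    """Degrees of freedom of the moderated t-statistic (df + d0, capped)."""
    return float(min(df + d0, cap))
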