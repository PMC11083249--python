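import numpy as np
import pandas as pd
import pytest

from hybridexpr import MODES, CountMatrix, SimConfig, simulate_cross


def brute_force_stepup(p_values, by: bool = False) -> np.ndarray:
    """Independent step-up FDR oracle (BH; BY when ``by`` is set).

    Literal definition: sort ascending, multiply by m/k (times the
    harmonic sum c(m) for BY), enforce monotonicity by a running minimum
    from the largest p, clip at 1, restore input order.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    c = sum(1.0 / i for i in range(1, m + 1)) if by else 1.0
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for idx in range(m - 1, -1, -1):
        k = idx + 1
        value = p[order[idx]] * m * c / k
        running = min(running, value)
        adjusted[order[idx]] = running
    return adjusted


@pytest.fixture
def toy_cm() -> CountMatrix:
    meta = pd.DataFrame(
        {
            "sample_id": ["p1a", "p1b", "p2a", "p2b", "f1a", "f1b"],
            "group": ["P1", "P1", "P2", "P2", "F1", "F1"],
            "tissue": ["liver"] * 6,
            "sex": ["M", "F", "M", "F", "M", "F"],
        }
    ).set_index("sample_id")
    counts = pd.DataFrame(
        np.array(
            [
                [10, 12, 40, 44, 25, 27],
                [100, 90, 10, 12, 50, 55],
                [0, 1, 0, 2, 1, 0],
            ]
        ),
        index=["gA", "gB", "gC"],
        columns=meta.index,
    )
    counts.index.name = "gene_id"
    return CountMatrix(counts, meta)


@pytest.fixture(scope="session")
def strong_sim():
    """Strong-signal simulation shared by recovery-style tests."""
    config = SimConfig(
        n_genes_per_mode={m: 50 for m in MODES},
        n_per_group=6,
        effect_log2=3.0,
        overshoot_log2=1.5,
        dispersion=0.05,
        seed=11,
    )
    return simulate_cross(config)
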