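"""Library-size normalization and variance-stabilizing transforms.

The pipeline works on counts-per-million (CPM): value(g, s) =
count(g, s) / column_sum(s) * 1e6.  CPM is deterministic and adequate
when library compositions are comparable across groups; when the F1
transcriptome's total output differs from the parents' (many strongly
over- or under-dominant genes), :func:`align_f1_to_midparent` removes
the resulting global offset under the assumption that the *median* gene
is additive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix, NormalizedMatrix


def normalize_cpm(cm: CountMatrix) -> NormalizedMatrix:
    """Counts per million by total column count; method_tag = "cpm"."""
    libsize = cm.counts.sum(axis=0)
    zero = libsize.index[libsize == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) {zero} have zero total count")
    values = cm.counts / libsize * 1e6
    return NormalizedMatrix(values, cm.meta.copy(), "cpm")


def log_transform(norm: NormalizedMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """value' = log2(value + pseudocount); appended to the method tag."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    values = np.log2(norm.values + pseudocount)
    return NormalizedMatrix(
        values, norm.meta.copy(), norm.method_tag + f"+log2(x+{pseudocount:g})"
    )


def group_means(norm: NormalizedMatrix, group: str) -> pd.Series:
    """Per-gene mean over the samples of one group, on the matrix's scale."""
    cols = norm.samples_in_group(group)
    if not cols:
        raise ValueError(f"no samples in group {group!r}")
    return norm.values[cols].mean(axis=1)


def align_f1_to_midparent(
    norm: NormalizedMatrix, pseudocount: float = 1.0
) -> tuple[NormalizedMatrix, float]:
    """Rescale F1 columns so the median gene sits on its mid-parent value.

    Pure per-library scaling (CPM) measures *relative* expression: if the
    F1 transcriptome's total output genuinely differs from the parental
    mid-point (e.g. many over-dominant genes), every F1 CPM value absorbs
    a common multiplicative offset and even truly additive genes appear
    shifted from the MPV.  This step estimates that offset as the median
    over genes of log2((mean_F1 + pc) / (MPV + pc)) and divides it out of
    the F1 columns — i.e. it assumes the median gene expresses additively,
    the transcriptome-level analogue of the "most genes are not DE"
    assumption behind TMM/RLE scaling.

    Expects a linear-scale matrix.  Returns the aligned matrix (method_tag
    + "+f1align") and the removed offset in log2 units.
    """
    if norm.is_log_scale:
        raise ValueError("align_f1_to_midparent expects a linear-scale matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    f1_cols = norm.samples_in_group("F1")
    if not f1_cols:
        raise ValueError("no F1 samples to align")
    mean_f1 = norm.values[f1_cols].mean(axis=1)
    mpv = (group_means(norm, "P1") + group_means(norm, "P2")) / 2.0
    d = np.log2(mean_f1 + pseudocount) - np.log2(mpv + pseudocount)
    delta = float(np.median(d)) if len(d) else 0.0
    values = norm.values.copy()
    values[f1_cols] = values[f1_cols] * 2.0 ** (-delta)
    return (
        NormalizedMatrix(values, norm.meta.copy(), norm.method_tag + "+f1align"),
        delta,
    )
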