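"""Count-matrix and result-table I/O with validation.

All tables are UTF-8, tab-separated text with a header row and LF line
endings.  The count file has a first column ``gene_id`` and one integer
column per sample; the metadata file has columns ``sample_id``, ``group``
(one of P1/P2/F1), ``tissue`` and ``sex`` (M/F/unknown).  Sample column
order always follows the metadata table, which is the single source of
truth for group assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("P1", "P2", "F1")
SEXES = ("M", "F", "unknown")

META_COLUMNS = ("sample_id", "group", "tissue", "sex")

#: float rendering used for every result table (6 significant digits)
FLOAT_FORMAT = "%.6g"


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (index = sample_id)."""
    for col in ("group", "tissue", "sex"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dups}")
    bad_group = sorted(set(meta["group"]) - set(GROUPS))
    if bad_group:
        raise ValueError(
            f"invalid group value(s) {bad_group}; allowed: {list(GROUPS)}"
        )
    bad_sex = sorted(set(meta["sex"]) - set(SEXES))
    if bad_sex:
        raise ValueError(f"invalid sex value(s) {bad_sex}; allowed: {list(SEXES)}")
    return meta


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus aligned sample metadata.

    ``counts`` is a pandas DataFrame indexed by gene_id with one column per
    sample; ``meta`` is indexed by sample_id with columns group/tissue/sex.
    Column order of ``counts`` equals the row order of ``meta``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        validate_meta(self.meta)
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene_id: {dups}")
        missing = [s for s in self.counts.columns if s not in self.meta.index]
        if missing:
            raise ValueError(
                f"sample(s) {missing} in count matrix but not in metadata"
            )
        extra = [s for s in self.meta.index if s not in self.counts.columns]
        if extra:
            raise ValueError(
                f"sample(s) {extra} in metadata but not in count matrix"
            )
        # reorder columns to metadata order
        self.counts = self.counts.loc[:, list(self.meta.index)]
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        arr = self.counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError("count matrix contains non-numeric cells")
            bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.floor(arr))
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValueError(
                    "count matrix cell is not a non-negative integer at "
                    f"gene {self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[:, sample_ids].copy(), self.meta.loc[sample_ids].copy()
        )

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids].copy(), self.meta.copy())


@dataclass
class NormalizedMatrix:
    """Per-sample scaled expression values; same layout as CountMatrix.

    ``method_tag`` records the normalization chain applied (e.g. ``"cpm"``,
    ``"cpm+log2(x+1)"``) so result tables are self-describing.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    method_tag: str = "none"

    def __post_init__(self) -> None:
        validate_meta(self.meta)
        if list(self.values.columns) != list(self.meta.index):
            missing = [s for s in self.values.columns if s not in self.meta.index]
            if missing:
                raise ValueError(
                    f"sample(s) {missing} in value matrix but not in metadata"
                )
            self.values = self.values.loc[:, list(self.meta.index)]
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        arr = self.values.to_numpy()
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise ValueError("normalized values must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def is_log_scale(self) -> bool:
        return "log2" in self.method_tag

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; allowed: {list(GROUPS)}")
        return list(self.meta.index[self.meta["group"] == group])


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata file is missing column {col!r}")
    meta = meta.set_index("sample_id")
    return validate_meta(meta)


def read_counts(path, meta_path) -> CountMatrix:
    """Read a gene x sample count TSV together with its sample metadata.

    Fails (naming the offending sample/gene/cell) rather than silently
    dropping anything that does not match.
    """
    meta = read_meta(meta_path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = "gene_id"
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, path, meta_path=None) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")
    if meta_path is not None:
        write_meta(cm.meta, meta_path)


def write_meta(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def write_norm(norm: NormalizedMatrix, path) -> None:
    out = norm.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


def read_norm(path, meta_path, method_tag: str = "unknown") -> NormalizedMatrix:
    meta = read_meta(meta_path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    return NormalizedMatrix(values, meta, method_tag)


def write_table(records: pd.DataFrame, path) -> None:
    """Write any result table as TSV with deterministic column order and
    floats rendered to 6 significant digits.  An empty table yields a file
    containing only the header line."""
    records.to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
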