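"""Expression-matrix container, low-signal filtering, batch adjustment and
orthologue mapping — the steps applied before network construction.

The container is a thin wrapper around a features x samples
:class:`pandas.DataFrame` plus a per-sample metadata frame (time, batch,
cell type).  All tables round-trip through TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "OrthologueMap",
    "FilterReport",
    "filter_low_signal",
    "batch_adjust",
    "map_orthologues",
]


@dataclass
class ExpressionMatrix:
    """A features x samples numeric expression table with sample metadata.

    Parameters
    ----------
    values
        Numeric table, features in rows, samples in columns.  Log2 intensity
        for time courses, TPM (or log-TPM) for promoter atlases.
    sample_meta
        One row per sample (index aligned with ``values.columns``); typical
        columns are ``time_h``, ``batch`` and ``cell_type``.  May be empty.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        self.values = self.values.rename_axis(index=None, columns=None)
        if self.sample_meta.index.empty and self.sample_meta.columns.empty:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        else:
            self.sample_meta = self.sample_meta.rename_axis(index=None)
            if not self.sample_meta.index.equals(self.values.columns):
                missing = set(self.values.columns) ^ set(self.sample_meta.index)
                raise ValueError(
                    f"sample metadata index does not match sample ids: {sorted(missing)}"
                )
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression values must be numeric")

    # -- basic introspection -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, features: Iterable[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``features`` (order preserved)."""
        features = list(features)
        return ExpressionMatrix(self.values.loc[features], self.sample_meta.copy())

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally the sample metadata) as TSV."""
        self.values.to_csv(path, sep="\t", index_label="feature_id")
        if meta_path is not None:
            self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls, path: str | Path, meta_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        meta = pd.DataFrame()
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
            meta.index = meta.index.astype(str)
        return cls(values, meta)


@dataclass
class OrthologueMap:
    """Mapping from source-species gene ids to one or more target ids."""

    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for src, targets in dict(self.mapping).items():
            targets = frozenset(targets)
            if not targets:
                raise ValueError(f"empty target set for source id {src!r}")
            clean[src] = targets
        self.mapping = clean

    def __contains__(self, src: str) -> bool:
        return src in self.mapping

    def __getitem__(self, src: str) -> frozenset[str]:
        return self.mapping[src]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologueMap":
        """Read a two-column (source, target) TSV, one pair per line."""
        df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"],
                         dtype=str, comment="#")
        grouped = df.groupby("source")["target"].apply(frozenset).to_dict()
        return cls(grouped)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (src, tgt)
            for src in sorted(self.mapping)
            for tgt in sorted(self.mapping[src])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class FilterReport:
    """Bookkeeping for a low-signal filter pass."""

    n_removed: int
    removed_ids: list[str]
    min_value: float


def filter_low_signal(
    matrix: ExpressionMatrix, min_value: float
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop features whose signal never exceeds ``min_value``.

    A feature is retained iff its maximum across samples is strictly greater
    than ``min_value`` — i.e. it exceeds the floor in at least one sample.
    A feature sitting exactly at the floor everywhere is removed.

    Returns the filtered matrix (sample set unchanged) and a report with the
    removed ids.  Raises ``ValueError`` on an empty matrix or negative floor.
    """
    if min_value < 0:
        raise ValueError("min_value must be >= 0")
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise ValueError("cannot filter an empty expression matrix")
    maxima = matrix.values.max(axis=1)
    keep = maxima > min_value
    removed = [str(i) for i in matrix.values.index[~keep]]
    filtered = ExpressionMatrix(matrix.values.loc[keep].copy(), matrix.sample_meta.copy())
    return filtered, FilterReport(len(removed), removed, float(min_value))


def batch_adjust(
    matrix: ExpressionMatrix,
    batch_labels: Mapping[str, str] | pd.Series | None = None,
    scale: bool = False,
) -> ExpressionMatrix:
    """Remove per-feature batch location (and optionally scale) effects.

    Each feature's values within a batch are shifted so every batch mean
    equals the feature's pooled mean; with ``scale=True`` batch standard
    deviations are additionally rescaled to the pooled SD.  This is a plain
    location/scale standardization: it removes the additive (and
    multiplicative) component of a batch effect without any shrinkage across
    features.

    ``batch_labels`` maps sample id -> batch label; when omitted the
    ``batch`` column of the sample metadata is used.  Every batch must hold
    at least two samples (merge upstream otherwise).
    """
    if batch_labels is None:
        if "batch" not in matrix.sample_meta.columns:
            raise ValueError("no batch labels given and sample_meta has no 'batch' column")
        labels = matrix.sample_meta["batch"]
    else:
        labels = pd.Series(dict(batch_labels))
    labels = labels.reindex(matrix.values.columns)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"samples without batch label: {missing}")

    counts = labels.value_counts()
    singletons = counts[counts < 2]
    if not singletons.empty:
        raise ValueError(
            "batches with a single sample cannot be adjusted: "
            f"{sorted(singletons.index.astype(str))}; merge them with another batch"
        )

    X = matrix.values.to_numpy(dtype=float, copy=True)
    pooled_mean = X.mean(axis=1, keepdims=True)
    pooled_sd = X.std(axis=1, ddof=0, keepdims=True)
    out = X.copy()
    for batch in counts.index:
        cols = np.flatnonzero((labels == batch).to_numpy())
        block = X[:, cols]
        b_mean = block.mean(axis=1, keepdims=True)
        if scale:
            b_sd = block.std(axis=1, ddof=0, keepdims=True)
            ratio = np.divide(
                pooled_sd, b_sd, out=np.ones_like(b_sd), where=b_sd > 0
            )
            out[:, cols] = (block - b_mean) * ratio + pooled_mean
        else:
            out[:, cols] = block - b_mean + pooled_mean
    if not np.isfinite(out).all():
        raise ValueError("batch adjustment produced non-finite values")
    adjusted = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(adjusted, matrix.sample_meta.copy())


@dataclass
class OrthologueAudit:
    mapped: dict[str, frozenset[str]]
    ambiguous: list[str]
    unmapped: list[str]


def map_orthologues(
    genes: Iterable[str],
    omap: OrthologueMap,
    policy: str = "keep_all",
) -> tuple[list[str], OrthologueAudit]:
    """Translate gene ids through an orthologue map.

    One-to-one mappings pass through.  One-to-many mappings are resolved per
    ``policy``: ``"keep_all"`` (default) keeps every target and flags the
    source as ambiguous; ``"first"`` keeps the lexicographically smallest
    target.  Unmapped genes are data, not errors: they are listed in the
    audit and omitted from the output.
    """
    if policy not in ("keep_all", "first"):
        raise ValueError(f"unknown policy {policy!r}")
    mapped: dict[str, frozenset[str]] = {}
    ambiguous: list[str] = []
    unmapped: list[str] = []
    out: list[str] = []
    seen: set[str] = set()
    for gene in genes:
        if gene not in omap:
            unmapped.append(gene)
            continue
        targets = omap[gene]
        if len(targets) > 1:
            ambiguous.append(gene)
            if policy == "first":
                targets = frozenset([min(targets)])
        mapped[gene] = targets
        for tgt in sorted(targets):
            if tgt not in seen:
                seen.add(tgt)
                out.append(tgt)
    return out, OrthologueAudit(mapped, ambiguous, unmapped)
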