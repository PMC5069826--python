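"""The expression-matrix container shared by every pipeline stage.

An :class:`ExpressionMatrix` is a features × samples numeric table plus the
two pieces of metadata every stage needs: the measurement scale and a
feature→gene map (identity when the features already are genes, a probe→gene
map for probe-level microarray data).  Values may contain missing entries
(NaN); count-scale matrices must be non-negative where observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised measurement scales.
SCALES = ("log2", "count", "fpkm", "zscore", "median_centered")


@dataclass
class ExpressionMatrix:
    """Features × samples expression values with scale and gene mapping.

    Parameters
    ----------
    values
        DataFrame with unique feature IDs as index and unique sample IDs as
        columns.  NaN marks a missing measurement.
    scale
        One of :data:`SCALES`.
    feature_to_gene
        Map feature ID → gene symbol.  ``None`` means the features are genes
        themselves (identity map).
    """

    values: pd.DataFrame
    scale: str
    feature_to_gene: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        self.values = self.values.astype(float)
        if self.scale == "count":
            arr = self.values.to_numpy()
            if np.nanmin(arr) < 0 if arr.size else False:
                raise ValueError("count-scale matrix contains negative values")
        if self.feature_to_gene is not None:
            missing = [f for f in self.values.index if f not in self.feature_to_gene]
            if missing:
                raise ValueError(f"feature_to_gene lacks entries for {missing[:5]}...")

    # -- metadata -------------------------------------------------------

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

    def gene_of(self, feature_id: str) -> str:
        if self.feature_to_gene is None:
            return feature_id
        return self.feature_to_gene[feature_id]

    def genes(self) -> list[str]:
        """Unique gene symbols covered, in first-appearance order."""
        seen: dict[str, None] = {}
        for f in self.feature_ids:
            seen.setdefault(self.gene_of(f), None)
        return list(seen)

    def gene_map(self) -> pd.Series:
        """feature_id → gene symbol as a Series (identity expanded)."""
        return pd.Series({f: self.gene_of(f) for f in self.feature_ids}, name="gene_symbol")

    # -- subsetting -----------------------------------------------------

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        feature_ids = list(feature_ids)
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        fmap = None
        if self.feature_to_gene is not None:
            fmap = {f: self.feature_to_gene[f] for f in feature_ids}
        return ExpressionMatrix(self.values.loc[feature_ids].copy(), self.scale, fmap)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        fmap = dict(self.feature_to_gene) if self.feature_to_gene is not None else None
        return ExpressionMatrix(self.values[sample_ids].copy(), self.scale, fmap)

    # -- I/O ------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the value table as UTF-8 TSV, feature IDs in the first column."""
        df = self.values.copy()
        df.index.name = "feature_id"
        try:
            df.to_csv(path, sep="\t", lineterminator="\n")
        except OSError as exc:
            raise OSError(f"failed writing expression matrix to {path}: {exc}") from exc

    @classmethod
    def from_tsv(cls, path, scale: str, feature_to_gene: dict[str, str] | None = None) -> "ExpressionMatrix":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        except OSError as exc:
            raise OSError(f"failed reading expression matrix from {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        return cls(df, scale, feature_to_gene)


def write_feature_map(mapping: dict[str, str], path) -> None:
    """Write a probe→gene two-column TSV (probe_id, gene_symbol)."""
    pd.Series(mapping, name="gene_symbol").rename_axis("probe_id").to_csv(
        path, sep="\t", lineterminator="\n"
    )


def read_feature_map(path) -> dict[str, str]:
    s = pd.read_csv(path, sep="\t", index_col=0)["gene_symbol"]
    return {str(k): str(v) for k, v in s.items()}
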