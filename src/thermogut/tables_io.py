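"""Tabular I/O for the three table kinds the pipeline touches.

All on-disk formats are plain UTF-8 TSV (lines starting with ``#`` are
ignored).  Feature tables hold non-negative integer counts (taxa) or
non-negative reals (transcripts); metadata is one row per sample with a
fixed set of experimental factors; expression matrices are normalized
non-negative real abundances with samples as rows.

Sample order is canonicalized lexicographically by sample id so that
permutation-based statistics are reproducible regardless of input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TOLERANCE_LEVELS = ("resistant", "sensitive")
TEMPERATURE_LEVELS = ("warm24", "cold12")
PART_LEVELS = ("anterior", "posterior")

METADATA_COLUMNS = ("sample_id", "tolerance", "temperature", "family", "part", "fish")


class TableValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass
class FeatureTable:
    """Sample x feature count matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Samples as rows, features as columns; non-negative values.
        Integer counts are required for ``kind="taxa"``.
    kind : str
        Either ``"taxa"`` or ``"transcripts"``.
    """

    data: pd.DataFrame
    kind: str = "taxa"

    def __post_init__(self) -> None:
        if self.kind not in ("taxa", "transcripts"):
            raise TableValidationError(f"unknown table kind: {self.kind!r}")
        _check_ids(self.data.index, "sample")
        _check_ids(self.data.columns, "feature")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise TableValidationError("feature table contains non-finite values")
        if (values < 0).any():
            raise TableValidationError("feature table contains negative values")
        if self.kind == "taxa":
            if not np.allclose(values, np.round(values)):
                raise TableValidationError("taxa counts must be integers")
            self.data = self.data.round().astype(np.int64)
        self.data = self.data.sort_index().rename_axis(index=None, columns=None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def select_samples(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(ids)].copy(), kind=self.kind)

    def select_features(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(ids)].copy(), kind=self.kind)


@dataclass
class SampleMetadata:
    """Per-sample experimental factors.

    Columns: tolerance (resistant/sensitive), temperature (warm24/cold12),
    family (categorical id), part (anterior/posterior), fish (individual id).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS[1:] if c not in self.data.columns]
        if missing:
            raise TableValidationError(f"metadata missing required columns: {missing}")
        _check_ids(self.data.index, "sample")
        for col, levels in (
            ("tolerance", TOLERANCE_LEVELS),
            ("temperature", TEMPERATURE_LEVELS),
            ("part", PART_LEVELS),
        ):
            bad = set(self.data[col].astype(str)) - set(levels)
            if bad:
                raise TableValidationError(
                    f"undeclared {col} level(s): {sorted(bad)}; allowed: {levels}"
                )
        self.data = self.data.sort_index().rename_axis(index=None, columns=None)
        for col in ("tolerance", "temperature", "family", "part", "fish"):
            self.data[col] = self.data[col].astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __getitem__(self, column: str) -> pd.Series:
        return self.data[column]

    def select_samples(self, ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(ids)].copy())


@dataclass
class ExpressionMatrix:
    """Sample x transcript matrix of normalized non-negative abundances."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_ids(self.data.index, "sample")
        _check_ids(self.data.columns, "transcript")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise TableValidationError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise TableValidationError("expression matrix contains negative values")
        self.data = self.data.astype(float).sort_index().rename_axis(index=None, columns=None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def select_samples(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(ids)].copy())


def _check_ids(index, what: str) -> None:
    ids = list(index)
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TableValidationError(f"duplicate {what} ids: {dupes[:5]}")
    if any(str(i) == "" for i in ids):
        raise TableValidationError(f"empty {what} id")


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        raise TableValidationError(f"duplicate row ids in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_feature_table(
    path, orientation: str = "samples_as_rows", kind: str = "taxa"
) -> FeatureTable:
    """Read a feature table from TSV.

    ``orientation="features_as_rows"`` transposes on read so the in-memory
    layout is always samples x features.
    """
    df = _read_tsv(path)
    if orientation == "features_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return FeatureTable(df, kind=kind)


def write_feature_table(table: FeatureTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    df = _read_tsv(path)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(path) -> ExpressionMatrix:
    df = _read_tsv(path)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="sample_id")


def align_tables(table, meta: SampleMetadata):
    """Restrict a table and the metadata to their common samples.

    Both outputs use the canonical (lexicographic) sample order.  Dropped
    ids are logged.  Works for FeatureTable and ExpressionMatrix alike.

    Raises
    ------
    TableValidationError
        If the sample-id intersection is empty.
    """
    table_ids = set(table.sample_ids)
    meta_ids = set(meta.sample_ids)
    common = sorted(table_ids & meta_ids)
    if not common:
        raise TableValidationError("no samples shared between table and metadata")
    dropped_table = sorted(table_ids - meta_ids)
    dropped_meta = sorted(meta_ids - table_ids)
    if dropped_table:
        logger.info("align_tables: dropping %d table-only samples: %s",
                    len(dropped_table), dropped_table[:10])
    if dropped_meta:
        logger.info("align_tables: dropping %d metadata-only samples: %s",
                    len(dropped_meta), dropped_meta[:10])
    return table.select_samples(common), meta.select_samples(common)
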