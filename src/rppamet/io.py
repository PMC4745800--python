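"""Data containers and file input/output.

The pipeline operates on three tabular inputs — gene-expression matrices
(genes x samples, log-scale intensities), RPPA protein matrices
(antibodies x samples) and clinical/survival tables — plus GMT gene-set
collections.  This module provides thin validated containers around pandas
DataFrames, delimited-text readers/writers, duplicate-gene collapsing, and
cross-dataset quantile alignment.

Quantile convention: throughout the package quantiles are computed by linear
interpolation between order statistics (numpy's default ``method="linear"``,
the classical "type 7" definition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Quantile interpolation used everywhere (grouping, alignment, medians).
QUANTILE_METHOD = "linear"

#: Minimum number of non-missing values required per RPPA antibody.
MIN_RPPA_OBSERVATIONS = 8


def _detect_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


class _NamedMatrix:
    """Shared behaviour of feature x sample matrices backed by a DataFrame."""

    _feature_kind = "feature"
    _allow_missing = False

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str).str.strip().rename(None)
        data.columns = data.columns.astype(str).str.strip().rename(None)
        if data.empty:
            raise DataError(f"empty {type(self).__name__}")
        if data.index.duplicated().any():
            dups = sorted(set(data.index[data.index.duplicated()]))
            raise DataError(
                f"duplicate {self._feature_kind} ids: {', '.join(dups[:5])}"
            )
        if data.columns.duplicated().any():
            dups = sorted(set(data.columns[data.columns.duplicated()]))
            raise DataError(f"duplicate sample ids: {', '.join(dups[:5])}")
        try:
            data = data.astype(float)
        except (TypeError, ValueError) as exc:
            raise DataError(f"non-numeric values in matrix: {exc}") from exc
        values = data.to_numpy()
        if self._allow_missing:
            if np.isinf(values).any():
                raise DataError("infinite values in matrix")
        elif not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at {self._feature_kind} "
                f"{data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
            )
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path: str | Path, delimiter: str | None = None) -> None:
        sep = _detect_delimiter(path, delimiter)
        self.data.to_csv(path, sep=sep, index_label=self._feature_kind + "_id")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"<{type(self).__name__} {n} {self._feature_kind}s x {m} samples>"


class ExpressionMatrix(_NamedMatrix):
    """Gene-expression matrix: unique gene symbols x unique samples, finite log-scale values."""

    _feature_kind = "gene"
    _allow_missing = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


class RPPAMatrix(_NamedMatrix):
    """RPPA protein matrix: unique antibody names x samples.

    Missing values are permitted and handled pairwise downstream; antibodies
    with fewer than :data:`MIN_RPPA_OBSERVATIONS` non-missing values are
    dropped at construction with a logged warning.
    """

    _feature_kind = "protein"
    _allow_missing = True

    def __init__(self, data: pd.DataFrame):
        super().__init__(data)
        counts = self.data.notna().sum(axis=1)
        thin = counts[counts < MIN_RPPA_OBSERVATIONS]
        if len(thin):
            for pid, k in thin.items():
                logger.warning(
                    "dropping antibody %r: only %d non-missing values (< %d)",
                    pid, int(k), MIN_RPPA_OBSERVATIONS,
                )
            self.data = self.data.drop(index=thin.index)
            if self.data.empty:
                raise InsufficientDataError(
                    "no antibody has enough non-missing values"
                )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class ClinicalTable:
    """Per-sample follow-up table with DDFS-style survival semantics.

    Required columns: ``time`` (months, >= 0), ``event`` (0/1), ``arm``
    ("treated"/"control").  Any additional column is treated as a covariate.
    """

    data: pd.DataFrame

    REQUIRED = ("time", "event", "arm")
    ARMS = ("treated", "control")

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str).str.strip()
        if df.index.duplicated().any():
            raise DataError("duplicate sample_id in clinical table")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise DataError(f"clinical table missing required column {col!r}")
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        if (df["time"] < 0).any():
            raise DataError("negative follow-up time")
        if not df["event"].isin([0, 1]).all():
            raise DataError("event must be 0 or 1")
        df["arm"] = df["arm"].astype(str).str.strip()
        bad = set(df["arm"]) - set(self.ARMS)
        if bad:
            raise DataError(f"unknown arm labels: {sorted(bad)}")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="sample_id")


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            genes = [str(g).strip() for g in genes if str(g).strip()]
            if not genes:
                raise DataError(f"gene set {name!r} is empty")
            if name in clean:
                raise DataError(f"duplicate gene set name {name!r}")
            clean[str(name)] = sorted(set(genes))
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def to_gmt(self, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
        descriptions = descriptions or {}
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, id_column: str | None, delimiter: str | None) -> pd.DataFrame:
    sep = _detect_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, dtype={0: str} if id_column is None else None)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty table: {path}") from exc
    if df.empty:
        raise DataError(f"empty table: {path}")
    if id_column is None:
        id_column = df.columns[0]
    if id_column not in df.columns:
        raise DataError(f"id column {id_column!r} not found in {path}")
    df[id_column] = df[id_column].astype(str).str.strip()
    df = df.set_index(id_column)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        fresh_na = coerced.isna() & df[col].notna()
        if fresh_na.any():
            row = df.index[fresh_na.to_numpy()][0]
            raise DataError(
                f"non-numeric value at row {row!r}, column {col!r} in {path}"
            )
        df[col] = coerced
    return df


def collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene id, per sample; sort rows lexicographically.

    Collapsing is idempotent: applying it to an already-collapsed matrix is
    the identity (up to row ordering, which is made deterministic here).
    """
    collapsed = df.groupby(level=0, sort=True).mean()
    return collapsed


def read_expression_matrix(
    path: str | Path,
    id_column: str | None = None,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a genes-in-rows delimited table, collapsing duplicate gene symbols.

    Rows that share a gene id (duplicate probes mapped to one symbol) are
    replaced by the arithmetic mean of their intensities per sample.  Row
    order of the result is lexicographic by gene id.
    """
    df = _read_table(path, id_column, delimiter)
    if df.isna().any().any():
        raise DataError(f"missing values in expression matrix {path}")
    return ExpressionMatrix(collapse_duplicate_genes(df))


def read_rppa_matrix(
    path: str | Path,
    id_column: str | None = None,
    delimiter: str | None = None,
) -> RPPAMatrix:
    """Read an antibodies-in-rows delimited table. Duplicate antibody names are an error."""
    df = _read_table(path, id_column, delimiter)
    return RPPAMatrix(df)


def read_clinical_table(path: str | Path, delimiter: str | None = None) -> ClinicalTable:
    sep = _detect_delimiter(path, delimiter if delimiter is not None else ",")
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty clinical table: {path}") from exc
    if "sample_id" not in df.columns:
        raise DataError("clinical table must have a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    return ClinicalTable(df.set_index("sample_id"))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"GMT line {lineno}: fewer than 3 fields")
            name = parts[0].strip()
            if name in sets:
                raise DataError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = parts[2:]
    if not sets:
        raise DataError(f"empty GMT file: {path}")
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Cross-dataset alignment
# ---------------------------------------------------------------------------

def quantile_align(
    matrices: Sequence[ExpressionMatrix],
    q: float = 0.95,
) -> list[ExpressionMatrix]:
    """Rescale datasets so their pooled q-quantiles match the first (reference).

    Each matrix is multiplied by a single scalar chosen so that the
    q-quantile of all its values equals the q-quantile of the reference
    matrix.  This makes intensity scales comparable across platforms before
    scores are compared, while leaving within-dataset structure (and hence
    correlations) untouched.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    if not matrices:
        raise DataError("no matrices to align")
    ref_q = float(np.quantile(matrices[0].values, q, method=QUANTILE_METHOD))
    if ref_q <= 0:
        raise DataError(f"reference {q}-quantile is non-positive ({ref_q})")
    out = [ExpressionMatrix(matrices[0].data)]
    for mat in matrices[1:]:
        mat_q = float(np.quantile(mat.values, q, method=QUANTILE_METHOD))
        if mat_q <= 0:
            raise DataError(f"{q}-quantile is non-positive ({mat_q}); cannot rescale")
        out.append(ExpressionMatrix(mat.data * (ref_q / mat_q)))
    return out
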