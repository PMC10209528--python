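"""Reading, validation and matching of expression / drug-response tables.

The pipeline consumes two tables:

* a genes x samples matrix of CPM (counts-per-million) expression values, and
* a drug-response table mapping (sample, inhibitor) to an ex vivo response AUC
  (area under the dose-response viability curve; distinct from classifier
  ROC-AUC) with an optional ic50.

Responses are sparse across inhibitors: each inhibitor was assayed on its own
subset of samples, so a missing cell in a wide table is absence of a
measurement, never a zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableDialect",
    "ExpressionMatrix",
    "DrugResponseTable",
    "MatchedCohort",
    "load_expression",
    "load_drug_response",
    "filter_inhibitors",
    "match_cohort",
]


@dataclass(frozen=True)
class TableDialect:
    """How a tabular text file is laid out.

    Defaults: comma-separated, header row present, first column carries the
    row identifiers.  ``layout`` applies to response tables only: ``"long"``
    expects columns (sample_id, inhibitor, response_auc[, ic50]); ``"wide"``
    expects samples x inhibitors with AUC cells (blank = not measured).
    """

    sep: str = ","
    header: int = 0
    index_col: int = 0
    layout: str = "long"


DEFAULT_DIALECT = TableDialect()


def _find_duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Genes x samples CPM grid with unique string identifiers."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        dup_g = _find_duplicates(self.data.index)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {dup_g}")
        dup_s = _find_duplicates(self.data.columns)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = _first_non_numeric(self.data)
            raise ValueError(f"non-numeric expression value at {bad}")
        finite = np.isfinite(vals)
        if not finite.all():
            g, s = np.argwhere(~finite)[0]
            raise ValueError(
                f"non-finite expression value at gene "
                f"{self.data.index[g]!r}, sample {self.data.columns[s]!r}"
            )
        neg = vals < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise ValueError(
                f"negative CPM at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}: {vals[g, s]}"
            )

    # -- manipulation ------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy())

    def samples_by_genes(self) -> pd.DataFrame:
        """ML-oriented view: samples as rows, genes as columns."""
        return self.data.T

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> None:
        self.data.to_csv(path, sep=dialect.sep)

    @classmethod
    def from_csv(
        cls, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
    ) -> "ExpressionMatrix":
        return load_expression(path, dialect)


def _first_non_numeric(df: pd.DataFrame) -> str:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            return f"gene {df.index[i]!r}, sample {col!r} (value {df[col].iloc[i]!r})"
    return "unknown location"


def load_expression(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> ExpressionMatrix:
    """Read a genes x samples CPM table; hard-errors on invariant violations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.sep, header=dialect.header, index_col=dialect.index_col)
    dup_g = _find_duplicates(df.index.astype(str))
    if dup_g:
        raise ValueError(f"duplicate gene ids in {path.name}: {dup_g}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        raise ValueError(
            f"non-numeric expression value in {path.name}: {_first_non_numeric(df)}"
        ) from None
    return ExpressionMatrix(df)


RESPONSE_COLUMNS = ["sample_id", "inhibitor", "response_auc", "ic50"]


@dataclass
class DrugResponseTable:
    """Long-form records of (sample, inhibitor) -> response AUC (+ optional ic50).

    ic50 is parsed and stored but never used downstream; every analysis in the
    pipeline runs on the response AUC.
    """

    records: pd.DataFrame  # columns RESPONSE_COLUMNS

    def __post_init__(self) -> None:
        df = self.records
        for col in RESPONSE_COLUMNS:
            if col not in df.columns:
                if col == "ic50":
                    df = df.assign(ic50=np.nan)
                else:
                    raise ValueError(f"response table missing column {col!r}")
        df = df[RESPONSE_COLUMNS].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["inhibitor"] = df["inhibitor"].astype(str)
        df["response_auc"] = pd.to_numeric(df["response_auc"])
        df["ic50"] = pd.to_numeric(df["ic50"])
        dup = df.duplicated(subset=["sample_id", "inhibitor"])
        if dup.any():
            pairs = df.loc[dup, ["sample_id", "inhibitor"]].itertuples(index=False)
            raise ValueError(
                "duplicate (sample, inhibitor) pairs: "
                + ", ".join(f"({s}, {i})" for s, i in pairs)
            )
        if not np.isfinite(df["response_auc"].to_numpy()).all():
            raise ValueError("non-finite response_auc present")
        if (df["response_auc"].to_numpy() < 0).any():
            raise ValueError("negative response_auc present")
        self.records = df.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def inhibitors(self) -> list[str]:
        return sorted(self.records["inhibitor"].unique())

    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def subset(self, inhibitor: str) -> pd.DataFrame:
        return self.records[self.records["inhibitor"] == inhibitor]

    def counts_per_inhibitor(self) -> pd.Series:
        return self.records.groupby("inhibitor").size()

    def to_csv(self, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> None:
        if dialect.layout == "long":
            self.records.to_csv(path, sep=dialect.sep, index=False)
        else:
            wide = self.records.pivot(
                index="sample_id", columns="inhibitor", values="response_auc"
            )
            wide.to_csv(path, sep=dialect.sep)


def load_drug_response(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> DrugResponseTable:
    """Read a response table in long or wide layout.

    Wide-layout blanks become absent records (each inhibitor covers a
    different sample subset), never zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect.layout == "long":
        df = pd.read_csv(path, sep=dialect.sep, header=dialect.header)
        return DrugResponseTable(df)
    if dialect.layout == "wide":
        wide = pd.read_csv(
            path, sep=dialect.sep, header=dialect.header, index_col=dialect.index_col
        )
        long = (
            wide.stack()
            .rename("response_auc")
            .rename_axis(["sample_id", "inhibitor"])
            .reset_index()
        )
        return DrugResponseTable(long)
    raise ValueError(f"unknown response layout {dialect.layout!r}")


@dataclass
class MatchedCohort:
    """Samples for one inhibitor with both an expression column and a response."""

    inhibitor: str
    sample_ids: list[str]
    expression: ExpressionMatrix
    response_auc: np.ndarray

    def __post_init__(self) -> None:
        if list(self.expression.sample_ids) != list(self.sample_ids):
            raise ValueError("expression columns not aligned with cohort sample order")
        if len(self.response_auc) != len(self.sample_ids):
            raise ValueError("response vector not aligned with cohort sample order")
        self.response_auc = np.asarray(self.response_auc, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def filter_inhibitors(
    resp: DrugResponseTable,
    allowed: Sequence[str] | str = "all",
    min_n: int = 300,
) -> list[str]:
    """Inhibitors in ``allowed`` with at least ``min_n`` response records.

    The bound is inclusive (>= min_n).  Output is sorted lexicographically, so
    the result is deterministic and independent of record order.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = resp.counts_per_inhibitor()
    names = counts.index[counts >= min_n]
    if allowed != "all":
        allowed_set = set(allowed)
        names = [n for n in names if n in allowed_set]
    return sorted(names)


def match_cohort(
    expr: ExpressionMatrix, resp: DrugResponseTable, inhibitor: str
) -> MatchedCohort:
    """Intersect expression samples with samples measured for ``inhibitor``."""
    sub = resp.subset(inhibitor)
    if sub.empty:
        raise KeyError(f"inhibitor {inhibitor!r} absent from response table")
    have_expr = set(expr.sample_ids)
    matched = [s for s in expr.sample_ids if s in set(sub["sample_id"])]
    if not matched:
        raise ValueError(
            f"no overlap between expression samples and responses for {inhibitor!r}"
        )
    auc = sub.set_index("sample_id").loc[matched, "response_auc"].to_numpy(dtype=float)
    return MatchedCohort(
        inhibitor=inhibitor,
        sample_ids=matched,
        expression=expr.subset_samples(matched),
        response_auc=auc,
    )
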