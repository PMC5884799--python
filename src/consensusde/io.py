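"""Reading/writing DE tables and identifier harmonization.

Differential-expression tables are tab-separated UTF-8 text with a header
row naming at least an identifier, a log2 fold-change and a p-value column;
an adjusted-p column is optional and may contain ``NA``.  Heterogeneous
platform identifiers are mapped to one canonical namespace (gene symbols in
the packaged fixtures) through a single user-supplied two-column mapping
table; no live database lookups are performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ComparisonTable, FormatError, HarmonizeReport

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TableDialect:
    """Column names used by a DE-table export."""

    id_col: str = "id"
    log2fc_col: str = "log2fc"
    pvalue_col: str = "pvalue"
    adj_pvalue_col: str = "adj_pvalue"


DEFAULT_DIALECT = TableDialect()

_NA_VALUES = ["NA", "NaN", "nan", ""]


def read_comparison_table(
    path: str | Path,
    comparison_id: str,
    group_label: str,
    n_case: int,
    n_control: int,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> ComparisonTable:
    """Parse one tab-delimited DE table into a :class:`ComparisonTable`.

    Raises :class:`FormatError` naming the offending column when a mandatory
    column is absent, when the file is empty, or when a numeric cell cannot
    be parsed.  Row order is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, na_values=_NA_VALUES
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file")

    for col in (dialect.id_col, dialect.log2fc_col, dialect.pvalue_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    records = pd.DataFrame({"source_id": df[dialect.id_col].astype(str)})
    records["log2fc"] = _numeric(df[dialect.log2fc_col], dialect.log2fc_col, path)
    records["pvalue"] = _numeric(df[dialect.pvalue_col], dialect.pvalue_col, path)
    if dialect.adj_pvalue_col in df.columns:
        records["adj_pvalue"] = _numeric(
            df[dialect.adj_pvalue_col], dialect.adj_pvalue_col, path, allow_na=True
        )

    _check_ranges(records, path)
    return ComparisonTable(
        comparison_id=comparison_id,
        group_label=group_label,
        n_case=n_case,
        n_control=n_control,
        records=records,
    )


def write_comparison_table(
    table: ComparisonTable, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    """Write a DE table back to TSV using the dialect's column names."""
    df = table.records.rename(
        columns={
            "source_id": dialect.id_col,
            "log2fc": dialect.log2fc_col,
            "pvalue": dialect.pvalue_col,
            "adj_pvalue": dialect.adj_pvalue_col,
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _numeric(col: pd.Series, name: str, path: Path, allow_na: bool = False) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna() & (col.astype(str).str.strip() != "")
    if bad.any():
        raise FormatError(
            f"{path}: malformed numeric value {col[bad].iloc[0]!r} in column {name!r}"
        )
    if not allow_na and out.isna().any():
        raise FormatError(f"{path}: missing value in mandatory column {name!r}")
    return out.astype(float)


def _check_ranges(records: pd.DataFrame, path: Path) -> None:
    if not np.isfinite(records["log2fc"]).all():
        raise FormatError(f"{path}: non-finite log2fc value")
    p = records["pvalue"]
    if ((p < 0) | (p > 1)).any():
        raise FormatError(f"{path}: pvalue outside [0, 1]")
    if "adj_pvalue" in records.columns:
        q = records["adj_pvalue"].dropna()
        if ((q < 0) | (q > 1)).any():
            raise FormatError(f"{path}: adj_pvalue outside [0, 1]")


# ---------------------------------------------------------------------------
# Identifier mapping


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``source_id<TAB>canonical_id`` mapping.

    A header row is accepted and skipped if its first field is ``source_id``.
    Many-to-one mappings are allowed; duplicate source ids keep the first
    entry seen.
    """
    mapping: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{i + 1}: expected two tab-separated columns")
        src, canon = fields[0].strip(), fields[1].strip()
        if i == 0 and src.lower() == "source_id":
            continue
        if not canon:
            raise FormatError(f"{path}:{i + 1}: empty canonical id for {src!r}")
        mapping.setdefault(src, canon)
    return mapping


def harmonize(
    table: ComparisonTable,
    mapping: dict[str, str],
    unmapped_policy: str = "drop",
) -> tuple[ComparisonTable, HarmonizeReport]:
    """Attach canonical identifiers to every record of one comparison.

    Records whose ``source_id`` has no entry in ``mapping`` are either removed
    (``unmapped_policy='drop'``) or kept with the source id promoted to the
    canonical column (``'keep_source'``).  Many probes may map to one gene;
    collapsing such duplicates is deliberately deferred to the merge stage so
    the average-or-remove rule is applied exactly once.
    """
    if unmapped_policy not in ("drop", "keep_source"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    records = table.records.copy()
    canonical = records["source_id"].map(mapping)
    mapped_mask = canonical.notna()
    n_total = len(records)
    n_mapped = int(mapped_mask.sum())

    if unmapped_policy == "drop":
        records = records.loc[mapped_mask].copy()
        records["canonical_id"] = canonical.loc[mapped_mask]
    else:
        records["canonical_id"] = canonical.where(mapped_mask, records["source_id"])
    records = records.reset_index(drop=True)

    report = HarmonizeReport(
        n_total=n_total,
        n_mapped=n_mapped,
        n_unmapped=n_total - n_mapped,
        policy=unmapped_policy,
    )
    if n_total and not len(records):
        logger.warning(
            "%s: no record survived harmonization (all %d unmapped, policy=drop)",
            table.comparison_id,
            n_total,
        )
    logger.info(
        "%s: harmonized %d/%d records (%d unmapped, policy=%s)",
        table.comparison_id,
        n_mapped,
        n_total,
        report.n_unmapped,
        unmapped_policy,
    )
    return replace(table, records=records), report
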