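"""Duplicate collapse and merging of comparisons into one long table.

After harmonization several platform probes may share one canonical gene
within a comparison.  Such repeats are averaged when they agree in direction
and removed outright when their fold changes point in opposite directions.
All comparisons are then concatenated into a long table keyed by
(canonical_id, comparison_id).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .types import LONG_COLUMNS, ComparisonTable

logger = logging.getLogger(__name__)

#: Sentinel returned when a duplicate set is sign-conflicted.
REMOVED = "REMOVED"


def collapse_duplicates(records: pd.DataFrame) -> pd.DataFrame | str:
    """Collapse records sharing one canonical id within one comparison.

    Returns a one-row DataFrame with the arithmetic-mean log2FC and the
    minimum of each p-value column, or the :data:`REMOVED` sentinel when the
    fold changes strictly conflict in sign (some > 0 and some < 0; zeros are
    sign-neutral).  The result is independent of input row order.
    """
    if len(records) == 0:
        raise ValueError("collapse_duplicates requires at least one record")
    if len(records) == 1:
        return records.copy()
    lfc = records["log2fc"].to_numpy()
    if (lfc > 0).any() and (lfc < 0).any():
        return REMOVED
    out = records.iloc[[0]].copy()
    out["log2fc"] = lfc.mean()
    for col in ("pvalue", "adj_pvalue", "chosen_p"):
        if col in records.columns:
            out[col] = records[col].min()
    return out


def collapse_table(table: ComparisonTable) -> ComparisonTable:
    """Apply the average-or-remove rule to every duplicated id in a table."""
    records = table.records
    key = table.id_column
    if not records[key].duplicated().any():
        return table
    kept: list[pd.DataFrame] = []
    n_removed = 0
    for _, group in records.groupby(key, sort=False):
        merged = collapse_duplicates(group)
        if isinstance(merged, str):  # REMOVED
            n_removed += 1
        else:
            kept.append(merged)
    if n_removed:
        logger.info(
            "%s: removed %d sign-conflicted duplicate molecule(s)",
            table.comparison_id,
            n_removed,
        )
    out = (
        pd.concat(kept, ignore_index=True)
        if kept
        else records.iloc[0:0].copy()
    )
    return replace(table, records=out)


def build_long_table(tables: list[ComparisonTable]) -> pd.DataFrame:
    """Concatenate collapsed, harmonized comparisons into one long table.

    One row per (canonical_id, comparison_id); group labels are propagated and
    the uniqueness invariant is asserted.  A gene absent from a comparison
    simply has no row — absence is not a zero.
    """
    frames = []
    for table in tables:
        key = table.id_column
        records = table.records
        if records[key].duplicated().any():
            raise ValueError(
                f"{table.comparison_id}: duplicate {key} after collapse; "
                "run collapse_table first"
            )
        frame = pd.DataFrame(
            {
                "canonical_id": records[key].to_numpy(),
                "comparison_id": table.comparison_id,
                "group_label": table.group_label,
                "log2fc": records["log2fc"].to_numpy(),
                "pvalue": records["pvalue"].to_numpy(),
                "passed": records["passed"].to_numpy()
                if "passed" in records.columns
                else np.ones(len(records), dtype=bool),
            }
        )
        frames.append(frame)
    long = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(LONG_COLUMNS))
    )
    dup = long.duplicated(subset=["canonical_id", "comparison_id"])
    if dup.any():
        raise ValueError("duplicate (canonical_id, comparison_id) across tables")
    return long[list(LONG_COLUMNS)]
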