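"""Shared domain containers for the cross-study consensus pipeline.

A *dataset comparison* is one case-vs-control contrast (e.g. healthy vs
relapsing-remitting MS within one expression study).  Comparisons are
assigned to phenotype groups; the reference groups are ``non_treated``
(healthy vs disease) and ``treated`` (disease vs treated disease), and the
comparator groups describe other disease patterns (viral infection,
inflammation, autoimmunity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Recognised phenotype group labels.
GROUP_LABELS = (
    "general",
    "non_treated",
    "treated",
    "virus",
    "inflammation",
    "autoimmune",
)

#: Number of dataset comparisons per group in the default study geometry.
DEFAULT_GROUP_SIZES = {
    "non_treated": 13,
    "treated": 22,
    "virus": 2,
    "inflammation": 3,
    "autoimmune": 14,
}

#: Columns a differential-expression record table must carry.
DE_COLUMNS = ("source_id", "log2fc", "pvalue")


class FormatError(ValueError):
    """A tabular input does not conform to the expected layout."""


class ConfigError(ValueError):
    """A configuration value is inconsistent or out of range."""


def validate_group_label(label: str) -> str:
    if label not in GROUP_LABELS:
        raise ConfigError(
            f"unknown group label {label!r}; expected one of {GROUP_LABELS}"
        )
    return label


@dataclass
class ComparisonTable:
    """Per-molecule differential-expression records of one dataset comparison.

    ``records`` is a DataFrame with at least ``source_id``, ``log2fc`` and
    ``pvalue`` columns; ``canonical_id``, ``adj_pvalue``, ``chosen_p`` and
    ``passed`` are added by the harmonization / testing stages.  ``adj_pvalue``
    may contain missing values so that precomputed GEO2R-style exports can be
    ingested as-is.
    """

    comparison_id: str
    group_label: str
    n_case: int
    n_control: int
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_group_label(self.group_label)
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("n_case and n_control must be positive")
        missing = [c for c in DE_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"records missing mandatory columns: {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def id_column(self) -> str:
        """Name of the identifier column to key on (canonical if present)."""
        return "canonical_id" if "canonical_id" in self.records.columns else "source_id"


@dataclass
class HarmonizeReport:
    """Bookkeeping emitted by identifier harmonization."""

    n_total: int
    n_mapped: int
    n_unmapped: int
    policy: str


#: Column layout of the merged long table (one row per molecule × comparison).
LONG_COLUMNS = (
    "canonical_id",
    "comparison_id",
    "group_label",
    "log2fc",
    "pvalue",
    "passed",
)

#: Column layout of a consensus (vote-counting) score table.
CONSENSUS_COLUMNS = (
    "canonical_id",
    "group_label",
    "direction",
    "occurrences",
    "n_group",
    "frequency",
    "mean_log2fc",
    "conflict_flag",
    "opposite_count",
)
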