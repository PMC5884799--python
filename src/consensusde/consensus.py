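"""Direction-aware vote-counting consensus scoring.

Rather than pooling effect sizes, molecules are ranked by the fraction of a
group's dataset comparisons in which they are significantly regulated in a
consistent direction.  The frequency denominator is the full group size (13
non-treated / 22 treated comparisons in the default geometry), not the number
of comparisons that measured the molecule: a gene significant and
up-regulated in 4 of 13 non-treated comparisons scores 4/13 ≈ 31%.

Tiered frequency thresholds (strict >) produce nested panels; the default
tiers per group follow the published threshold table: general 20/17/14/11%,
non-treated 23/15%, treated 23/18/14%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .types import CONSENSUS_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_TIERS = {
    "general": (0.20, 0.17, 0.14, 0.11),
    "non_treated": (0.23, 0.15),
    "treated": (0.23, 0.18, 0.14),
}


@dataclass(frozen=True)
class TierConfig:
    """Strictly decreasing frequency thresholds (fractions in (0, 1])."""

    thresholds: tuple[float, ...] = (0.20,)

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t:
            raise ValueError("at least one tier threshold required")
        if any(not 0 < x <= 1 for x in t):
            raise ValueError("tier thresholds must lie in (0, 1]")
        if any(nxt >= prev for nxt, prev in zip(t[1:], t[:-1])):
            raise ValueError("tier thresholds must be strictly decreasing")


def score_group(
    long: pd.DataFrame, group_label: str, n_group: int | None = None
) -> pd.DataFrame:
    """Consensus-score every molecule of one phenotype group.

    ``long`` is the merged long table; only rows with ``passed`` True count as
    significant occurrences.  Per molecule the majority direction is taken by
    occurrence count (ties broken toward the side with larger mean |log2FC|,
    and logged); ``occurrences`` counts majority-direction comparisons only,
    while opposite-direction significant comparisons set ``conflict_flag`` and
    are tallied in ``opposite_count``.  Molecules never significant in the
    group are not emitted.
    """
    if group_label == "general":
        # the general group is the union of the two MS reference groups
        mask = long["group_label"].isin(("non_treated", "treated"))
    else:
        mask = long["group_label"] == group_label
    sub = long.loc[mask & long["passed"]]
    if n_group is None:
        n_group = long.loc[mask, "comparison_id"].nunique()
    if n_group < 1:
        raise ValueError("n_group must be at least 1")

    rows = []
    for gene, grp in sub.groupby("canonical_id", sort=True):
        lfc = grp["log2fc"].to_numpy()
        up, down = lfc > 0, lfc < 0
        n_up, n_down = int(up.sum()), int(down.sum())
        if n_up == n_down == 0:
            continue  # only zero fold changes: no direction to vote on
        if n_up > n_down:
            direction = "up"
        elif n_down > n_up:
            direction = "down"
        else:
            direction = "up" if lfc[up].mean() >= -lfc[down].mean() else "down"
            logger.info(
                "%s/%s: direction tie (%d vs %d) broken toward %s by |log2FC|",
                group_label,
                gene,
                n_up,
                n_down,
                direction,
            )
        major = up if direction == "up" else down
        occurrences = int(major.sum())
        opposite = (n_up + n_down) - occurrences
        rows.append(
            {
                "canonical_id": gene,
                "group_label": group_label,
                "direction": direction,
                "occurrences": occurrences,
                "n_group": n_group,
                "frequency": occurrences / n_group,
                "mean_log2fc": float(lfc[major].mean()),
                "conflict_flag": opposite > 0,
                "opposite_count": opposite,
            }
        )
    return pd.DataFrame(rows, columns=list(CONSENSUS_COLUMNS))


def apply_tiers(
    records: pd.DataFrame, tiers: TierConfig
) -> dict[float, pd.DataFrame]:
    """Panels at each frequency tier (strict >), highest threshold first.

    Panels are nested (higher tier ⊆ lower tier) and sorted by frequency then
    |mean_log2fc|, both descending.
    """
    panels: dict[float, pd.DataFrame] = {}
    for threshold in tiers.thresholds:
        panel = records.loc[records["frequency"] > threshold].copy()
        panel = panel.assign(_abs=panel["mean_log2fc"].abs())
        panel = panel.sort_values(
            ["frequency", "_abs", "canonical_id"],
            ascending=[False, False, True],
            kind="mergesort",
        ).drop(columns="_abs")
        panels[threshold] = panel.reset_index(drop=True)
    return panels


def format_frequency(frequency: float) -> str:
    """Human-readable frequency, rounded to the nearest integer percent."""
    return f"{round(frequency * 100):.0f}%"
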