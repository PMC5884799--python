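"""Packaged transcriptions of the published consensus panels.

Two 16-gene panels are shipped as TSV inside the package: the most
consistently deregulated molecules across the untreated-MS comparisons
(``table1_non_treated``, scored over 13 comparisons) and across the treated-MS
comparisons (``table2_treated``, scored over 22 comparisons).  Each row also
carries the gene's status in three comparator phenotype groups — EBV-infected
blood (``virus``, 2 comparisons), inflammatory conditions (``inflammation``,
3) and autoimmune diseases (``autoimmune``, 14) — as printed: regulation
direction, signed log2 fold change, and the number of significant occurrences
in brackets.  ``opposite_n`` counts datasets in which the molecule was also
significant in the opposite direction (the footnote asterisks).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .types import CONSENSUS_COLUMNS, DEFAULT_GROUP_SIZES

PANEL_NAMES = ("table1_non_treated", "table2_treated")

_PANEL_GROUP = {
    "table1_non_treated": "non_treated",
    "table2_treated": "treated",
}

COMPARATOR_GROUPS = ("virus", "inflammation", "autoimmune")


@dataclass
class FixturePanel:
    """One packaged panel plus its comparator-group columns."""

    panel_name: str
    group_label: str
    n_group: int
    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)

    def consensus_records(self) -> pd.DataFrame:
        """The panel itself as a consensus score table."""
        r = self.rows
        return pd.DataFrame(
            {
                "canonical_id": r["gene"],
                "group_label": self.group_label,
                "direction": r["regulation"],
                "occurrences": r["occurrences"].astype(int),
                "n_group": self.n_group,
                "frequency": r["occurrences"].astype(int) / self.n_group,
                "mean_log2fc": r["log2fc"].astype(float),
                "conflict_flag": r["opposite_n"].astype(int) > 0,
                "opposite_count": r["opposite_n"].astype(int),
            },
            columns=list(CONSENSUS_COLUMNS),
        )

    def comparator_records(self, comparator: str) -> pd.DataFrame:
        """One comparator group's columns as a consensus score table.

        Genes printed as non-significant in that group are omitted (a
        consensus table only lists molecules significant somewhere).
        """
        if comparator not in COMPARATOR_GROUPS:
            raise KeyError(f"unknown comparator group {comparator!r}")
        r = self.rows
        sig = r[f"{comparator}_status"] != "ns"
        r = r.loc[sig]
        n_group = DEFAULT_GROUP_SIZES[comparator]
        occ = r[f"{comparator}_occurrences"].astype(float).astype(int)
        return pd.DataFrame(
            {
                "canonical_id": r["gene"],
                "group_label": comparator,
                "direction": r[f"{comparator}_status"],
                "occurrences": occ,
                "n_group": n_group,
                "frequency": occ / n_group,
                "mean_log2fc": r[f"{comparator}_log2fc"].astype(float),
                "conflict_flag": r[f"{comparator}_opposite_n"].astype(int) > 0,
                "opposite_count": r[f"{comparator}_opposite_n"].astype(int),
            },
            columns=list(CONSENSUS_COLUMNS),
        ).reset_index(drop=True)


def load_fixture(panel_name: str) -> FixturePanel:
    """Load one packaged panel transcription.

    Raises ``KeyError`` for an unknown panel name.
    """
    if panel_name not in PANEL_NAMES:
        raise KeyError(
            f"unknown fixture panel {panel_name!r}; expected one of {PANEL_NAMES}"
        )
    ref = resources.files("consensusde.data").joinpath(f"{panel_name}.tsv")
    with resources.as_file(ref) as path:
        rows = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    group = _PANEL_GROUP[panel_name]
    panel = FixturePanel(
        panel_name=panel_name,
        group_label=group,
        n_group=DEFAULT_GROUP_SIZES[group],
        rows=rows,
    )
    _validate(panel)
    return panel


def _validate(panel: FixturePanel) -> None:
    r = panel.rows
    if len(r) != 16:
        raise ValueError(f"{panel.panel_name}: expected 16 rows, found {len(r)}")
    if (r["occurrences"] < 1).any():
        raise ValueError(f"{panel.panel_name}: occurrence count below 1")
    sign = np.sign(r["log2fc"])
    expected = r["regulation"].map({"up": 1.0, "down": -1.0})
    if (sign != expected).any():
        raise ValueError(f"{panel.panel_name}: log2fc sign disagrees with regulation")
    for comp in COMPARATOR_GROUPS:
        sig = r[f"{comp}_status"] != "ns"
        occ = r.loc[sig, f"{comp}_occurrences"]
        if occ.isna().any() or (occ.astype(float) < 1).any():
            raise ValueError(
                f"{panel.panel_name}: {comp} occurrences missing or below 1"
            )
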