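"""Cross-phenotype concordance of a consensus panel.

Each gene of a reference panel (e.g. the 16-gene untreated-MS panel) is
looked up in a comparator group's consensus table and classified:

* ``ns`` — not significant in the comparator group;
* ``concordant`` — significant with the same log2FC sign;
* ``discordant`` — significant with the opposite sign;
* ``ambiguous`` — significant, but the comparator's direction vote is an
  exact tie (equally many up- and down-regulated occurrences), so no
  direction comparison is meaningful.

"Overlap" counts every non-``ns`` status regardless of direction; the
concordant subset is what the analysis calls a similar fold-change trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONCORDANCE_COLUMNS = (
    "canonical_id",
    "reference_direction",
    "comparator_group",
    "comparator_status",
    "comparator_log2fc",
    "comparator_occurrences",
)


@dataclass(frozen=True)
class OverlapSummary:
    comparator_group: str
    n_panel: int
    n_overlap: int
    n_concordant: int
    n_discordant: int
    n_ambiguous: int
    n_ns: int
    overlap_fraction: float


def classify_panel(
    panel: pd.DataFrame, comparator: pd.DataFrame
) -> pd.DataFrame:
    """Classify every panel gene against one comparator consensus table.

    Both inputs are consensus score tables in the same canonical namespace.
    Comparator genes outside the panel are ignored.  Raises on duplicate
    panel genes.
    """
    if panel["canonical_id"].duplicated().any():
        raise ValueError("duplicate gene in reference panel")
    comp = comparator.set_index("canonical_id")
    comparator_group = (
        comparator["group_label"].iloc[0] if len(comparator) else "comparator"
    )
    rows = []
    for rec in panel.itertuples(index=False):
        status, lfc, occ = "ns", np.nan, 0
        if rec.canonical_id in comp.index:
            c = comp.loc[rec.canonical_id]
            lfc = float(c["mean_log2fc"])
            occ = int(c["occurrences"])
            tie = bool(c.get("opposite_count", 0) == c["occurrences"])
            if tie:
                status = "ambiguous"
            elif np.sign(lfc) == np.sign(rec.mean_log2fc):
                status = "concordant"
            else:
                status = "discordant"
        rows.append(
            {
                "canonical_id": rec.canonical_id,
                "reference_direction": rec.direction,
                "comparator_group": comparator_group,
                "comparator_status": status,
                "comparator_log2fc": lfc,
                "comparator_occurrences": occ,
            }
        )
    return pd.DataFrame(rows, columns=list(CONCORDANCE_COLUMNS))


def summarize_overlap(records: pd.DataFrame) -> OverlapSummary:
    """Overlap counts for one (panel, comparator) classification."""
    status = records["comparator_status"]
    n_panel = len(records)
    n_conc = int((status == "concordant").sum())
    n_disc = int((status == "discordant").sum())
    n_ambi = int((status == "ambiguous").sum())
    n_ns = int((status == "ns").sum())
    n_overlap = n_conc + n_disc + n_ambi
    return OverlapSummary(
        comparator_group=records["comparator_group"].iloc[0] if n_panel else "",
        n_panel=n_panel,
        n_overlap=n_overlap,
        n_concordant=n_conc,
        n_discordant=n_disc,
        n_ambiguous=n_ambi,
        n_ns=n_ns,
        overlap_fraction=n_overlap / n_panel if n_panel else 0.0,
    )


def summary_frame(summaries: list[OverlapSummary]) -> pd.DataFrame:
    """Stack summaries into one table mirroring the printed panel layout."""
    return pd.DataFrame([s.__dict__ for s in summaries])
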