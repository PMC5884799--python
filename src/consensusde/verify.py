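"""Recompute the published panel summaries from the packaged fixtures.

Every quantity is computed by running the package's own consensus /
concordance operations on the fixture transcriptions and compared against
the counts stated in the publication's text.
"""

from __future__ import annotations

from dataclasses import dataclass

from .concordance import classify_panel, summarize_overlap
from .consensus import TierConfig, apply_tiers
from .fixtures import load_fixture


@dataclass(frozen=True)
class Check:
    name: str
    computed: float
    expected: float
    cmp: str = "eq"  # eq | ge

    @property
    def ok(self) -> bool:
        if self.cmp == "ge":
            return self.computed >= self.expected
        return self.computed == self.expected


def fixture_summaries() -> dict[str, float]:
    """All fixture-derived summary quantities, computed from scratch."""
    t1 = load_fixture("table1_non_treated")
    t2 = load_fixture("table2_treated")
    panel1, panel2 = t1.consensus_records(), t2.consensus_records()

    out: dict[str, float] = {}
    ank = panel1.set_index("canonical_id").loc["ANKRD10"]
    out["ankrd10_frequency_pct"] = round(ank["frequency"] * 100)

    top2 = panel2.sort_values("occurrences", ascending=False).head(2)
    out["treated_top2_min_frequency"] = float(top2["frequency"].min())

    for panel, fixture, tag in ((panel1, t1, "non_treated"), (panel2, t2, "treated")):
        for comparator in ("virus", "inflammation", "autoimmune"):
            summary = summarize_overlap(
                classify_panel(panel, fixture.comparator_records(comparator))
            )
            prefix = f"{tag}_vs_{comparator}"
            out[f"{prefix}_overlap"] = summary.n_overlap
            out[f"{prefix}_concordant"] = summary.n_concordant
            out[f"{prefix}_discordant"] = summary.n_discordant
            out[f"{prefix}_overlap_fraction"] = summary.overlap_fraction

    tier20 = apply_tiers(panel1, TierConfig((0.20,)))[0.20]
    out["non_treated_panel_size_20pct"] = len(tier20)
    return out


#: Published counts the fixtures must reproduce.
EXPECTED = {
    "ankrd10_frequency_pct": 31,
    "treated_top2_min_frequency_ge": 0.5,
    "non_treated_vs_autoimmune_overlap": 6,
    "non_treated_vs_autoimmune_discordant": 3,
    "non_treated_vs_virus_overlap": 3,
    "non_treated_vs_inflammation_concordant": 2,
    "treated_vs_virus_concordant": 4,
    "treated_vs_inflammation_overlap": 3,
    "treated_vs_autoimmune_overlap_fraction": 1.0,
    "non_treated_panel_size_20pct": 16,
}


def verify_fixtures() -> list[Check]:
    """Pass/fail checks of the packaged panels against the published counts."""
    got = fixture_summaries()
    checks = []
    for name, expected in EXPECTED.items():
        if name.endswith("_ge"):
            value = got[name[: -len("_ge")]]
            checks.append(Check(name, computed=value, expected=expected, cmp="ge"))
        else:
            checks.append(Check(name, computed=got[name], expected=expected))
    return checks
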