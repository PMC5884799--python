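#!/usr/bin/env python
"""Vote-counting consensus scores and tiered panels per phenotype group.

Scores every molecule by its direction-consistent significance frequency
within each group (denominator = group size) and applies the default tier
thresholds (general 20/17/14/11%, non-treated 23/15%, treated 23/18/14%).
Panel membership is then compared with the planted truth from step 02.
"""

from pathlib import Path

import pandas as pd

from consensusde.consensus import DEFAULT_TIERS, TierConfig, apply_tiers, score_group

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

long = pd.read_csv(SCRATCH / "long_table.tsv", sep="\t")
truth = pd.read_csv(SCRATCH / "compendium" / "truth.tsv", sep="\t")

panel_rows = []
for group in ("general", "non_treated", "treated", "virus", "inflammation", "autoimmune"):
    scored = score_group(long, group)
    scored.to_csv(ROOT / f"consensus_{group}.tsv", sep="\t", index=False)
    tiers = TierConfig(DEFAULT_TIERS.get(group, (0.20,)))
    panels = apply_tiers(scored, tiers)
    sizes = {f">{t:.0%}": len(p) for t, p in panels.items()}
    print(f"{group}: {len(scored)} molecules scored; panel sizes {sizes}")
    top = panels[tiers.thresholds[0]]
    planted_here = set(truth.loc[truth["group_label"] == group, "gene"].unique())
    hits = set(top["canonical_id"]) & planted_here if planted_here else set()
    panel_rows.append(
        {
            "group": group,
            "n_scored": len(scored),
            "top_tier": tiers.thresholds[0],
            "top_panel_size": len(top),
            "planted_recovered": len(hits),
        }
    )

pd.DataFrame(panel_rows).to_csv(ROOT / "panel_summary.tsv", sep="\t", index=False)
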