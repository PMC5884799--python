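#!/usr/bin/env python
"""Classify the MS consensus panels against the comparator disease groups.

For each reference panel (non-treated, treated; top tier from step 04) and
each comparator group (virus, inflammation, autoimmune), every panel gene is
classified as ns / concordant / discordant / ambiguous by fold-change sign,
and the overlap summary is tabulated.  With the planted design, the AUTO*
genes should overlap concordantly with the autoimmune comparator while the
MSONLY* genes should not overlap at all.
"""

from pathlib import Path

import pandas as pd

from consensusde.concordance import classify_panel, summarize_overlap
from consensusde.consensus import DEFAULT_TIERS, TierConfig, apply_tiers, score_group

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
long = pd.read_csv(SCRATCH / "long_table.tsv", sep="\t")

panels = {}
for group in ("non_treated", "treated"):
    scored = score_group(long, group)
    tiers = TierConfig(DEFAULT_TIERS[group])
    panels[group] = apply_tiers(scored, tiers)[tiers.thresholds[0]]

summaries = []
for group, panel in panels.items():
    for comparator in ("virus", "inflammation", "autoimmune"):
        comp_scores = score_group(long, comparator)
        classified = classify_panel(panel, comp_scores)
        classified.to_csv(
            ROOT / f"concordance_{group}_vs_{comparator}.tsv", sep="\t", index=False
        )
        s = summarize_overlap(classified)
        summaries.append({"reference": group, **s.__dict__})
        print(
            f"{group} panel ({s.n_panel} genes) vs {comparator}: "
            f"overlap {s.n_overlap} (concordant {s.n_concordant}, "
            f"discordant {s.n_discordant})"
        )

pd.DataFrame(summaries).to_csv(ROOT / "overlap_summary.tsv", sep="\t", index=False)
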