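#!/usr/bin/env python
"""Simulate a study-shaped synthetic compendium with planted consensus genes.

The geometry mirrors the study conditions (13 non-treated, 22 treated, 2
virus, 3 inflammation, 14 autoimmune dataset comparisons).  Eight genes are
planted: four regulated in both MS groups and the autoimmune group
(penetrance 0.5) emulating a generic autoimmune signature, and four unique to
the untreated-MS group (penetrance 0.3) emulating a disease-specific panel.
Per-comparison DE tables, metadata and the realized ground truth are written
for the downstream steps.
"""

from pathlib import Path

import pandas as pd

from consensusde.io import write_comparison_table
from consensusde.simulate import PlantedGene, SyntheticConfig, generate_compendium

OUT = Path(__file__).resolve().parent.parent / "scratch" / "compendium"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 20240117

planted = tuple(
    PlantedGene(
        gene=f"AUTO{i}",
        target_groups=frozenset({"non_treated", "treated", "autoimmune"}),
        effect_log2fc=2.5 if i % 2 == 0 else -2.0,
        penetrance=0.5,
    )
    for i in range(4)
) + tuple(
    PlantedGene(
        gene=f"MSONLY{i}",
        target_groups=frozenset({"non_treated"}),
        effect_log2fc=2.0 if i % 2 == 0 else -2.5,
        penetrance=0.3,
    )
    for i in range(4)
)

config = SyntheticConfig(n_genes=500, planted=planted, seed=SEED)
tables, truth = generate_compendium(config)

meta = []
for table in tables:
    write_comparison_table(table, OUT / f"{table.comparison_id}.tsv")
    meta.append(
        {
            "comparison_id": table.comparison_id,
            "group_label": table.group_label,
            "n_case": table.n_case,
            "n_control": table.n_control,
        }
    )
pd.DataFrame(meta).to_csv(OUT / "metadata.tsv", sep="\t", index=False)
truth.realized_frame().to_csv(OUT / "truth.tsv", sep="\t", index=False)

n_passed = sum(int(t.records["passed"].sum()) for t in tables)
print(f"wrote {len(tables)} comparisons ({config.n_genes} genes, seed {SEED})")
print(f"planted genes: {[p.gene for p in planted]}")
print(f"significant records across all comparisons: {n_passed}")
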