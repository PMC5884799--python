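#!/usr/bin/env python
"""Merge the simulated comparisons and stratify them by PCA.

Reads the per-comparison DE tables from step 02, collapses duplicates,
builds the long table, runs PCA over the MS comparisons' fold-change matrix
and flags robust outliers (|score − median| > 3 · 1.4826 · MAD on the first
two components).
"""

from pathlib import Path

import pandas as pd

from consensusde.differential import (
    ThresholdConfig,
    choose_pvalue_column,
    mark_significant,
)
from consensusde.io import read_comparison_table
from consensusde.merge import build_long_table, collapse_table
from consensusde.stratify import build_feature_matrix, flag_outliers, run_pca

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
IN = SCRATCH / "compendium"

meta = pd.read_csv(IN / "metadata.tsv", sep="\t")
cfg = ThresholdConfig()
tables = []
for row in meta.itertuples(index=False):
    table = collapse_table(
        read_comparison_table(
            IN / f"{row.comparison_id}.tsv",
            comparison_id=row.comparison_id,
            group_label=row.group_label,
            n_case=int(row.n_case),
            n_control=int(row.n_control),
        )
    )
    # re-derive the chosen p-value column (poor-dataset fallback) and the
    # significance flag, which are not part of the interchange format
    chosen, _ = choose_pvalue_column(
        table.records["pvalue"], table.records["adj_pvalue"]
    )
    table.records["chosen_p"] = chosen
    table.records = mark_significant(table.records, cfg)
    tables.append(table)
long = build_long_table(tables)
long.to_csv(SCRATCH / "long_table.tsv", sep="\t", index=False)

ms = long.loc[long["group_label"].isin(("non_treated", "treated")) & long["passed"]]
matrix = build_feature_matrix(ms)
pca = run_pca(matrix)
pca.scores.to_csv(ROOT / "pca_scores.tsv", sep="\t")
removed = flag_outliers(pca, k=3.0, n_components=2)
(ROOT / "pca_removed.txt").write_text("\n".join(removed) + "\n")

evr = pca.explained_variance_ratio
print(f"long table: {len(long)} records, {int(long['passed'].sum())} significant")
print(f"PCA over {matrix.shape[0]} MS comparisons × {matrix.shape[1]} genes")
print(f"PC1/PC2 explained variance: {evr[0]:.1%} / {evr[1]:.1%}")
print(f"flagged outliers: {removed or 'none'}")
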