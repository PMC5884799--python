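"""End-to-end pipeline: simulate/load → test → merge → stratify → score →
compare → enrich, with a reproducible run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import concordance as conc
from . import consensus, enrichment, merge, stratify
from .differential import ThresholdConfig
from .simulate import SyntheticConfig, generate_compendium
from .types import ComparisonTable, ConfigError

logger = logging.getLogger(__name__)

COMPARATOR_GROUPS = ("virus", "inflammation", "autoimmune")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or file-based input)."""

    out_dir: Path
    synthetic: SyntheticConfig | None = None
    tables: list[ComparisonTable] | None = None
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    tiers: dict[str, consensus.TierConfig] = field(
        default_factory=lambda: {
            g: consensus.TierConfig(t) for g, t in consensus.DEFAULT_TIERS.items()
        }
    )
    outlier_k: float = 3.0
    outlier_components: int = 2
    manual_remove: tuple[str, ...] = ()
    gmt_path: Path | None = None
    n_perm: int = 1000

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.tables is None):
            raise ConfigError("exactly one of synthetic config or input tables required")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write per-stage TSVs and return the manifest.

    Re-running with the same configuration and seed reproduces byte-identical
    outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}

    # --- input / differential stage
    if config.synthetic is not None:
        tables, truth = generate_compendium(config.synthetic, config.threshold)
        manifest["seed"] = config.synthetic.seed
        manifest["synthetic"] = {
            "n_genes": config.synthetic.n_genes,
            "groups": dict(config.synthetic.groups),
            "noise_sd": config.synthetic.noise_sd,
            "dropout_rate": config.synthetic.dropout_rate,
            "sign_flip_rate": config.synthetic.sign_flip_rate,
            "n_planted": len(config.synthetic.planted),
        }
        truth.realized_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        tables = config.tables
    manifest["stages"]["comparisons"] = {
        "n_tables": len(tables),
        "n_records": int(sum(len(t) for t in tables)),
    }

    # --- merge stage
    tables = [merge.collapse_table(t) for t in tables]
    long = merge.build_long_table(tables)
    long.to_csv(out / "long_table.tsv", sep="\t", index=False)
    manifest["stages"]["merge"] = {
        "n_long_records": len(long),
        "n_passed": int(long["passed"].sum()),
    }

    # --- stratification stage (PCA over the MS reference comparisons)
    ms_long = long.loc[
        long["group_label"].isin(("non_treated", "treated")) & long["passed"]
    ]
    removed: list[str] = list(config.manual_remove)
    if ms_long["comparison_id"].nunique() >= 2 and len(ms_long):
        matrix = stratify.build_feature_matrix(ms_long)
        pca = stratify.run_pca(matrix)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        removed = stratify.flag_outliers(
            pca,
            k=config.outlier_k,
            n_components=config.outlier_components,
            manual=list(config.manual_remove),
        )
        manifest["stages"]["stratify"] = {
            "explained_variance_ratio": [
                round(float(v), 6) for v in pca.explained_variance_ratio[:5]
            ],
            "removed": removed,
        }
    ms_ids = {
        t.comparison_id: t.group_label
        for t in tables
        if t.group_label in ("non_treated", "treated")
    }
    plan = stratify.assign_groups(
        ms_ids, [c for c in ms_ids if c not in removed]
    )
    long = long.loc[~long["comparison_id"].isin(removed)]

    # --- consensus stage
    group_sizes = {
        "general": len(plan.retained),
        "non_treated": sum(1 for g in plan.assignment.values() if g == "non_treated"),
        "treated": sum(1 for g in plan.assignment.values() if g == "treated"),
    }
    scores: dict[str, pd.DataFrame] = {}
    panels: dict[str, pd.DataFrame] = {}
    for group in ("general", "non_treated", "treated"):
        records = consensus.score_group(long, group, n_group=group_sizes[group])
        scores[group] = records
        records.to_csv(out / f"consensus_{group}.tsv", sep="\t", index=False)
        tiers = config.tiers.get(group, consensus.TierConfig((0.20,)))
        tiered = consensus.apply_tiers(records, tiers)
        top = tiers.thresholds[0]
        panels[group] = tiered[top]
        manifest["stages"].setdefault("consensus", {})[group] = {
            "n_scored": len(records),
            "panel_sizes": {f"{t:.2f}": len(p) for t, p in tiered.items()},
        }
    for comparator in COMPARATOR_GROUPS:
        if (long["group_label"] == comparator).any():
            scores[comparator] = consensus.score_group(long, comparator)
            scores[comparator].to_csv(
                out / f"consensus_{comparator}.tsv", sep="\t", index=False
            )

    # --- concordance stage
    summaries = []
    for group in ("non_treated", "treated"):
        for comparator in COMPARATOR_GROUPS:
            if comparator not in scores or panels[group].empty:
                continue
            classified = conc.classify_panel(panels[group], scores[comparator])
            classified.to_csv(
                out / f"concordance_{group}_vs_{comparator}.tsv",
                sep="\t",
                index=False,
            )
            s = conc.summarize_overlap(classified)
            summaries.append(
                {"reference_group": group, **s.__dict__}
            )
    if summaries:
        pd.DataFrame(summaries).to_csv(out / "overlap_summary.tsv", sep="\t", index=False)
        manifest["stages"]["concordance"] = {"n_pairs": len(summaries)}

    # --- enrichment stage (optional: needs gene sets)
    if config.gmt_path is not None:
        universe = set(long["canonical_id"].unique())
        collection = enrichment.read_gene_sets(config.gmt_path, universe=universe)
        panel_genes = set(panels["general"]["canonical_id"])
        result = enrichment.hypergeometric_ora(panel_genes, collection)
        seed = manifest.get("seed", 0)
        p_perm = []
        for row in result.itertuples(index=False):
            p_perm.append(
                enrichment.permutation_null(
                    row.n,
                    collection.sets[row.term],
                    collection.universe,
                    n_perm=config.n_perm,
                    seed=seed,
                    observed_k=row.k,
                )
            )
        result["p_perm"] = p_perm
        result.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"] = {
            "n_terms": len(result),
            "n_significant": int((result["p_adj"] < 0.05).sum()),
        }

    manifest["threshold"] = {
        "p_cut": config.threshold.p_cut,
        "lfc_cut": config.threshold.lfc_cut,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
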