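"""Synthetic multi-study compendia with planted consistent regulation.

Expression is simulated directly on the log2 scale: control samples are
Gaussian around a per-gene baseline, case samples add a planted log2FC shift
when the gene's effect is realized in that comparison.  This makes the
log2 fold change exactly a difference of group means, matching the
differential stage's contract without modelling array preprocessing.

Cross-study heterogeneity is emulated by three mechanisms:

* ``penetrance`` — per-comparison probability that a planted effect is
  present at all (the generator's analogue of cross-study consistency);
* ``sign_flip_rate`` — probability that a realized effect enters with the
  opposite sign (annotation/batch artifacts);
* ``dropout_rate`` — probability that a gene is absent from a comparison's
  platform entirely.

The default geometry mirrors the study conditions: 13 non-treated, 22
treated, 2 virus, 3 inflammation and 14 autoimmune dataset comparisons.  A
single root seed drives everything through per-comparison substreams, so
compendia are bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .differential import ThresholdConfig, mark_significant, test_comparison
from .types import ComparisonTable, ConfigError, validate_group_label


@dataclass(frozen=True)
class PlantedGene:
    """Ground-truth consistently regulated gene."""

    gene: str
    target_groups: frozenset[str]
    effect_log2fc: float
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        for g in self.target_groups:
            validate_group_label(g)
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigError("penetrance must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped compendium configuration (log2-scale expression)."""

    n_genes: int = 2000
    groups: tuple[tuple[str, int], ...] = (
        ("non_treated", 13),
        ("treated", 22),
        ("virus", 2),
        ("inflammation", 3),
        ("autoimmune", 14),
    )
    n_case: int = 10
    n_control: int = 10
    planted: tuple[PlantedGene, ...] = ()
    baseline_mean: float = 8.0
    noise_sd: float = 1.0
    dropout_rate: float = 0.1
    sign_flip_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        for label, n in self.groups:
            validate_group_label(label)
            if n < 1:
                raise ConfigError(f"group {label!r} needs at least 1 comparison")
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("n_case and n_control must be at least 2 (t-test)")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be positive")
        for name in ("dropout_rate", "sign_flip_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        planted_names = [p.gene for p in self.planted]
        if len(planted_names) != len(set(planted_names)):
            raise ConfigError("duplicate planted gene names")

    @property
    def gene_ids(self) -> list[str]:
        planted = [p.gene for p in self.planted]
        n_background = self.n_genes - len(planted)
        if n_background < 0:
            raise ConfigError("more planted genes than n_genes")
        return planted + [f"G{i:05d}" for i in range(n_background)]


@dataclass
class TruthSlice:
    """Realized planted effects in one comparison."""

    comparison_id: str
    group_label: str
    realized: dict[str, float] = field(default_factory=dict)  # gene -> signed effect
    dropped: frozenset[str] = frozenset()


@dataclass
class SyntheticTruth:
    """Ground truth for a whole compendium."""

    config: SyntheticConfig
    slices: list[TruthSlice]

    def realized_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison_id": s.comparison_id,
                "group_label": s.group_label,
                "gene": gene,
                "effect_log2fc": effect,
            }
            for s in self.slices
            for gene, effect in sorted(s.realized.items())
        ]
        return pd.DataFrame(
            rows, columns=["comparison_id", "group_label", "gene", "effect_log2fc"]
        )

    def planted_for(self, group_label: str) -> set[str]:
        return {
            p.gene for p in self.config.planted if group_label in p.target_groups
        }


def _substream(seed: int, group_label: str, index: int) -> np.random.Generator:
    # deterministic per-comparison substream from the root seed (crc32 is
    # stable across processes, unlike the builtin salted hash)
    key = zlib.crc32(f"{group_label}:{index}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def generate_comparison(
    config: SyntheticConfig, group_label: str, comparison_index: int
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSlice]:
    """Simulate one comparison's case/control matrices (genes × samples).

    Planted genes targeting this group carry their mean shift with
    probability ``penetrance`` (sign flipped with ``sign_flip_rate``); every
    value has Gaussian noise with sd ``noise_sd``; genes are dropped from the
    platform with probability ``dropout_rate``.  Fully reproducible from the
    root seed.
    """
    validate_group_label(group_label)
    rng = _substream(config.seed, group_label, comparison_index)
    genes = config.gene_ids
    comparison_id = f"{group_label}_{comparison_index:02d}"

    keep = rng.random(len(genes)) >= config.dropout_rate
    if not keep.any():
        raise ConfigError(f"{comparison_id}: every gene dropped (dropout_rate too high)")
    kept_genes = [g for g, k in zip(genes, keep) if k]

    baseline = config.baseline_mean + rng.normal(0.0, 1.0, size=len(kept_genes))
    shift = np.zeros(len(kept_genes))
    realized: dict[str, float] = {}
    planted_by_gene = {p.gene: p for p in config.planted}
    for i, gene in enumerate(kept_genes):
        p = planted_by_gene.get(gene)
        if p is None or group_label not in p.target_groups:
            continue
        if rng.random() < p.penetrance:
            effect = p.effect_log2fc
            if rng.random() < config.sign_flip_rate:
                effect = -effect
            shift[i] = effect
            realized[gene] = effect

    control = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(kept_genes), config.n_control)
    )
    case = (baseline + shift)[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(kept_genes), config.n_case)
    )
    case_df = pd.DataFrame(case, index=kept_genes)
    control_df = pd.DataFrame(control, index=kept_genes)
    truth = TruthSlice(
        comparison_id=comparison_id,
        group_label=group_label,
        realized=realized,
        dropped=frozenset(g for g, k in zip(genes, keep) if not k),
    )
    return case_df, control_df, truth


def generate_compendium(
    config: SyntheticConfig,
    threshold: ThresholdConfig | None = None,
    variant: str = "welch",
) -> tuple[list[ComparisonTable], SyntheticTruth]:
    """Simulate the whole compendium and run the differential stage.

    Returns one :class:`ComparisonTable` per (group, index) — with log2FC,
    raw/adjusted/chosen p-values and the ``passed`` significance flag — plus
    the planted-gene ground truth.
    """
    threshold = threshold or ThresholdConfig()
    tables: list[ComparisonTable] = []
    slices: list[TruthSlice] = []
    for group_label, n_comparisons in config.groups:
        for index in range(n_comparisons):
            case, control, truth = generate_comparison(config, group_label, index)
            records = test_comparison(
                case.to_numpy(), control.to_numpy(), case.index, variant=variant
            )
            records["canonical_id"] = records["source_id"]
            records = mark_significant(records, threshold)
            tables.append(
                ComparisonTable(
                    comparison_id=truth.comparison_id,
                    group_label=group_label,
                    n_case=config.n_case,
                    n_control=config.n_control,
                    records=records,
                )
            )
            slices.append(truth)
    return tables, SyntheticTruth(config=config, slices=slices)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of a config with a different root seed."""
    return replace(config, seed=seed)
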