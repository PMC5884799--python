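"""Planted-truth recovery experiments on synthetic compendia.

These drive the quantitative validation of the vote-counting pipeline:

* exact recovery of the planted gene set in the zero-noise, full-penetrance
  limit, at every frequency tier;
* convergence of a planted gene's empirical consensus frequency to its
  penetrance under realistic noise (binomial confidence-interval check);
* the false-consensus rate of a null compendium against the binomial tail
  bound implied by the per-comparison significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import consensus, merge
from .simulate import PlantedGene, SyntheticConfig, generate_compendium, with_seed

#: Geometry shared by the recovery experiments: the untreated-MS group size.
N_COMPARISONS = 13


def _score_run(config: SyntheticConfig, group: str) -> pd.DataFrame:
    tables, _ = generate_compendium(config)
    long = merge.build_long_table(tables)
    return consensus.score_group(long, group)


@dataclass(frozen=True)
class RecoveryResult:
    planted: frozenset[str]
    recovered_by_tier: dict[float, frozenset[str]]

    @property
    def exact(self) -> bool:
        return all(r == self.planted for r in self.recovered_by_tier.values())


def zero_noise_recovery(
    seed: int = 0,
    n_genes: int = 60,
    tiers: tuple[float, ...] = (0.23, 0.15),
) -> RecoveryResult:
    """Zero-noise-limit, full-penetrance compendium through the full pipeline.

    With penetrance 1 and vanishing within-group noise every planted gene is
    significant in every comparison (frequency 1), so the consensus panel at
    any tier must equal the planted set exactly.
    """
    planted = tuple(
        PlantedGene(
            gene=f"PLANT{i}",
            target_groups=frozenset({"non_treated"}),
            effect_log2fc=2.0 if i % 2 == 0 else -2.0,
            penetrance=1.0,
        )
        for i in range(6)
    )
    config = SyntheticConfig(
        n_genes=n_genes,
        groups=(("non_treated", N_COMPARISONS),),
        n_case=5,
        n_control=5,
        planted=planted,
        noise_sd=1e-6,
        dropout_rate=0.0,
        sign_flip_rate=0.0,
        seed=seed,
    )
    scored = _score_run(config, "non_treated")
    panels = consensus.apply_tiers(scored, consensus.TierConfig(tiers))
    return RecoveryResult(
        planted=frozenset(p.gene for p in planted),
        recovered_by_tier={
            t: frozenset(panel["canonical_id"]) for t, panel in panels.items()
        },
    )


@dataclass(frozen=True)
class FrequencyRecoveryResult:
    penetrance: float
    mean_frequency: float
    n_draws: int
    ci_low: float
    ci_high: float

    @property
    def within_ci(self) -> bool:
        return self.ci_low <= self.mean_frequency <= self.ci_high


def frequency_recovery(
    n_replicates: int = 500,
    penetrance: float = 0.3,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_genes: int = 40,
    n_planted: int = 3,
    ci_level: float = 0.95,
) -> FrequencyRecoveryResult:
    """Mean detected consensus frequency of planted genes vs their penetrance.

    Each replicate simulates 13 comparisons with planted genes of the given
    effect and penetrance under unit log2-scale noise, runs the differential
    and consensus stages, and records each planted gene's consensus frequency
    (0 when undetected).  The replicate-averaged frequency is compared with
    the binomial confidence interval around the penetrance given the total
    number of per-comparison realization draws.
    """
    planted = tuple(
        PlantedGene(
            gene=f"PLANT{i}",
            target_groups=frozenset({"non_treated"}),
            effect_log2fc=effect,
            penetrance=penetrance,
        )
        for i in range(n_planted)
    )
    base = SyntheticConfig(
        n_genes=n_genes,
        groups=(("non_treated", N_COMPARISONS),),
        n_case=20,
        n_control=20,
        planted=planted,
        noise_sd=noise_sd,
        dropout_rate=0.0,
        sign_flip_rate=0.0,
        seed=seed,
    )
    freqs = []
    for rep in range(n_replicates):
        scored = _score_run(with_seed(base, (seed + 1) * 100_003 + rep), "non_treated")
        by_gene = scored.set_index("canonical_id")["frequency"]
        for p in planted:
            freqs.append(float(by_gene.get(p.gene, 0.0)))
    mean_freq = float(np.mean(freqs))
    n_draws = n_replicates * n_planted * N_COMPARISONS
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * np.sqrt(penetrance * (1 - penetrance) / n_draws)
    return FrequencyRecoveryResult(
        penetrance=penetrance,
        mean_frequency=mean_freq,
        n_draws=n_draws,
        ci_low=penetrance - half,
        ci_high=penetrance + half,
    )


@dataclass(frozen=True)
class NullConsensusResult:
    false_rate: float
    bound: float
    n_gene_trials: int

    @property
    def below_bound(self) -> bool:
        return self.false_rate < self.bound


def null_false_consensus(
    n_replicates: int = 100,
    n_genes: int = 200,
    alpha: float = 0.05,
    tier: float = 0.20,
    seed: int = 0,
) -> NullConsensusResult:
    """False-consensus rate of null compendia at a frequency tier.

    No genes are planted; the fraction of (gene, replicate) trials entering
    the panel at the given tier is compared with the binomial tail bound
    P(Binom(13, alpha) >= ceil(tier·13)) — the rate that would obtain if a
    gene were falsely significant in the same direction with probability
    alpha in every comparison.
    """
    base = SyntheticConfig(
        n_genes=n_genes,
        groups=(("non_treated", N_COMPARISONS),),
        n_case=10,
        n_control=10,
        planted=(),
        noise_sd=1.0,
        dropout_rate=0.0,
        sign_flip_rate=0.0,
        seed=seed,
    )
    n_false = 0
    for rep in range(n_replicates):
        scored = _score_run(with_seed(base, (seed + 2) * 99_991 + rep), "non_treated")
        n_false += int((scored["frequency"] > tier).sum())
    # smallest occurrence count with frequency strictly above the tier
    k_min = int(np.floor(tier * N_COMPARISONS)) + 1
    bound = float(stats.binom.sf(k_min - 1, N_COMPARISONS, alpha))
    n_trials = n_replicates * n_genes
    return NullConsensusResult(
        false_rate=n_false / n_trials, bound=bound, n_gene_trials=n_trials
    )
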