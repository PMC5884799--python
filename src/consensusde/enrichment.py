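"""Gene-set over-representation and pathway z-score statistics.

Two complementary statistics are computed for a gene panel against each
annotated gene set: the upper-tail hypergeometric probability P(X ≥ k) with
Benjamini–Hochberg adjustment across sets, and a standardized pathway
z-score

    z = (k − n·K/N) / sqrt(n · (K/N) · (1 − K/N) · (1 − (n−1)/(N−1)))

where N is the universe size, K the set size, n the panel size and k the
observed panel∩set count; the final factor is the finite-population
correction of sampling without replacement.  An empirical p-value for z is
obtained from a permutation null of random panels of the same size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a common universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]


def read_gene_sets(
    gmt_path,
    universe=None,
    min_size: int = 1,
) -> GeneSetCollection:
    """Load a GMT file into a :class:`GeneSetCollection`.

    When ``universe`` is given every set is intersected with it; otherwise
    the universe is the union of all set members.  Sets smaller than
    ``min_size`` after restriction are dropped.
    """
    raw = read_gmt(str(gmt_path))
    if universe is None:
        universe = frozenset(g for members in raw.values() for g in members)
    else:
        universe = frozenset(universe)
    sets = {}
    for term, members in raw.items():
        restricted = frozenset(members) & universe
        if len(restricted) >= min_size:
            sets[term] = restricted
    return GeneSetCollection(sets=sets, universe=universe)


def hypergeometric_ora(panel, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a panel in each gene set.

    Panel genes outside the universe are dropped with a warning.  Returns one
    row per term with k, n, K, N, the upper-tail p-value P(X ≥ k) and its BH
    adjustment across terms.
    """
    if not collection.universe:
        raise ValueError("empty gene universe")
    panel = frozenset(panel)
    outside = panel - collection.universe
    if outside:
        logger.warning(
            "%d panel gene(s) outside the universe dropped", len(outside)
        )
        panel = panel & collection.universe
    N, n = len(collection.universe), len(panel)
    rows = []
    for term, members in collection.sets.items():
        K = len(members)
        k = len(panel & members)
        # P(X >= k) under Hypergeom(N, K, n)
        p_hyper = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_hyper": min(p_hyper, 1.0),
                "z_score": pathway_zscore_counts(k, n, K, N),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p_hyper", "z_score"]
    )
    if len(result):
        result["p_adj"] = bh_adjust(result["p_hyper"].to_numpy())
    else:
        result["p_adj"] = pd.Series(dtype=float)
    return result.sort_values("p_hyper", kind="mergesort").reset_index(drop=True)


def pathway_zscore(panel, term_set, universe) -> float:
    """Pathway z-score of a panel against one gene set (set interface)."""
    panel, term_set, universe = frozenset(panel), frozenset(term_set), frozenset(universe)
    N = len(universe)
    if N < 2:
        raise ValueError("universe must contain at least 2 genes")
    n = len(panel & universe)
    K = len(term_set & universe)
    k = len(panel & term_set & universe)
    return pathway_zscore_counts(k, n, K, N)


def pathway_zscore_counts(k: int, n: int, K: int, N: int) -> float:
    """Pathway z-score from the four counts; 0 when the variance vanishes."""
    if N < 2:
        raise ValueError("universe must contain at least 2 genes")
    if not (0 <= K <= N and 0 <= n <= N and k <= min(n, K)):
        raise ValueError("inconsistent counts")
    frac = K / N
    var = n * frac * (1 - frac) * (1 - (n - 1) / (N - 1))
    if var <= 0:
        if K in (0, N) and n > 0:
            logger.warning("degenerate gene set (K=%d of N=%d): z set to 0", K, N)
        return 0.0
    return float((k - n * frac) / np.sqrt(var))


def permutation_null(
    panel_size: int,
    term_set,
    universe,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    observed_z: float | None = None,
    observed_k: int | None = None,
) -> float:
    """Permutation p-value for an observed pathway z-score.

    Draws ``n_perm`` uniform random panels of ``panel_size`` from the
    universe and compares their z-scores with the observed one:
    p = (1 + #{z_perm ≥ z_obs}) / (n_perm + 1).  Since z is a monotone
    function of the in-set count k for fixed sizes, the null draws are taken
    directly as hypergeometric counts, which is distributionally identical to
    drawing panels and intersecting.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    term_set, universe = frozenset(term_set), frozenset(universe)
    N = len(universe)
    if panel_size > N:
        raise ValueError("panel_size exceeds universe size")
    K = len(term_set & universe)
    if observed_z is None:
        if observed_k is None:
            raise ValueError("provide observed_z or observed_k")
        observed_z = pathway_zscore_counts(observed_k, panel_size, K, N)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ks = rng.hypergeometric(K, N - K, panel_size, size=n_perm)
    zs = np.array([pathway_zscore_counts(int(x), panel_size, K, N) for x in ks])
    return float((1 + np.sum(zs >= observed_z - 1e-12)) / (n_perm + 1))
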