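"""PCA over the comparison-by-gene fold-change matrix.

Relatedness of dataset comparisons is visualised and filtered through PCA of
the comparisons × genes log2FC matrix (missing genes filled with 0 — absence
of evidence treated as no change).  Outlying comparisons are flagged with a
reproducible robust rule: a comparison is an outlier when its score on any of
the first components deviates from the component median by more than
k · 1.4826 · MAD.  Retained comparisons are assigned to the General /
Non-treated / Treated analysis groups from design metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # comparisons × components
    loadings: pd.DataFrame  # genes × components
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray = field(repr=False, default=None)


@dataclass
class GroupingPlan:
    retained: list[str]
    removed: dict[str, str]  # comparison_id -> reason
    assignment: dict[str, str]  # comparison_id -> non_treated | treated


def build_feature_matrix(long: pd.DataFrame, fill: str = "zero") -> pd.DataFrame:
    """Pivot the long table into a comparisons × genes log2FC matrix.

    Rows are comparisons, columns the union of genes across comparisons,
    missing entries 0.  Requires at least two comparisons.
    """
    if fill != "zero":
        raise ValueError("only zero-fill is supported")
    n_comparisons = long["comparison_id"].nunique()
    if n_comparisons < 2:
        raise ValueError("PCA needs at least 2 comparisons")
    matrix = long.pivot_table(
        index="comparison_id",
        columns="canonical_id",
        values="log2fc",
        aggfunc="mean",
        fill_value=0.0,
    )
    return matrix.astype(float)


def run_pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of the (column-centered) feature matrix.

    Components are orthonormal; with all components retained the centered
    matrix is reconstructed to numerical tolerance.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    centered = X - X.mean(axis=0)
    if not np.any(centered):
        raise ValueError("degenerate feature matrix: zero variance everywhere")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_labels = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_labels),
        loadings=pd.DataFrame(
            pca.components_.T, index=matrix.columns, columns=comp_labels
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean_=pca.mean_,
    )


def flag_outliers(
    result: PcaResult,
    k: float = 3.0,
    n_components: int = 2,
    manual: list[str] | None = None,
) -> list[str]:
    """Comparisons deviating more than k robust spreads on an early component.

    The spread is the scaled median absolute deviation (1.4826 · MAD); a
    component whose MAD is zero is skipped with a warning.  ``manual`` ids are
    always flagged.  Deterministic and invariant to row order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    flagged: set[str] = set(manual or ())
    scores = result.scores
    for col in scores.columns[:n_components]:
        s = scores[col].to_numpy()
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        if mad == 0:
            logger.warning("component %s has zero MAD; skipped", col)
            continue
        spread = 1.4826 * mad
        out = scores.index[np.abs(s - med) > k * spread]
        flagged.update(out)
    return sorted(flagged)


def assign_groups(
    metadata: dict[str, str], retained: list[str]
) -> GroupingPlan:
    """Partition retained comparisons into non_treated / treated groups.

    ``metadata`` maps every comparison to its design: ``'non_treated'``
    (healthy vs disease) or ``'treated'`` (disease vs treated disease).  The
    general group is all retained comparisons.
    """
    assignment: dict[str, str] = {}
    for cid in retained:
        if cid not in metadata:
            raise ValueError(f"comparison {cid!r} has no design metadata")
        design = metadata[cid]
        if design not in ("non_treated", "treated"):
            raise ValueError(f"comparison {cid!r}: unknown design {design!r}")
        assignment[cid] = design
    return GroupingPlan(retained=list(retained), removed={}, assignment=assignment)


def plot_scores(result: PcaResult, path, groups: dict[str, str] | None = None) -> None:
    """Scatter of the first two PCA score components (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    scores = result.scores
    colors = None
    if groups:
        labels = [groups.get(c, "?") for c in scores.index]
        uniq = sorted(set(labels))
        cmap = dict(zip(uniq, plt.cm.tab10.colors))
        colors = [cmap[label] for label in labels]
    ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], c=colors, s=25)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    if scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
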