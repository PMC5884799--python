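"""Per-comparison differential expression testing.

Each dataset comparison is analysed independently: a two-sample t-test per
molecule (Welch by default, pooled-variance Student available), Benjamini–
Hochberg adjustment across molecules, and a fallback rule for statistically
poor comparisons — when no molecule survives adjustment at 0.05, the raw
p-values are used instead.  Significance is then thresholded at p < 0.05 and
|log2FC| > 1 (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ComparisonTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    df: float


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance cut-offs: p < p_cut and log2FC > lfc_cut or < -lfc_cut."""

    p_cut: float = 0.05
    lfc_cut: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cut < 1.0:
            raise ValueError("p_cut must be in (0, 1)")
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be >= 0")


def two_sample_t(case, control, variant: str = "welch") -> TestResult:
    """Two-sided two-sample t-test of case vs control expression values.

    ``variant='pooled'`` is the classic equal-variance Student test with
    df = n1 + n2 - 2; ``'welch'`` uses the Welch–Satterthwaite approximation.
    Two constant, equal groups yield (t=0, p=1) rather than NaN.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(case).all() and np.isfinite(control).all()):
        raise ValueError("non-finite expression value")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")

    if case.var(ddof=1) == 0 and control.var(ddof=1) == 0:
        df = case.size + control.size - 2.0
        if case.mean() == control.mean():
            return TestResult(0.0, 1.0, df)
        # degenerate but unambiguous: zero within-group spread, shifted means
        return TestResult(np.inf if case.mean() > control.mean() else -np.inf, 0.0, df)

    res = stats.ttest_ind(case, control, equal_var=(variant == "pooled"))
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def choose_pvalue_column(
    raw, adjusted, poor_cut: float = 0.05
) -> tuple[np.ndarray, bool]:
    """Pick the p-value column for a comparison, with the poor-dataset rule.

    If no molecule's adjusted p-value falls below ``poor_cut`` the comparison
    is treated as statistically poor and the raw p-values are used; otherwise
    the adjusted ones are.  Returns ``(chosen, used_adjusted)``.
    """
    raw = np.asarray(raw, dtype=float)
    adjusted = np.asarray(adjusted, dtype=float)
    if raw.shape != adjusted.shape:
        raise ValueError("raw and adjusted p-value vectors differ in length")
    if raw.size == 0:
        return raw.copy(), True
    used_adjusted = bool(np.nanmin(adjusted) <= poor_cut)
    chosen = adjusted if used_adjusted else raw
    if not used_adjusted:
        logger.info(
            "statistically poor comparison: min adjusted p %.3g > %.3g, "
            "falling back to raw p-values",
            np.nanmin(adjusted),
            poor_cut,
        )
    return chosen.copy(), used_adjusted


def log2_fold_change(case, control, scale: str = "already_log2") -> float:
    """log2 fold change of case over control group means."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("empty expression vector")
    if scale == "already_log2":
        return float(case.mean() - control.mean())
    if scale == "linear":
        mc, mk = case.mean(), control.mean()
        if mc <= 0 or mk <= 0:
            raise ValueError("linear-scale fold change requires positive means")
        return float(np.log2(mc / mk))
    raise ValueError(f"unknown scale {scale!r}")


def test_comparison(
    case: np.ndarray,
    control: np.ndarray,
    gene_ids,
    variant: str = "welch",
    scale: str = "already_log2",
) -> pd.DataFrame:
    """Vectorised per-gene DE table for one comparison.

    ``case``/``control`` are genes × samples matrices on the given scale.
    Returns a records DataFrame (source_id, log2fc, pvalue, adj_pvalue,
    chosen_p, used_adjusted) ready for thresholding.
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=(variant == "pooled"))
    pvalues = np.asarray(res.pvalue, dtype=float)
    stats_t = np.asarray(res.statistic, dtype=float)
    # constant, equal groups: define t=0, p=1
    degenerate = np.isnan(pvalues)
    if degenerate.any():
        equal = np.isclose(case.mean(axis=1), control.mean(axis=1))
        pvalues[degenerate & equal] = 1.0
        stats_t[degenerate & equal] = 0.0
        pvalues[degenerate & ~equal] = 0.0

    if scale == "already_log2":
        lfc = case.mean(axis=1) - control.mean(axis=1)
    else:
        lfc = np.array(
            [log2_fold_change(c, k, scale) for c, k in zip(case, control)]
        )

    adj = bh_adjust(pvalues)
    chosen, used_adjusted = choose_pvalue_column(pvalues, adj)
    return pd.DataFrame(
        {
            "source_id": list(gene_ids),
            "log2fc": lfc,
            "pvalue": pvalues,
            "adj_pvalue": adj,
            "chosen_p": chosen,
            "used_adjusted": used_adjusted,
            "t_statistic": stats_t,
        }
    )


def threshold_significant(
    table: ComparisonTable, cfg: ThresholdConfig | None = None
) -> ComparisonTable:
    """Flag and retain records passing p < p_cut and |log2FC| > lfc_cut.

    Uses the ``chosen_p`` column when present (post fallback rule), otherwise
    ``adj_pvalue`` falling back to ``pvalue``.  Both inequalities are strict.
    """
    cfg = cfg or ThresholdConfig()
    records = mark_significant(table.records, cfg)
    return replace(table, records=records.loc[records["passed"]].reset_index(drop=True))


def mark_significant(records: pd.DataFrame, cfg: ThresholdConfig) -> pd.DataFrame:
    """Add/refresh the boolean ``passed`` column without dropping rows."""
    records = records.copy()
    if "chosen_p" in records.columns:
        p = records["chosen_p"]
    elif "adj_pvalue" in records.columns and records["adj_pvalue"].notna().all():
        p = records["adj_pvalue"]
    else:
        p = records["pvalue"]
    lfc = records["log2fc"]
    records["passed"] = (p < cfg.p_cut) & ((lfc > cfg.lfc_cut) | (lfc < -cfg.lfc_cut))
    return records
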