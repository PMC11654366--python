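"""Neighboring-cell-dependent differential expression.

After decomposition, the reference cells that scored above the selection
cutoff in at least one real doublet are assumed to have been physically
interacting with the partner cell type.  Genes whose expression differs
between these selected cells and the unselected cells of the same type
are the neighboring-cell-dependent genes.

The test is the two-sided Wilcoxon–Mann–Whitney rank-sum test run per
gene on preprocessed expression (per-cell 10,000-total scaling, ln(x+1),
total-count regression, per-gene z-scoring), with Benjamini–Hochberg
adjustment.  Effect size is

    logFC = log2((mean1 + b) / (mean2 + b)),   b = 1 by default,

where the group means are taken on the 10,000-normalized linear scale —
the pseudo-count b only makes sense for non-negative means, which the
regressed/scaled values used by the rank test are not.  Both scale
choices are configurable.  A gene is flagged when adjusted p < 0.05 and
|logFC| > 0.5 (defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .expr_data import (
    ExpressionMatrix,
    lognorm_10k,
    regress_out_totals,
    scale_genes,
)

__all__ = [
    "DEConfig",
    "DEResult",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "log_fc",
    "neighboring_de",
    "NeighborDE",
]

# exact null enumeration is used when n*m is at most this and there are no ties
EXACT_LIMIT = 200


@dataclass(frozen=True)
class DEConfig:
    """Cutoffs and constants of the differential test."""

    alpha_adj: float = 0.05
    lfc_cutoff: float = 0.5
    pseudo_b: float = 1.0
    adjustment: Literal["fdr_bh"] = "fdr_bh"
    test_scale: Literal["scaled", "lognorm"] = "scaled"
    mean_scale: Literal["norm10k", "lognorm"] = "norm10k"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_adj < 1.0:
            raise ValueError("alpha_adj must be in (0, 1)")
        if self.lfc_cutoff < 0:
            raise ValueError("lfc_cutoff must be >= 0")
        if self.pseudo_b <= 0:
            raise ValueError("pseudo_b must be positive")


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test of two independent samples.

    Midranks handle ties.  For small samples (n*m <= 200) without ties the
    p-value comes from exact enumeration of the null distribution;
    otherwise from the tie-corrected normal approximation with continuity
    correction.  Returns ``(U, p)`` with U computed for the first sample.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        # degenerate: all values identical; no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    method = "exact" if (len(x) * len(y) <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(pvals), dtype=np.float64)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_fc(mean1: float, mean2: float, b: float = 1.0) -> float:
    """log2 fold change with pseudo-count b damping low-expression genes."""
    if mean1 < 0 or mean2 < 0:
        raise ValueError("means must be non-negative")
    if b <= 0:
        raise ValueError("b must be positive")
    return math.log2((mean1 + b) / (mean2 + b))


def _mwu_pergene(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene rank-sum test (columns are genes)."""
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 * n2 <= EXACT_LIMIT:
        stats = np.empty(x1.shape[1])
        pvals = np.empty(x1.shape[1])
        for g in range(x1.shape[1]):
            stats[g], pvals[g] = wilcoxon_rank_sum(x1[:, g], x2[:, g])
        return stats, pvals
    res = scipy.stats.mannwhitneyu(
        x1, x2, alternative="two-sided", method="asymptotic",
        use_continuity=True, axis=0,
    )
    stats = np.asarray(res.statistic, dtype=np.float64)
    pvals = np.asarray(res.pvalue, dtype=np.float64)
    # constant genes produce sd=0 under the tie correction -> NaN; no signal
    degenerate = ~np.isfinite(pvals)
    pvals[degenerate] = 1.0
    return stats, pvals


@dataclass
class DEResult:
    """Per-gene differential-expression table plus the config that made it."""

    table: pd.DataFrame
    config: DEConfig
    n_selected: int
    n_other: int

    @property
    def up(self) -> list[str]:
        t = self.table
        return t.loc[t["pass"] & (t["direction"] == "up"), "gene"].tolist()

    @property
    def down(self) -> list[str]:
        t = self.table
        return t.loc[t["pass"] & (t["direction"] == "down"), "gene"].tolist()

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Neighboring-cell-dependent differential expression",
            "=" * 56,
            f"selected cells: {self.n_selected}   unselected: {self.n_other}",
            f"cutoffs: adjusted p < {cfg.alpha_adj}, |logFC| > {cfg.lfc_cutoff} "
            f"(b = {cfg.pseudo_b})",
            f"upregulated genes: {len(self.up)}   downregulated: {len(self.down)}",
        ]
        top = self.table.loc[self.table["pass"]].nsmallest(12, "pval_adj")
        if len(top):
            with pd.option_context("display.float_format", "{:.3g}".format):
                lines.append(top.to_string(index=False))
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def neighboring_de(
    matrix: ExpressionMatrix,
    selected: Iterable[str],
    cfg: DEConfig | None = None,
) -> DEResult:
    """Test every gene between selected and unselected cells of one type.

    ``matrix`` holds the reference single cells of one cell type;
    ``selected`` names the cells retained by the score cutoff.  See the
    module docstring for the processing chain and flagging rule.
    """
    cfg = cfg or DEConfig()
    selected = set(selected)
    unknown = selected - set(matrix.cell_ids)
    if unknown:
        raise ValueError(f"selected cells not in matrix: {sorted(unknown)[:5]}")
    sel_mask = np.array([c in selected for c in matrix.cell_ids])
    if sel_mask.sum() < 2 or (~sel_mask).sum() < 2:
        raise ValueError("selected and unselected groups each need >= 2 cells")

    logn = lognorm_10k(matrix)
    if cfg.test_scale == "scaled":
        processed = scale_genes(regress_out_totals(logn, matrix.totals()))
    else:
        processed = logn
    x1 = processed.values[sel_mask]
    x2 = processed.values[~sel_mask]
    stats, pvals = _mwu_pergene(x1, x2)
    padj = bh_adjust(pvals)

    if cfg.mean_scale == "norm10k":
        norm = matrix.counts / matrix.totals()[:, None] * 1e4
    else:
        norm = logn.values
    mean_sel = norm[sel_mask].mean(axis=0)
    mean_other = norm[~sel_mask].mean(axis=0)
    lfc = np.log2((mean_sel + cfg.pseudo_b) / (mean_other + cfg.pseudo_b))

    passes = (padj < cfg.alpha_adj) & (np.abs(lfc) > cfg.lfc_cutoff)
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "mean_selected": mean_sel,
            "mean_other": mean_other,
            "u_stat": stats,
            "pval": pvals,
            "pval_adj": padj,
            "log_fc": lfc,
            "direction": direction,
            "pass": passes,
        }
    )
    return DEResult(
        table=table,
        config=cfg,
        n_selected=int(sel_mask.sum()),
        n_other=int((~sel_mask).sum()),
    )


class NeighborDE:
    """Model-style wrapper: data in the constructor, ``fit()`` runs the test."""

    def __init__(
        self,
        matrix: ExpressionMatrix,
        selected: Iterable[str],
        config: DEConfig | None = None,
    ) -> None:
        self.matrix = matrix
        self.selected = set(selected)
        self.config = config or DEConfig()

    def fit(self) -> DEResult:
        return neighboring_de(self.matrix, self.selected, self.config)
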