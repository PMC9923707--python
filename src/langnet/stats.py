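"""Downstream expression-specificity statistics.

Welch two-sample contrast of gene expression between network regions and
comparison regions (with Benjamini-Hochberg FDR across the tested genes
and a 95% confidence interval of the mean difference), plus the fold-change
rule for calling a gene specific to one cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialExpressionResult",
    "differential_expression",
    "bh_fdr",
    "celltype_specificity",
    "welch_t",
]


@dataclass(frozen=True)
class DifferentialExpressionResult:
    gene_id: str
    t: float
    df: float
    p: float
    p_fdr: float
    mean_in: float
    mean_out: float
    ci_low: float
    ci_high: float


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def differential_expression(
    rem: pd.DataFrame,
    in_regions: Sequence[int],
    out_regions: Sequence[int],
    genes: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch contrast of expression between two region groups.

    ``rem`` is regions x genes.  The groups must be disjoint and each have
    at least 2 regions.  Returns one row per gene with the Welch t,
    Welch-Satterthwaite df, two-sided p, Benjamini-Hochberg adjusted p
    over the supplied gene list, the group means, and a 95% CI of the
    mean difference (in - out).
    """
    in_set, out_set = set(in_regions), set(out_regions)
    if in_set & out_set:
        raise ValueError("region groups overlap; they must be disjoint")
    if len(in_set) < 2 or len(out_set) < 2:
        raise ValueError("each region group needs at least 2 regions")
    missing = [g for g in genes if g not in rem.columns]
    if missing:
        raise ValueError(f"genes not in expression matrix: {missing[:5]}")

    a_all = rem.loc[list(in_regions), list(genes)].to_numpy(dtype=float)
    b_all = rem.loc[list(out_regions), list(genes)].to_numpy(dtype=float)
    rows = []
    for k, g in enumerate(genes):
        a, b = a_all[:, k], b_all[:, k]
        t, df, p = welch_t(a, b)
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        diff = a.mean() - b.mean()
        half = sps.t.ppf(1.0 - alpha / 2.0, df) * se
        rows.append(
            {
                "gene_id": g,
                "t": t,
                "df": df,
                "p": p,
                "mean_in": float(a.mean()),
                "mean_out": float(b.mean()),
                "ci_low": float(diff - half),
                "ci_high": float(diff + half),
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out[["t", "df", "p", "p_fdr", "mean_in", "mean_out", "ci_low", "ci_high"]]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def celltype_specificity(
    table: pd.DataFrame, fold: float = 1.5
) -> pd.DataFrame:
    """Call genes specific to one cell type by a fold-change rule.

    ``table`` is cell types x genes with nonnegative expression.  A gene
    is specific to cell type c iff its expression in c is at least
    ``fold`` times the maximum over all other cell types.  Returns one row
    per gene with the top cell type (or None), and the top/second ratio.
    All-zero genes get no call and are flagged.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 cell types")
    vals = table.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("expression must be nonnegative")
    rows = []
    for j, gene in enumerate(table.columns):
        col = vals[:, j]
        if np.all(col == 0):
            rows.append(
                {"gene_id": gene, "top_cell_type": None, "ratio": 0.0,
                 "flag": "all_zero"}
            )
            continue
        order = np.argsort(col)[::-1]
        top, second = col[order[0]], col[order[1]]
        ratio = float(np.inf) if second == 0 else float(top / second)
        specific = ratio >= fold
        rows.append(
            {
                "gene_id": gene,
                "top_cell_type": str(table.index[order[0]]) if specific else None,
                "ratio": ratio,
                "flag": "",
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
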