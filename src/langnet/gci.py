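"""Leave-one-out gene contribution index (GCI) and consensus genes.

The GCI of a gene, for one (region set, cohort) analysis, is the drop in
the overall connectivity-similarity Spearman correlation when that gene is
removed before the similarity matrix is built:

    GCI(g) = rho(full gene set) - rho(gene set without g)

so a positive score means the gene supports the observed correlation.
Removal happens at the similarity-construction step, not at the matrix-
correlation step.  Leave-one-out similarity matrices are obtained by
downdating the full set's cross-products rather than recomputing from
scratch, which makes the scan linear in the number of genes.

Consensus genes are those with strictly positive GCI in every analysis of
the factorial design (region definitions x cohorts).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .netcorr import spearman, upper_triangle

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusSet",
    "gci",
    "consensus_genes",
    "gci_cross_correlation",
    "compare_consensus_gci",
    "top_mean_gci",
]


@dataclass(frozen=True)
class ConsensusSet:
    gene_ids: tuple[str, ...]
    rule: str


def gci(
    rem: pd.DataFrame, fc: pd.DataFrame, gene_set: Sequence[str]
) -> pd.Series:
    """Leave-one-out contribution of each gene in ``gene_set``.

    ``rem`` is the regions-by-genes expression matrix and ``fc`` the group
    connectivity matrix over the same ordered regions.
    """
    genes = list(gene_set)
    if len(genes) < 3:
        raise ValueError("gene_set must have at least 3 genes")
    if not rem.index.equals(fc.index):
        raise ValueError("expression and connectivity region order differ")

    x = rem.loc[:, genes].to_numpy(dtype=float)  # regions x genes
    n_regions, n_genes = x.shape
    # centering each region's profile stabilizes the sum-of-products
    # downdating below; correlations are shift-invariant per region
    x = x - x.mean(axis=1, keepdims=True)

    fc_vec = upper_triangle(fc)
    iu = np.triu_indices(n_regions, k=1)

    s = x.sum(axis=1)  # per-region sums
    q = x @ x.T  # cross-products
    rho_full, _ = spearman(fc_vec, _corr_from_stats(q, s, n_genes)[iu])

    fc_ranks = stats.rankdata(fc_vec)
    out = np.empty(n_genes)
    for g in range(n_genes):
        xg = x[:, g]
        s_loo = s - xg
        q_loo = q - np.outer(xg, xg)
        sim = _corr_from_stats(q_loo, s_loo, n_genes - 1, context=genes[g])
        sim_ranks = stats.rankdata(sim[iu])
        out[g] = rho_full - np.corrcoef(fc_ranks, sim_ranks)[0, 1]
    return pd.Series(out, index=genes, name="gci")


def _corr_from_stats(
    q: np.ndarray, s: np.ndarray, n: int, context: str | None = None
) -> np.ndarray:
    """Pearson correlation matrix from cross-products and sums."""
    cov = q / n - np.outer(s, s) / n**2
    var = np.diag(cov).copy()
    if np.any(var <= 0):
        which = np.flatnonzero(var <= 0)
        msg = f"zero-variance region profile (rows {which.tolist()})"
        if context is not None:
            msg += f" after removing gene {context!r}"
        raise ValueError(msg)
    d = np.sqrt(var)
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def consensus_genes(table: pd.DataFrame, rule: str = "all_positive") -> ConsensusSet:
    """Genes with strictly positive GCI in every analysis column.

    ``table`` is genes x analyses.  Zeros do not count as positive.  An
    empty consensus is allowed but warned about.
    """
    if table.empty:
        raise ValueError("GCI table is empty")
    if rule != "all_positive":
        raise ValueError(f"unknown consensus rule {rule!r}")
    mask = (table > 0).all(axis=1)
    ids = tuple(table.index[mask])
    if not ids:
        warnings.warn("no gene has positive GCI in all analyses", stacklevel=2)
    return ConsensusSet(gene_ids=ids, rule="GCI > 0 in all analyses")


def gci_cross_correlation(
    table: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Correlation of GCI profiles between every pair of analyses.

    Pearson by default (Spearman available); computed over genes present
    in both columns of a pair.  Raises if a pair shares fewer than 3
    genes.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 analyses")
    cols = list(table.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pair = table[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"analyses {cols[i]!r} and {cols[j]!r} share fewer than "
                    "3 genes"
                )
            if method == "pearson":
                r = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
            elif method == "spearman":
                r = float(stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])[0])
            else:
                raise ValueError(f"unknown method {method!r}")
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


def compare_consensus_gci(
    table: pd.DataFrame, consensus: ConsensusSet
) -> pd.DataFrame:
    """Welch t-test of consensus vs all other genes, per analysis.

    Unequal variances are not assumed equal (Welch-Satterthwaite degrees
    of freedom); p-values are two-sided.
    """
    in_mask = table.index.isin(consensus.gene_ids)
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError("both groups need at least 2 genes")
    rows = []
    for col in table.columns:
        a = table.loc[in_mask, col].dropna()
        b = table.loc[~in_mask, col].dropna()
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "analysis": col,
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "mean_consensus": float(a.mean()),
                "mean_rest": float(b.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("analysis")


def top_mean_gci(
    table: pd.DataFrame, columns: Sequence[str], n: int
) -> list[str]:
    """The ``n`` genes with the highest GCI averaged over ``columns``.

    This is how a comparison network's "top genes" are picked: rank by the
    mean score over that network's cohort analyses.  Ties break
    lexicographically by gene id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    means = table[list(columns)].mean(axis=1)
    order = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order[:n]]
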