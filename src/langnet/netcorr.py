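"""Connectivity-vs-transcriptomic-similarity correlation statistics.

The match between a functional connectivity matrix and an expression
similarity matrix over the same region set is quantified by the Spearman
correlation of their strict upper triangles.  A distance-corrected variant
partials out the Euclidean distance between region centers (Pearson on the
residuals of rank-transformed vectors).  Significance against gene
selection is assessed with a random-gene-set null: equal-sized gene sets
drawn without replacement from the full pool, the similarity matrix and
its correlation with connectivity recomputed for each draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import expression_similarity
from .regions import RegionSet

__all__ = [
    "NetworkCorrelationResult",
    "upper_triangle",
    "spearman",
    "partial_spearman",
    "region_distances",
    "random_gene_null",
    "correlate_networks",
]


@dataclass(frozen=True)
class NetworkCorrelationResult:
    """Full record of one network-level correlation analysis."""

    rho: float
    p_parametric: float
    n_pairs: int
    rho_partial: float | None = None
    p_partial: float | None = None
    null_rhos: np.ndarray | None = None
    p_empirical: float | None = None

    def to_dict(self) -> dict:
        d = {
            "rho": self.rho,
            "p_parametric": self.p_parametric,
            "n_pairs": self.n_pairs,
            "rho_partial": self.rho_partial,
            "p_partial": self.p_partial,
            "p_empirical": self.p_empirical,
        }
        if self.null_rhos is not None:
            d["null_rhos"] = np.asarray(self.null_rhos).tolist()
        return d


def upper_triangle(m) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major order.

    The ordering is a pure function of the matrix size, so every matrix
    built over the same ordered region set vectorizes identically.
    """
    a = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    return a[np.triu_indices(a.shape[0], k=1)]


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Average-rank Spearman correlation with a two-sided parametric p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation of x and y after partialling out a covariate.

    All three vectors are rank-transformed (average ranks); ranked x and
    ranked y are each regressed on the ranked covariate (least squares
    with intercept) and the Pearson correlation of the residuals is
    returned, with a two-sided p from a t distribution on n - 3 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == c.shape) or x.ndim != 1:
        raise ValueError("x, y and covariate must be 1-D vectors of equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    rx, ry, rc = (stats.rankdata(v) for v in (x, y, c))
    design = np.column_stack([np.ones(n), rc])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    ss_x, ss_y = (res_x**2).sum(), (res_y**2).sum()
    if ss_x < 1e-12 * n or ss_y < 1e-12 * n:
        raise ValueError(
            "covariate is rank-collinear with an input; partial correlation "
            "is degenerate"
        )
    r = float((res_x @ res_y) / np.sqrt(ss_x * ss_y))
    df = n - 3
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def region_distances(metadata: pd.DataFrame, region_set: RegionSet) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between region centers.

    Returned in the same strict-upper-triangle order as
    :func:`upper_triangle` over the region set.
    """
    from scipy.spatial.distance import pdist

    meta = metadata.set_index("region_id") if "region_id" in metadata.columns else metadata
    missing = [r for r in region_set.region_ids if r not in meta.index]
    if missing:
        raise ValueError(f"regions {missing} have no center coordinates")
    centers = meta.loc[list(region_set.region_ids), ["x_mm", "y_mm", "z_mm"]]
    if centers.isna().any().any():
        raise ValueError("region centers contain missing coordinates")
    return pdist(centers.to_numpy(dtype=float))


def random_gene_null(
    rem: pd.DataFrame,
    fc: pd.DataFrame,
    gene_pool: Sequence[str],
    set_size: int,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
    observed_rho: float | None = None,
    observed_genes: Sequence[str] | None = None,
) -> tuple[np.ndarray, float | None]:
    """Null distribution of rho over random equal-sized gene sets.

    Each of ``n_draws`` draws samples ``set_size`` genes without
    replacement from ``gene_pool``, rebuilds the similarity matrix on the
    drawn set and correlates it with ``fc``.  Given an observed statistic —
    either ``observed_rho`` directly or ``observed_genes``, whose rho is
    computed through the same code path as the nulls so that exact ties
    compare exactly — the one-sided (greater) empirical p-value
    (#{null >= observed} + 1) / (n_draws + 1) is returned with the null
    vector; it is never exactly zero.
    """
    pool = list(gene_pool)
    if set_size < 2:
        raise ValueError("set_size must be at least 2")
    if set_size > len(pool):
        raise ValueError("set_size exceeds the gene pool")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fc_vec = upper_triangle(fc)
    fc_ranks = stats.rankdata(fc_vec)

    def _rho(gene_ids) -> float:
        sim = expression_similarity(rem, gene_ids)
        sim_ranks = stats.rankdata(upper_triangle(sim))
        return float(np.corrcoef(fc_ranks, sim_ranks)[0, 1])

    nulls = np.empty(n_draws)
    for b in range(n_draws):
        draw = rng.choice(len(pool), size=set_size, replace=False)
        nulls[b] = _rho([pool[i] for i in draw])
    if observed_genes is not None:
        observed_rho = _rho(list(observed_genes))
    p_emp = None
    if observed_rho is not None:
        p_emp = (float(np.sum(nulls >= observed_rho)) + 1.0) / (n_draws + 1.0)
    return nulls, p_emp


def correlate_networks(
    fc: pd.DataFrame,
    sim: pd.DataFrame,
    distances: np.ndarray | None = None,
    rem: pd.DataFrame | None = None,
    gene_pool: Sequence[str] | None = None,
    set_size: int | None = None,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
    observed_genes: Sequence[str] | None = None,
) -> NetworkCorrelationResult:
    """One-stop analysis record: plain, distance-partial, and empirical p.

    ``fc`` and ``sim`` must share region order.  ``distances`` enables the
    partial correlation; ``rem``/``gene_pool``/``set_size`` enable the
    random-gene-set null (``observed_genes`` names the set behind ``sim``
    so that the observed rho is recomputed through the null's code path).
    """
    if not fc.index.equals(sim.index):
        raise ValueError("connectivity and similarity matrices have "
                         "mismatched region order")
    x = upper_triangle(fc)
    y = upper_triangle(sim)
    rho, p = spearman(x, y)
    rho_partial = p_partial = None
    if distances is not None:
        rho_partial, p_partial = partial_spearman(x, y, distances)
    nulls = p_emp = None
    if rem is not None and gene_pool is not None and set_size is not None:
        nulls, p_emp = random_gene_null(
            rem, fc, gene_pool, set_size, n_draws=n_draws, seed=seed,
            observed_genes=observed_genes,
        )
    return NetworkCorrelationResult(
        rho=rho,
        p_parametric=p,
        n_pairs=x.size,
        rho_partial=rho_partial,
        p_partial=p_partial,
        null_rhos=nulls,
        p_empirical=p_emp,
    )
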