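"""From donor site-level expression to regional transcriptomic similarity.

The chain is: collapse microarray probes to genes (mean per gene per site
per donor), assign sampling sites to atlas regions by their millimetre
coordinates, average within region (pooled across all sites of all donors,
or donor means first), filter genes by differential stability — the mean
Pearson correlation of a gene's regional profile between donor pairs — and
finally correlate regional expression profiles between every pair of
regions to obtain the transcriptomic similarity matrix.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import RegionSet
from .synthetic import Atlas

logger = logging.getLogger(__name__)

__all__ = [
    "collapse_probes",
    "assign_sites_to_regions",
    "build_region_expression",
    "differential_stability",
    "select_stable_genes",
    "expression_similarity",
]


def collapse_probes(
    table: pd.DataFrame, probe_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Average multi-probe measurements to one value per gene per site.

    ``probe_map`` maps probe_id to gene_id; if omitted, the table's own
    ``gene_id`` column is used.  Probes mapping to no gene are dropped with
    a warning reporting how many.
    """
    t = table.copy()
    if probe_map is not None:
        t["gene_id"] = t["probe_id"].map(dict(probe_map))
    if "gene_id" not in t.columns:
        raise ValueError("no gene_id column and no probe_map supplied")
    unmapped = t["gene_id"].isna()
    if unmapped.any():
        n_probes = t.loc[unmapped, "probe_id"].nunique()
        warnings.warn(
            f"dropping {n_probes} probe(s) with no gene mapping",
            stacklevel=2,
        )
        t = t[~unmapped]
    keys = ["donor_id", "site_id", "gene_id"]
    coord_cols = [c for c in ("x_mm", "y_mm", "z_mm", "region_id") if c in t.columns]
    agg = {c: "first" for c in coord_cols}
    agg["value"] = "mean"
    out = t.groupby(keys, as_index=False, sort=False).agg(agg)
    return out[keys[:2] + coord_cols + ["gene_id", "value"]]


def assign_sites_to_regions(
    table: pd.DataFrame, atlas: Atlas, snap_radius_mm: float = 2.0
) -> pd.DataFrame:
    """Label each sampling site with the atlas region containing it.

    Site millimetre coordinates are mapped through the inverse affine to
    voxel indices.  Sites landing on background (or outside the volume)
    are snapped to the nearest labeled voxel if one lies within
    ``snap_radius_mm``; otherwise they stay unassigned (region_id NaN) and
    are counted in the log.
    """
    from scipy.spatial import cKDTree

    sites = table[["site_id", "x_mm", "y_mm", "z_mm"]].drop_duplicates("site_id")
    xyz = sites[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    inv = np.linalg.inv(atlas.affine)
    ijk = np.round(xyz @ inv[:3, :3].T + inv[:3, 3]).astype(int)

    shape = np.asarray(atlas.labels.shape)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    labels = np.full(len(sites), 0, dtype=int)
    labels[inside] = atlas.labels[tuple(ijk[inside].T)]

    missing = labels == 0
    if missing.any() and snap_radius_mm > 0:
        lab_ijk = np.argwhere(atlas.labels > 0)
        lab_mm = lab_ijk @ atlas.affine[:3, :3].T + atlas.affine[:3, 3]
        tree = cKDTree(lab_mm)
        dist, idx = tree.query(xyz[missing], k=1)
        snapped = atlas.labels[tuple(lab_ijk[idx].T)]
        snapped[dist > snap_radius_mm] = 0
        labels[missing] = snapped

    n_unassigned = int((labels == 0).sum())
    if n_unassigned:
        logger.info("%d site(s) could not be assigned to any region", n_unassigned)
    assignment = pd.Series(
        np.where(labels == 0, np.nan, labels), index=sites["site_id"]
    )
    out = table.copy()
    out["region_id"] = out["site_id"].map(assignment)
    return out


def build_region_expression(
    table: pd.DataFrame,
    region_set: RegionSet,
    mode: str = "pooled",
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Aggregate site-level values to one expression measure per region.

    ``pooled`` (default) averages over all sites of all donors in a region;
    ``donor_first`` averages each donor's sites first and then averages the
    donor means.  Also returns the per-donor region-by-gene matrices needed
    for differential stability.

    Raises if a retained region has no assigned sites — such regions should
    already have been removed by the exclusion rules.
    """
    if mode not in ("pooled", "donor_first"):
        raise ValueError(f"unknown mode {mode!r}")
    t = table.dropna(subset=["region_id"]).copy()
    t["region_id"] = t["region_id"].astype(int)
    t = t[t["region_id"].isin(region_set.region_ids)]

    present = set(t["region_id"].unique())
    empty = [r for r in region_set.region_ids if r not in present]
    if empty:
        raise ValueError(
            f"regions {empty} have no assigned sampling sites; apply the "
            "exclusion rules before building the expression matrix"
        )

    donor_mats: dict[str, pd.DataFrame] = {}
    for donor_id, sub in t.groupby("donor_id"):
        donor_mats[donor_id] = sub.pivot_table(
            index="region_id", columns="gene_id", values="value", aggfunc="mean"
        )

    if mode == "pooled":
        pooled = t.pivot_table(
            index="region_id", columns="gene_id", values="value", aggfunc="mean"
        )
    else:
        pooled = (
            pd.concat(donor_mats, names=["donor_id"])
            .groupby(level="region_id")
            .mean()
        )
    pooled = pooled.reindex(index=list(region_set.region_ids))
    return pooled, donor_mats


def differential_stability(
    per_donor: Mapping[str, pd.DataFrame], min_common_regions: int = 3
) -> pd.Series:
    """Mean Pearson correlation of regional profiles between donor pairs.

    For each gene, every pair of donors contributes the correlation of the
    two donors' regional expression profiles over their pairwise-complete
    regions (pairs sharing fewer than ``min_common_regions`` regions with
    data are skipped).  Genes measured in fewer than two donors, or with no
    valid donor pair, are excluded from the result and logged.
    """
    donors = list(per_donor)
    if len(donors) < 2:
        raise ValueError("differential stability needs at least two donors")
    genes = sorted(set().union(*(set(m.columns) for m in per_donor.values())))
    sums = pd.Series(0.0, index=genes)
    counts = pd.Series(0, index=genes)
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            a, b = per_donor[donors[i]], per_donor[donors[j]]
            common_genes = a.columns.intersection(b.columns)
            common_regions = a.index.intersection(b.index)
            if len(common_regions) < min_common_regions:
                continue
            x = a.loc[common_regions, common_genes].to_numpy()
            y = b.loc[common_regions, common_genes].to_numpy()
            ok = ~(np.isnan(x).any(axis=0) | np.isnan(y).any(axis=0))
            r = _columnwise_pearson(x[:, ok], y[:, ok])
            sums[common_genes[ok]] += r
            counts[common_genes[ok]] += 1
    valid = counts > 0
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info(
            "differential stability undefined for %d gene(s)", n_dropped
        )
    ds = sums[valid] / counts[valid]
    ds.name = "differential_stability"
    return ds


def _columnwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (xc * yc).sum(axis=0)
    den = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def select_stable_genes(
    ds: pd.Series,
    top_fraction: float | None = 0.05,
    cutoff: float | None = None,
    tail: str = "top",
) -> list[str]:
    """Genes passing the differential-stability filter.

    Fraction mode (default): the ``round(top_fraction * n)`` genes with the
    highest stability; ties at the boundary are broken lexicographically by
    gene id so the count is exact.  ``tail="bottom"`` returns the low-
    stability complement tail of the same size (negative control).
    Absolute mode (``cutoff``): genes with stability strictly greater than
    the cutoff (the convention behind "greater than 0.357").
    """
    if ds.empty:
        raise ValueError("stability vector is empty")
    if cutoff is not None:
        chosen = ds.index[ds > cutoff]
        out = sorted(chosen)
    else:
        if top_fraction is None or not 0.0 < top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        n = int(np.floor(top_fraction * len(ds) + 0.5))
        ascending = tail == "bottom"
        order = sorted(
            ds.items(), key=lambda kv: ((kv[1], kv[0]) if ascending else (-kv[1], kv[0]))
        )
        out = [g for g, _ in order[:n]]
    if len(out) < 2:
        raise ValueError(
            f"stability filter keeps {len(out)} gene(s); at least 2 are "
            "needed to define similarity"
        )
    return out


def expression_similarity(
    rem: pd.DataFrame, gene_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation of regional expression profiles between regions.

    ``rem`` is the regions-by-genes expression matrix; the correlation is
    taken across ``gene_subset`` (all genes if omitted).  Symmetric with a
    unit diagonal.
    """
    x = rem if gene_subset is None else rem.loc[:, list(gene_subset)]
    if x.shape[1] < 2:
        raise ValueError("similarity needs at least 2 genes")
    vals = x.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [str(x.index[i]) for i in flat]
        raise ValueError(
            f"region(s) {names} have zero-variance expression profiles over "
            "the selected genes"
        )
    sim = np.corrcoef(vals)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=x.index, columns=x.index)
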