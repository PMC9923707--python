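"""Define a network's region set from activation evidence and an atlas.

Implements the overlap-threshold rule (a region joins the network when a
strict majority fraction of its voxels carries suprathreshold evidence) and
the exclusion rules applied before any matrix is built: regions that are
too small (< 150 voxels by default), regions with too few expression
sampling sites (< 2 summed across donors), and an explicit drop list for
anatomically excluded structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import Atlas

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSet",
    "voxel_consistency_map",
    "binarize_probability_map",
    "select_regions",
    "apply_region_exclusions",
]


@dataclass(frozen=True)
class RegionSet:
    """Ordered set of atlas regions defining one network.

    ``region_ids`` is kept in ascending order so that every matrix built
    over the set (connectivity, similarity, distances) shares one row
    ordering across pipeline stages.
    """

    network_name: str
    region_ids: tuple[int, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(sorted(set(self.region_ids)))
        if len(ids) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        object.__setattr__(self, "region_ids", ids)

    def __len__(self) -> int:
        return len(self.region_ids)


def voxel_consistency_map(
    subject_stat_maps: Sequence[np.ndarray], t_threshold: float
) -> np.ndarray:
    """Fraction of subjects whose statistic exceeds ``t_threshold`` per voxel.

    This is the probabilistic-map construction: threshold each subject's
    statistical map (strictly greater), overlap the binarized maps, and
    divide by the number of subjects.
    """
    maps = list(subject_stat_maps)
    if not maps:
        raise ValueError("at least one subject statistical map is required")
    shape = maps[0].shape
    for i, m in enumerate(maps):
        if m.shape != shape:
            raise ValueError(
                f"map {i} has shape {m.shape}, expected {shape}"
            )
    stacked = np.stack(maps)
    return (stacked > t_threshold).mean(axis=0)


def binarize_probability_map(
    prob_map: np.ndarray, threshold: float = 0.5, inclusive: bool = True
) -> np.ndarray:
    """Binarize a consistency/probability map at ``threshold``.

    Inclusive (>=) by default: the threshold names the cut identifying
    voxels, not an exclusion. Set ``inclusive=False`` for a strict cut.
    """
    if inclusive:
        return prob_map >= threshold
    return prob_map > threshold


def select_regions(
    evidence_mask: np.ndarray,
    atlas: Atlas,
    overlap_fraction: float,
    network_name: str = "network",
) -> RegionSet:
    """Regions whose voxels overlap the evidence mask by a strict majority.

    A region is included iff
    (suprathreshold voxels in region) / (region voxels) > overlap_fraction;
    the inequality is strict ("more than half"), applied uniformly to any
    fraction (1/4, 1/2, 3/4).  Per-region fractions are recorded in
    ``provenance``.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    if evidence_mask.shape != atlas.labels.shape:
        raise ValueError(
            f"mask shape {evidence_mask.shape} != atlas shape {atlas.labels.shape}"
        )
    if atlas.metadata.empty:
        raise ValueError("atlas has no regions")
    mask = evidence_mask.astype(bool)
    fractions: dict[int, float] = {}
    selected: list[int] = []
    for region_id in atlas.region_ids:
        in_region = atlas.labels == region_id
        n_vox = int(in_region.sum())
        frac = float(mask[in_region].sum()) / n_vox if n_vox else 0.0
        fractions[int(region_id)] = frac
        if frac > overlap_fraction:
            selected.append(int(region_id))
    return RegionSet(
        network_name=network_name,
        region_ids=tuple(selected),
        provenance={
            "rule": f"overlap_fraction > {overlap_fraction}",
            "fractions": fractions,
        },
    )


def apply_region_exclusions(
    rs: RegionSet,
    atlas: Atlas,
    site_table: pd.DataFrame | None = None,
    min_voxels: int = 150,
    min_sites: int = 2,
    drop_list: Iterable[int] = (),
) -> RegionSet:
    """Drop regions that are too small, under-sampled, or explicitly listed.

    ``min_voxels`` removes regions with voxel count strictly below it
    (default 150); ``min_sites`` removes regions whose expression sampling
    sites, summed across donors, number strictly fewer than it (default 2).
    ``drop_list`` holds ids excluded a priori (e.g. subcortical or deep
    structures).  Each removal is logged with its reason.  The operation is
    idempotent.
    """
    if min_voxels < 1 or min_sites < 1:
        raise ValueError("min_voxels and min_sites must be >= 1")
    voxel_counts = atlas.metadata.set_index("region_id")["n_voxels"]
    if site_table is not None and "region_id" in site_table.columns:
        site_counts = (
            site_table[["donor_id", "site_id", "region_id"]]
            .drop_duplicates()
            .groupby("region_id")
            .size()
        )
    else:
        site_counts = None
    dropped: dict[int, str] = dict(rs.provenance.get("excluded", {}))
    drop_set = set(int(i) for i in drop_list)
    kept: list[int] = []
    for region_id in rs.region_ids:
        if region_id in drop_set:
            reason = "listed in drop_list"
        elif int(voxel_counts.get(region_id, 0)) < min_voxels:
            reason = (
                f"{int(voxel_counts.get(region_id, 0))} voxels < {min_voxels}"
            )
        elif site_counts is not None and int(site_counts.get(region_id, 0)) < min_sites:
            reason = (
                f"{int(site_counts.get(region_id, 0))} sampling sites < {min_sites}"
            )
        else:
            kept.append(region_id)
            continue
        dropped[region_id] = reason
        logger.info("excluding region %d: %s", region_id, reason)
    if not kept:
        logger.warning("all regions excluded from %s", rs.network_name)
    provenance = dict(rs.provenance)
    provenance["excluded"] = dropped
    return RegionSet(
        network_name=rs.network_name,
        region_ids=tuple(kept),
        provenance=provenance,
    )
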