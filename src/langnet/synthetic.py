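"""Synthetic coupled expression/connectivity data with planted ground truth.

The generator emulates the statistical structure that the analysis pipeline
assumes in real data:

* a labeled atlas volume whose regions are contiguous voxel blocks with
  MNI-like millimetre coordinates;
* a multi-donor, site-sampled expression table with a controllable
  inter-donor differential-stability spectrum and a large gene-level
  baseline (so that, as in postmortem microarray data, all regional
  expression profiles correlate highly with each other);
* a planted subset of "driver" genes whose regional expression similarity
  is coupled — with tunable strength — to the latent covariance that also
  generates the resting-state time series;
* an optional spatial-distance confound that enters both the connectivity
  and the expression side, giving the distance-partialling stage something
  real to remove.

A latent K-factor model ties the two data modalities together: region
loadings define the ground-truth connectivity covariance, and driver genes'
regional expectation profiles are random directions in the same factor
space.  Non-driver genes carry independent regional profiles.  All
randomness flows from one master seed through named spawned substreams, so
every artifact is reproducible independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "SynthGroundTruth",
    "Atlas",
    "SynthDataset",
    "generate_atlas",
    "make_ground_truth",
    "generate_expression_sites",
    "generate_timeseries",
    "generate_dataset",
]

_VOXEL_MM = 2.0  # isotropic voxel size of the synthetic label volume
_BLOCK_SIDE = 6  # 6**3 = 216 voxels per region block (>150 by default)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real study's conditions at desk scale: 6 donors
    (as in the Allen Human Brain Atlas), two independent resting-state
    cohorts of 30 subjects with 240 volumes each, and a driver-gene
    coupling strength of 0.8.
    """

    n_regions: int = 20
    n_genes: int = 200
    n_driver_genes: int = 20
    n_donors: int = 6
    sites_per_region_range: tuple[int, int] = (2, 5)
    n_subjects: int = 30
    n_cohorts: int = 2
    n_timepoints: int = 240
    coupling_strength: float = 0.8
    stability_high: float = 0.9
    stability_low: float = 0.05
    distance_confound_weight: float = 0.0
    region_extent_mm: float = 40.0
    seed: int = 0
    # secondary knobs, rarely moved
    n_factors: int = 3
    probes_per_gene: int = 1
    gene_baseline_sd: float = 5.0
    site_noise_sd: float = 0.2
    probe_noise_sd: float = 0.1
    subject_noise_sd: float = 0.5
    stability_spectrum: str = "uniform"
    undersized_regions: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError(
                f"coupling_strength must be in [0, 1], got {self.coupling_strength}"
            )
        if self.n_driver_genes > self.n_genes:
            raise ValueError("n_driver_genes must not exceed n_genes")
        if self.n_regions < 2:
            raise ValueError("n_regions must be at least 2")
        if self.n_donors < 2:
            raise ValueError("n_donors must be at least 2")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be at least 10")
        lo, hi = self.sites_per_region_range
        if lo < 2 or hi < lo:
            raise ValueError("sites_per_region_range must satisfy 2 <= min <= max")

    def substream(self, name: str) -> np.random.Generator:
        """Deterministic named RNG substream derived from the master seed."""
        h = np.frombuffer(name.encode(), dtype=np.uint8)
        child = np.random.SeedSequence([self.seed, *h.tolist()])
        return np.random.default_rng(child)


@dataclass(frozen=True)
class SynthGroundTruth:
    """Planted structure: what a successful analysis should recover."""

    driver_gene_ids: tuple[str, ...]
    true_connectivity: np.ndarray  # region x region latent correlation Sigma
    region_centers: pd.DataFrame  # region_id -> (x_mm, y_mm, z_mm)
    per_gene_stability_target: pd.Series  # gene_id -> target in (0, 1)
    gene_ids: tuple[str, ...] = ()
    region_profiles: pd.DataFrame | None = None  # genes x regions mean profiles

    def to_json(self) -> str:
        payload = {
            "driver_gene_ids": list(self.driver_gene_ids),
            "true_connectivity": self.true_connectivity.tolist(),
            "region_centers": self.region_centers.to_dict(orient="index"),
            "per_gene_stability_target": self.per_gene_stability_target.to_dict(),
        }
        return json.dumps(payload, indent=1)


@dataclass(frozen=True)
class Atlas:
    """Integer label volume plus region metadata.

    ``labels`` uses 0 for background and 1..n for regions; ``affine`` maps
    voxel indices to MNI-like millimetre coordinates.  ``metadata`` has one
    row per region: region_id, name, hemisphere, x_mm, y_mm, z_mm, n_voxels.
    """

    labels: np.ndarray
    affine: np.ndarray
    metadata: pd.DataFrame

    @property
    def region_ids(self) -> np.ndarray:
        return self.metadata["region_id"].to_numpy()

    def voxel_centers_mm(self, region_id: int) -> np.ndarray:
        ijk = np.argwhere(self.labels == region_id)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class SynthDataset:
    """Bundle of all generated artifacts for one master seed."""

    config: SynthConfig
    atlas: Atlas
    truth: SynthGroundTruth
    sites: pd.DataFrame
    cohorts: tuple[tuple[pd.DataFrame, ...], ...]  # cohort -> subject frames


def generate_atlas(config: SynthConfig) -> Atlas:
    """Lay out ``n_regions`` contiguous blocks on a 3D grid.

    Each block is a 6x6x6 voxel cube (216 voxels) unless shrunk through
    ``config.undersized_regions`` (region_id -> voxel count), which exists
    to exercise the downstream minimum-size exclusion rule.

    Raises
    ------
    ValueError
        If the implied grid cannot host the requested regions.
    """
    n = config.n_regions
    per_side = int(np.ceil(n ** (1.0 / 3.0)))
    if per_side ** 3 < n:
        raise ValueError("internal sizing error: grid too small for regions")
    shape = (per_side * _BLOCK_SIDE,) * 3
    labels = np.zeros(shape, dtype=np.int32)

    slots = [
        (i, j, k)
        for i in range(per_side)
        for j in range(per_side)
        for k in range(per_side)
    ][:n]
    for region_id, (i, j, k) in enumerate(slots, start=1):
        sl = tuple(
            slice(a * _BLOCK_SIDE, (a + 1) * _BLOCK_SIDE) for a in (i, j, k)
        )
        block = np.full((_BLOCK_SIDE,) * 3, region_id, dtype=np.int32)
        target = config.undersized_regions.get(region_id)
        if target is not None:
            flat = block.reshape(-1)
            if target > flat.size:
                raise ValueError(
                    f"undersized_regions[{region_id}]={target} exceeds block size"
                )
            flat[target:] = 0
            block = flat.reshape(block.shape)
        labels[sl] = block

    # MNI-like affine: 2 mm voxels, volume roughly centred on the origin
    affine = np.diag([_VOXEL_MM, _VOXEL_MM, _VOXEL_MM, 1.0])
    affine[:3, 3] = -_VOXEL_MM * (np.asarray(shape) - 1) / 2.0

    rows = []
    for region_id in range(1, n + 1):
        ijk = np.argwhere(labels == region_id)
        center = ijk.mean(axis=0) @ affine[:3, :3].T + affine[:3, 3]
        rows.append(
            {
                "region_id": region_id,
                "name": f"R{region_id:03d}",
                "hemisphere": "L" if center[0] <= 0 else "R",
                "x_mm": center[0],
                "y_mm": center[1],
                "z_mm": center[2],
                "n_voxels": int(ijk.shape[0]),
            }
        )
    metadata = pd.DataFrame(rows)
    return Atlas(labels=labels, affine=affine, metadata=metadata)


def _distance_kernel(centers: np.ndarray, length_scale: float) -> np.ndarray:
    """Exponential-decay spatial correlation kernel (positive definite)."""
    from scipy.spatial.distance import cdist

    d = cdist(centers, centers)
    return np.exp(-d / length_scale)


def make_ground_truth(config: SynthConfig, atlas: Atlas) -> SynthGroundTruth:
    """Plant the latent structure shared by both data modalities.

    The ground-truth connectivity is built from the K-factor region
    loadings (inner products with a diagonal ridge, normalized to unit
    diagonal), optionally mixed with an exponential spatial kernel whose
    share is ``w / (1 + w)`` with ``w = distance_confound_weight``.
    Driver genes' regional mean profiles put a ``coupling_strength``
    fraction of their variance on random directions in the same factor
    space (plus the same spatial field), so "similar expression implies
    stronger connectivity" is literally true for drivers at positive
    coupling, and expression is unrelated to connectivity at zero.
    """
    rng = config.substream("truth")
    n = config.n_regions
    centers = atlas.metadata[["x_mm", "y_mm", "z_mm"]].to_numpy()

    loadings = rng.standard_normal((n, config.n_factors))
    sig = loadings @ loadings.T / config.n_factors + 0.3 * np.eye(n)
    d = np.sqrt(np.diag(sig))
    base = sig / np.outer(d, d)

    c = config.coupling_strength
    w = config.distance_confound_weight
    if w < 0:
        raise ValueError("distance_confound_weight must be >= 0")
    if w > 0:
        kernel = _distance_kernel(centers, config.region_extent_mm)
        sigma = (base + w * kernel) / (1.0 + w)
    else:
        sigma = base
    np.fill_diagonal(sigma, 1.0)

    gene_ids = tuple(f"G{i:04d}" for i in range(1, config.n_genes + 1))
    drivers = tuple(gene_ids[: config.n_driver_genes])

    targets = np.empty(config.n_genes)
    targets[: config.n_driver_genes] = config.stability_high
    n_rest = config.n_genes - config.n_driver_genes
    if config.stability_spectrum == "uniform":
        targets[config.n_driver_genes:] = rng.uniform(
            config.stability_low, config.stability_high, size=n_rest
        )
    elif config.stability_spectrum == "two_level":
        targets[config.n_driver_genes:] = config.stability_low
    else:
        raise ValueError(
            f"unknown stability_spectrum {config.stability_spectrum!r}"
        )
    target_series = pd.Series(targets, index=list(gene_ids), name="stability_target")

    # regional mean profiles (genes x regions), standardized per gene
    s_spatial = w / (1.0 + w)
    if s_spatial > 0:
        chol_kernel = np.linalg.cholesky(
            _distance_kernel(centers, config.region_extent_mm) + 1e-9 * np.eye(n)
        )
        eta = rng.standard_normal((config.n_genes, n)) @ chol_kernel.T
        eta = _standardize_rows(eta)
    else:
        eta = np.zeros((config.n_genes, n))
    eps = _standardize_rows(rng.standard_normal((config.n_genes, n)))

    betas = rng.standard_normal((config.n_driver_genes, config.n_factors))
    fac = _standardize_rows(betas @ loadings.T)

    a2 = np.zeros(config.n_genes)
    a2[: config.n_driver_genes] = c * (1.0 - s_spatial)
    b2 = np.full(config.n_genes, s_spatial)
    d2 = 1.0 - a2 - b2

    profiles = (
        np.sqrt(b2)[:, None] * eta + np.sqrt(d2)[:, None] * eps
    )
    profiles[: config.n_driver_genes] += (
        np.sqrt(a2[: config.n_driver_genes])[:, None] * fac
    )
    profiles = _standardize_rows(profiles)
    profile_df = pd.DataFrame(
        profiles, index=list(gene_ids), columns=atlas.region_ids
    )

    center_df = atlas.metadata.set_index("region_id")[["x_mm", "y_mm", "z_mm"]]
    return SynthGroundTruth(
        driver_gene_ids=drivers,
        true_connectivity=sigma,
        region_centers=center_df,
        per_gene_stability_target=target_series,
        gene_ids=gene_ids,
        region_profiles=profile_df,
    )


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def generate_expression_sites(
    config: SynthConfig,
    truth: SynthGroundTruth,
    atlas: Atlas | None = None,
) -> pd.DataFrame:
    """Draw the donor-tagged expression site table.

    Each donor samples 2-5 sites per region (``sites_per_region_range``);
    a site's value for gene g is

        baseline_g + tau * profile_g[region] + donor effect + site noise,

    where the donor-by-region effect variance is solved analytically from
    the gene's stability target (see :func:`_donor_noise_sd`) so realized
    differential stability concentrates near that target.  The gene
    baseline has a large spread across genes, which is what makes all
    pairwise regional similarity values high, as in real cortical
    microarray data.

    Returns a long-format frame with columns donor_id, site_id, x_mm, y_mm,
    z_mm, region_id, probe_id, gene_id, value.  ``region_id`` records the
    generative assignment; the pipeline re-derives it from coordinates.
    """
    rng = config.substream("expression")
    n_genes, n_regions = config.n_genes, config.n_regions
    gene_ids = np.asarray(truth.gene_ids)
    assert truth.region_profiles is not None
    profiles = truth.region_profiles.to_numpy()  # genes x regions
    region_ids = truth.region_profiles.columns.to_numpy()

    baseline = rng.normal(0.0, config.gene_baseline_sd, size=n_genes)
    lo, hi = config.sites_per_region_range
    mean_sites = (lo + hi) / 2.0
    donor_sd = _donor_noise_sd(
        truth.per_gene_stability_target.to_numpy(),
        config.site_noise_sd,
        mean_sites,
    )

    # donor-by-gene-by-region effects, shared by all of a donor's sites in
    # the region
    donor_eff = (
        rng.standard_normal((config.n_donors, n_genes, n_regions))
        * donor_sd[None, :, None]
    )

    frames = []
    for d in range(config.n_donors):
        donor_id = f"D{d + 1:02d}"
        for r_idx, region_id in enumerate(region_ids):
            n_sites = int(rng.integers(lo, hi + 1))
            if atlas is not None:
                vox = atlas.voxel_centers_mm(int(region_id))
                pick = rng.choice(vox.shape[0], size=n_sites, replace=False)
                coords = vox[pick]
            else:
                center = truth.region_centers.loc[int(region_id)].to_numpy()
                coords = center[None, :] + rng.normal(0, 2.0, size=(n_sites, 3))
            site_mean = (
                baseline + profiles[:, r_idx] + donor_eff[d, :, r_idx]
            )
            vals = site_mean[None, :] + rng.normal(
                0.0, config.site_noise_sd, size=(n_sites, n_genes)
            )
            for s in range(n_sites):
                frames.append(
                    _site_rows(
                        donor_id,
                        f"{donor_id}_R{region_id}_S{s + 1}",
                        coords[s],
                        int(region_id),
                        gene_ids,
                        vals[s],
                        config,
                        rng,
                    )
                )
    return pd.concat(frames, ignore_index=True)


def _site_rows(
    donor_id: str,
    site_id: str,
    xyz: np.ndarray,
    region_id: int,
    gene_ids: np.ndarray,
    values: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    p = config.probes_per_gene
    if p > 1:
        gene_col = np.repeat(gene_ids, p)
        probe_col = np.array(
            [f"{g}_p{i + 1}" for g in gene_ids for i in range(p)]
        )
        value_col = np.repeat(values, p) + rng.normal(
            0.0, config.probe_noise_sd, size=values.size * p
        )
    else:
        gene_col = gene_ids
        probe_col = np.array([f"{g}_p1" for g in gene_ids])
        value_col = values
    return pd.DataFrame(
        {
            "donor_id": donor_id,
            "site_id": site_id,
            "x_mm": xyz[0],
            "y_mm": xyz[1],
            "z_mm": xyz[2],
            "region_id": region_id,
            "probe_id": probe_col,
            "gene_id": gene_col,
            "value": value_col,
        }
    )


def _donor_noise_sd(
    target: np.ndarray, site_noise_sd: float, mean_sites: float
) -> np.ndarray:
    """Solve the donor-effect SD from the target inter-donor correlation.

    With unit-variance regional profiles, the expected correlation between
    two donors' regional means of a gene is
    1 / (1 + sd^2 + site_var / n_sites); inverting gives the donor-effect
    variance.  Targets at or below zero are clamped to a small positive
    value (this additive model cannot produce negative stability).
    """
    t = np.clip(target, 0.01, 0.995)
    var = 1.0 / t - 1.0 - site_noise_sd**2 / mean_sites
    return np.sqrt(np.clip(var, 1e-4, None))


def generate_timeseries(
    config: SynthConfig, truth: SynthGroundTruth
) -> tuple[tuple[pd.DataFrame, ...], ...]:
    """Simulate ``n_cohorts`` independent resting-state cohorts.

    Each subject's regions-by-timepoints array is drawn i.i.d. in time from
    N(0, Sigma) with Sigma = ``truth.true_connectivity``, plus white
    subject noise of SD ``subject_noise_sd`` (which attenuates all observed
    correlations uniformly and leaves their ranking intact).

    Raises
    ------
    ValueError
        If the ground-truth covariance is not positive semi-definite.
    """
    sigma = truth.true_connectivity
    try:
        chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(sigma.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "true_connectivity is not positive semi-definite; cannot draw "
            "time series from it"
        ) from exc

    region_index = truth.region_centers.index
    cohorts = []
    for c in range(config.n_cohorts):
        rng = config.substream(f"cohort{c}")
        subjects = []
        for s in range(config.n_subjects):
            z = rng.standard_normal((sigma.shape[0], config.n_timepoints))
            x = chol @ z + config.subject_noise_sd * rng.standard_normal(z.shape)
            subjects.append(
                pd.DataFrame(
                    x,
                    index=region_index,
                    columns=[f"t{t}" for t in range(config.n_timepoints)],
                )
            )
        cohorts.append(tuple(subjects))
    return tuple(cohorts)


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate the full bundle: atlas, ground truth, sites, cohorts."""
    atlas = generate_atlas(config)
    truth = make_ground_truth(config, atlas)
    sites = generate_expression_sites(config, truth, atlas)
    cohorts = generate_timeseries(config, truth)
    return SynthDataset(
        config=config, atlas=atlas, truth=truth, sites=sites, cohorts=cohorts
    )


def write_dataset(ds: SynthDataset, out_dir) -> None:
    """Write all artifacts as plain-text files plus a NIfTI label volume."""
    import pathlib

    import nibabel as nib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(ds.atlas.labels.astype(np.int16), ds.atlas.affine),
        out / "atlas.nii.gz",
    )
    ds.atlas.metadata.to_csv(out / "regions.csv", index=False)
    ds.sites.to_csv(out / "expression_sites.csv", index=False)
    (out / "ground_truth.json").write_text(ds.truth.to_json())
    for c, cohort in enumerate(ds.cohorts):
        cdir = out / f"cohort{c + 1}"
        cdir.mkdir(exist_ok=True)
        for s, frame in enumerate(cohort):
            frame.to_csv(cdir / f"subject{s + 1:03d}.csv")
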