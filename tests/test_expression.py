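"""Expression aggregation, differential stability, and similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from langnet import (
    RegionSet,
    SynthConfig,
    assign_sites_to_regions,
    build_region_expression,
    collapse_probes,
    differential_stability,
    expression_similarity,
    generate_atlas,
    select_stable_genes,
)


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=["donor_id", "site_id", "x_mm", "y_mm", "z_mm", "probe_id",
                 "gene_id", "value"],
    )


class TestCollapseProbes:
    def test_mean_over_probes(self):
        t = _table([
            ("D1", "s1", 0, 0, 0, "p1", "g", 2.0),
            ("D1", "s1", 0, 0, 0, "p2", "g", 4.0),
            ("D1", "s1", 0, 0, 0, "q1", "h", 7.0),
        ])
        out = collapse_probes(t)
        assert out.set_index("gene_id")["value"].to_dict() == {"g": 3.0, "h": 7.0}

    def test_probe_map_and_unmapped_dropped_with_warning(self):
        t = _table([
            ("D1", "s1", 0, 0, 0, "p1", None, 2.0),
            ("D1", "s1", 0, 0, 0, "p2", None, 4.0),
            ("D1", "s1", 0, 0, 0, "orphan", None, 9.0),
        ])
        with pytest.warns(UserWarning, match="1 probe"):
            out = collapse_probes(t, probe_map={"p1": "g", "p2": "g"})
        assert len(out) == 1
        assert out["value"].iloc[0] == 3.0


@pytest.fixture(scope="module")
def site_atlas():
    return generate_atlas(SynthConfig(n_regions=8, seed=4))


class TestSiteAssignment:

    def _sites_at(self, coords):
        return pd.DataFrame(
            [
                {"donor_id": "D1", "site_id": f"s{i}", "x_mm": x, "y_mm": y,
                 "z_mm": z, "gene_id": "g", "value": 1.0}
                for i, (x, y, z) in enumerate(coords)
            ]
        )

    def test_site_inside_region(self, site_atlas):
        center = site_atlas.voxel_centers_mm(1)[0]
        out = assign_sites_to_regions(self._sites_at([center]), site_atlas)
        assert out["region_id"].tolist() == [1]

    def test_site_just_outside_snaps_to_nearest(self, site_atlas):
        edge = site_atlas.voxel_centers_mm(1).min(axis=0) - 1.0  # 1 mm outside
        out = assign_sites_to_regions(
            self._sites_at([edge]), site_atlas, snap_radius_mm=2.0
        )
        assert out["region_id"].tolist() == [1]

    def test_site_far_outside_stays_unassigned(self, site_atlas):
        far = site_atlas.voxel_centers_mm(1).min(axis=0) - 10.0
        out = assign_sites_to_regions(
            self._sites_at([far]), site_atlas, snap_radius_mm=2.0
        )
        assert out["region_id"].isna().all()


class TestRegionExpression:
    def _gene_table(self, spec):
        # spec: list of (donor, site, region, value) for one gene
        return pd.DataFrame(
            [
                {"donor_id": d, "site_id": s, "region_id": r, "gene_id": "g",
                 "value": v}
                for d, s, r, v in spec
            ]
        )

    def test_single_donor_mean(self):
        t = self._gene_table([
            ("A", "s1", 1, 1.0), ("A", "s2", 1, 2.0), ("A", "s3", 1, 3.0),
            ("A", "s4", 2, 0.0),
        ])
        pooled, _ = build_region_expression(t, RegionSet("n", (1, 2)))
        assert pooled.loc[1, "g"] == 2.0

    def test_pooled_vs_donor_first(self):
        t = self._gene_table([
            ("A", "s1", 1, 1.0), ("A", "s2", 1, 3.0), ("B", "s3", 1, 5.0),
            ("A", "s4", 2, 0.0), ("B", "s5", 2, 0.0),
        ])
        rs = RegionSet("n", (1, 2))
        pooled, _ = build_region_expression(t, rs, mode="pooled")
        donor_first, _ = build_region_expression(t, rs, mode="donor_first")
        assert pooled.loc[1, "g"] == 3.0  # (1+3+5)/3
        assert donor_first.loc[1, "g"] == 3.5  # ((1+3)/2 + 5)/2

    def test_identical_donors_make_modes_agree(self):
        t = self._gene_table([
            ("A", "s1", 1, 2.0), ("B", "s2", 1, 2.0),
            ("A", "s3", 2, 4.0), ("B", "s4", 2, 4.0),
        ])
        rs = RegionSet("n", (1, 2))
        pooled, _ = build_region_expression(t, rs, "pooled")
        donor_first, _ = build_region_expression(t, rs, "donor_first")
        pd.testing.assert_frame_equal(pooled, donor_first)

    def test_region_without_sites_is_an_error(self):
        t = self._gene_table([("A", "s1", 1, 1.0)])
        with pytest.raises(ValueError, match="no assigned sampling sites"):
            build_region_expression(t, RegionSet("n", (1, 2)))


def _donor_matrix(profile, genes=("g",)):
    return pd.DataFrame(
        {g: profile for g in genes}, index=range(1, len(profile) + 1)
    )


class TestDifferentialStability:
    def test_identical_profiles_score_one(self):
        a = _donor_matrix([1.0, 2.0, 3.0, 4.0])
        ds = differential_stability({"A": a, "B": a.copy()})
        assert ds["g"] == pytest.approx(1.0)

    def test_mirrored_profile_scores_minus_one(self):
        prof = np.array([1.0, 2.0, 5.0, 4.0])
        mirrored = -(prof - prof.mean()) + prof.mean()
        ds = differential_stability(
            {"A": _donor_matrix(prof), "B": _donor_matrix(mirrored)}
        )
        assert ds["g"] == pytest.approx(-1.0)

    def test_mean_over_donor_pairs(self, rng):
        mats = {d: _donor_matrix(rng.standard_normal(6)) for d in "ABC"}
        expected = np.mean(
            [
                np.corrcoef(mats[a]["g"], mats[b]["g"])[0, 1]
                for a, b in (("A", "B"), ("A", "C"), ("B", "C"))
            ]
        )
        ds = differential_stability(mats)
        assert ds["g"] == pytest.approx(expected)

    def test_fewer_than_two_donors_rejected(self):
        with pytest.raises(ValueError, match="two donors"):
            differential_stability({"A": _donor_matrix([1, 2, 3])})

    def test_added_noise_monotonically_degrades_stability(self, rng):
        base = rng.standard_normal((10, 25))
        means = []
        for noise_sd in (0.1, 1.0, 4.0):
            mats = {
                d: pd.DataFrame(
                    base + noise_sd * rng.standard_normal(base.shape),
                    index=range(10),
                    columns=[f"g{j}" for j in range(25)],
                )
                for d in "ABCD"
            }
            means.append(differential_stability(mats).mean())
        assert means[0] > means[1] > means[2]


class TestSelectStableGenes:
    def test_top_fraction_exact_count(self, rng):
        ds = pd.Series(rng.random(100), index=[f"g{i:03d}" for i in range(100)])
        top = select_stable_genes(ds, top_fraction=0.05)
        assert len(top) == 5
        assert set(top) == set(ds.nlargest(5).index)

    def test_boundary_ties_break_by_gene_id(self):
        ds = pd.Series([0.9, 0.5, 0.5, 0.5, 0.1, 0.0],
                       index=["a", "d", "b", "c", "e", "f"])
        assert select_stable_genes(ds, top_fraction=0.5) == ["a", "b", "c"]

    def test_bottom_tail_negative_control(self):
        ds = pd.Series([0.9, 0.7, 0.5, 0.3, 0.1, 0.0],
                       index=list("abcdef"))
        assert set(select_stable_genes(ds, 1 / 3, tail="bottom")) == {"e", "f"}

    def test_absolute_cutoff_mode(self):
        ds = pd.Series([0.9, 0.5, 0.357, 0.36, 0.1],
                       index=list("abcde"))
        assert select_stable_genes(ds, cutoff=0.357) == ["a", "b", "d"]

    def test_too_few_survivors_rejected(self):
        ds = pd.Series([0.5, 0.4, 0.3], index=list("abc"))
        with pytest.raises(ValueError, match="at least 2"):
            select_stable_genes(ds, cutoff=0.45)


class TestExpressionSimilarity:
    def test_identical_and_reversed_profiles(self):
        rem = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
            index=[1, 2, 3], columns=["a", "b", "c"],
        )
        sim = expression_similarity(rem)
        assert sim.loc[1, 2] == pytest.approx(1.0)
        assert sim.loc[1, 3] == pytest.approx(-1.0)
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)

    def test_zero_variance_region_named(self):
        rem = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"],
            columns=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="flat"):
            expression_similarity(rem)

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(0.01, 100.0), shift=st.floats(-50.0, 50.0))
    def test_affine_rescaling_of_a_region_profile_is_invariant(self, scale, shift):
        rng = np.random.default_rng(8)
        rem = pd.DataFrame(
            rng.standard_normal((4, 12)), index=[1, 2, 3, 4],
            columns=[f"g{j}" for j in range(12)],
        )
        sim = expression_similarity(rem)
        rem2 = rem.copy()
        rem2.loc[2] = scale * rem2.loc[2] + shift
        sim2 = expression_similarity(rem2)
        assert np.allclose(sim, sim2, atol=1e-9)

    def test_generator_default_yields_high_regional_similarity(self):
        """The shared gene-level baseline makes every regional pair highly
        correlated over the full default-scale gene panel, as in cortical
        microarray data."""
        from langnet import generate_dataset

        ds = generate_dataset(SynthConfig(seed=0, n_cohorts=0))
        gene_level = collapse_probes(ds.sites)
        rs = RegionSet("all", tuple(ds.atlas.region_ids))
        pooled, _ = build_region_expression(gene_level, rs)
        sim = expression_similarity(pooled)
        off = sim.to_numpy()[np.triu_indices(len(sim), 1)]
        assert off.min() > 0.9
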