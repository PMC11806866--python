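"""Generators: planted structure, prescribed correlations, determinism."""

import numpy as np
import pandas as pd
import pytest

from plscortex import (
    make_cohort,
    make_expression,
    make_pathology_sets,
    make_receptor_atlas,
)
from plscortex.signature import region_columns


class TestMakeExpression:
    def test_full_scale_dimensions(self):
        x, truth = make_expression(n_regions=100, n_genes=15633, n_planted=200, seed=1)
        assert x.shape == (100, 15633)
        assert len(truth.planted_gene_ids) == 200

    def test_noiseless_rank_equals_n_latent(self):
        for n_latent in (1, 3):
            x, _ = make_expression(30, 80, n_latent=n_latent, noise_sd=0.0, seed=2)
            sv = np.linalg.svd(x.to_numpy(), compute_uv=False)
            assert sv[n_latent] <= 1e-10 * sv[0]

    def test_planted_genes_track_factor_one(self):
        x, truth = make_expression(50, 500, n_planted=50, seed=7)
        f1 = truth.spatial_factors["factor_1"].to_numpy()
        corr = {
            g: abs(np.corrcoef(x[g], f1)[0, 1]) for g in x.columns
        }
        planted = set(truth.planted_gene_ids)
        mean_planted = np.mean([corr[g] for g in planted])
        mean_other = np.mean([c for g, c in corr.items() if g not in planted])
        assert mean_planted > mean_other

    def test_deterministic_given_seed(self):
        a, ta = make_expression(20, 50, seed=5)
        b, tb = make_expression(20, 50, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert ta.planted_gene_ids == tb.planted_gene_ids

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_regions": 0, "n_genes": 10},
            {"n_regions": 10, "n_genes": -1},
            {"n_regions": 10, "n_genes": 10, "n_latent": 0},
            {"n_regions": 2, "n_genes": 10, "n_latent": 3},
            {"n_regions": 10, "n_genes": 10, "n_planted": 11},
            {"n_regions": 10, "n_genes": 10, "noise_sd": -0.1},
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            make_expression(**kwargs)


class TestMakeCohort:
    def test_paper_scale_control_arm(self):
        coh = make_cohort(n_controls=172, n_sporadic=10, n_genetic=10,
                          n_regions=10, effect=0.0, seed=0)
        assert (coh["group"] == "control").sum() == 172
        assert coh["duration"].isna().sum() == 172
        assert (coh.loc[coh.group != "control", "duration"] >= 0).all()

    def test_group_difference_tracks_effect_times_map(self):
        rng = np.random.default_rng(0)
        amap = pd.Series(rng.normal(size=40),
                         index=[f"LH_region_{i + 1:03d}" for i in range(40)])
        coh = make_cohort(n_controls=10, n_sporadic=300, n_genetic=300,
                          atrophy_map=amap, effect=1.5, seed=11)
        regions = region_columns(coh)
        gm = coh[coh.group == "genetic"][regions].mean()
        sm = coh[coh.group == "sporadic"][regions].mean()
        diff = (gm - sm).to_numpy()
        amap_z = (amap - amap.mean()) / amap.std()
        # planted shift: effect * resid_sd(=0.1) * z(map); sporadic adds an
        # independent small map, so the difference is dominated by the target
        slope = np.polyfit(amap_z.to_numpy(), diff, 1)[0]
        assert np.corrcoef(amap_z, diff)[0, 1] > 0.8
        assert slope == pytest.approx(1.5 * 0.10, rel=0.35)

    def test_zero_effect_groups_exchangeable(self):
        amap = pd.Series(np.linspace(-1, 1, 20),
                         index=[f"LH_region_{i + 1:03d}" for i in range(20)])
        coh = make_cohort(n_controls=10, n_sporadic=200, n_genetic=200,
                          atrophy_map=amap, effect=0.0, seed=3)
        regions = region_columns(coh)
        gm = coh[coh.group == "genetic"][regions].mean()
        sm = coh[coh.group == "sporadic"][regions].mean()
        # group means agree within a few SEs of the per-region noise
        se = 0.10 * np.sqrt(2.0 / 200)
        assert np.abs(gm - sm).max() < 5 * se

    def test_region_count_mismatch(self):
        amap = pd.Series(np.ones(5), index=list("abcde"))
        with pytest.raises(ValueError):
            make_cohort(20, 5, 5, atrophy_map=amap, n_regions=7)


class TestMakeReceptorAtlas:
    @pytest.fixture()
    def amap(self):
        rng = np.random.default_rng(1)
        return pd.Series(rng.normal(size=200),
                         index=[f"LH_region_{i + 1:03d}" for i in range(200)])

    def test_default_receptor_count_and_systems(self, amap):
        atlas, truth = make_receptor_atlas(amap, [0.0] * 15, seed=0)
        assert atlas.densities.shape == (200, 15)
        assert len(set(atlas.systems.values())) == 5
        assert len(truth.receptor_target_correlations) == 15

    def test_sample_correlations_near_targets(self, amap):
        targets = [0.8, -0.5, 0.0]
        atlas, _ = make_receptor_atlas(amap, targets, seed=3)
        for name, target in zip(atlas.receptors, targets):
            r = np.corrcoef(atlas.densities[name], amap)[0, 1]
            assert r == pytest.approx(target, abs=0.15)

    def test_zero_target_independent(self, amap):
        atlas, _ = make_receptor_atlas(amap, [0.0], seed=5)
        r = np.corrcoef(atlas.densities.iloc[:, 0], amap)[0, 1]
        assert abs(r) <= 3 / np.sqrt(len(amap))

    def test_correlation_error_vanishes_with_regions(self):
        rng = np.random.default_rng(2)
        big = pd.Series(rng.normal(size=1000))
        targets = [0.7, -0.6, 0.3, 0.0, -0.2]
        atlas, _ = make_receptor_atlas(big, targets, seed=9)
        devs = [
            abs(np.corrcoef(atlas.densities.iloc[:, j], big)[0, 1] - t)
            for j, t in enumerate(targets)
        ]
        assert np.mean(devs) < 0.05

    def test_rejects_unit_target(self, amap):
        with pytest.raises(ValueError):
            make_receptor_atlas(amap, [1.0], seed=0)


class TestMakePathologySets:
    BACKGROUND = [f"G{i:04d}" for i in range(1000)]
    SIGNATURE = [f"G{i:04d}" for i in range(50)]

    def test_zero_overlap_fraction_disjoint(self):
        s = make_pathology_sets(self.BACKGROUND, self.SIGNATURE, 0.0, 200, seed=1)
        assert len(s) == 200
        assert not (s & set(self.SIGNATURE))

    def test_full_overlap_fraction_contains_signature(self):
        s = make_pathology_sets(self.BACKGROUND, self.SIGNATURE, 1.0, 200, seed=1)
        assert len(s & set(self.SIGNATURE)) == 50

    def test_half_overlap_rounding(self):
        s = make_pathology_sets(self.BACKGROUND, self.SIGNATURE, 0.5, 200, seed=2)
        assert len(s & set(self.SIGNATURE)) == round(0.5 * 50)

    def test_signature_outside_background_rejected(self):
        with pytest.raises(ValueError):
            make_pathology_sets(self.BACKGROUND, ["NOT_THERE"], 0.5, 10, seed=0)

    def test_deterministic(self):
        a = make_pathology_sets(self.BACKGROUND, self.SIGNATURE, 0.3, 100, seed=4)
        b = make_pathology_sets(self.BACKGROUND, self.SIGNATURE, 0.3, 100, seed=4)
        assert a == b
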