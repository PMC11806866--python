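"""PLS1 fit, resampling null, bootstrap gene inference, VIP, gene selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from plscortex import (
    ExpressionMatrix,
    bootstrap_gene_weights,
    compute_vip,
    fit_pls1,
    null_variance_explained,
    select_genes,
)


def _random_instance(seed, n=20, p=10):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return x, y


def _as_matrix(x):
    n, p = x.shape
    df = pd.DataFrame(
        x,
        index=[f"LH_region_{i + 1:03d}" for i in range(n)],
        columns=[f"GENE{j + 1:05d}" for j in range(p)],
    )
    return ExpressionMatrix(values=df)


class TestFitPLS1:
    def test_single_gene_reduces_to_simple_regression(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=30)
        y = 2.0 * g + rng.normal(size=30)
        model = fit_pls1(g[:, None], y)
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        assert model.variance_explained == pytest.approx(100 * r2, abs=1e-10)

    def test_weight_collinear_with_cross_covariance(self):
        x, y = _random_instance(13, n=10, p=5)
        model = fit_pls1(x, y)
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        oracle = xc.T @ yc
        oracle /= np.linalg.norm(oracle)
        cos = abs(model.pls1_weights.to_numpy() @ oracle)
        assert cos >= 1 - 1e-8

    def test_matches_sklearn_first_component(self):
        """Independent cross-check of the weight direction and scores."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        x, y = _random_instance(99, n=25, p=8)
        model = fit_pls1(x, y, k=1)
        sk = sklearn.PLSRegression(n_components=1, scale=False).fit(x, y)
        w_sk = sk.x_weights_[:, 0] / np.linalg.norm(sk.x_weights_[:, 0])
        cos = abs(model.pls1_weights.to_numpy() @ w_sk)
        assert cos >= 1 - 1e-8

    def test_sign_convention_scores_correlate_positively(self):
        for seed in range(10):
            x, y = _random_instance(seed)
            model = fit_pls1(x, y)
            assert np.corrcoef(model.pls1_scores, y)[0, 1] >= 0

    def test_unit_norm_weights_multi_component(self):
        x, y = _random_instance(3, n=30, p=12)
        model = fit_pls1(x, y, k=3)
        norms = np.linalg.norm(model.weights.to_numpy(), axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_full_scale_dimensions_accepted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 15633))
        y = rng.normal(size=100)
        model = fit_pls1(x, y)
        assert model.weights.shape == (15633, 1)

    def test_constant_response_rejected(self):
        x, _ = _random_instance(0)
        with pytest.raises(ValueError, match="constant"):
            fit_pls1(x, np.ones(20))

    @given(seed=st.integers(0, 500), scale=st.floats(0.1, 10.0))
    def test_variance_explained_invariances(self, seed, scale):
        """Invariant under positive rescaling of Y and joint row permutation."""
        x, y = _random_instance(seed, n=15, p=6)
        base = fit_pls1(x, y).variance_explained
        assert fit_pls1(x, scale * y).variance_explained == pytest.approx(
            base, abs=1e-8
        )
        perm = np.random.default_rng(seed).permutation(15)
        assert fit_pls1(x[perm], y[perm]).variance_explained == pytest.approx(
            base, abs=1e-8
        )


class TestNullVarianceExplained:
    def test_pvalue_matches_addone_count_formula(self):
        x, y = _random_instance(4, n=15, p=8)
        nd = null_variance_explained(_as_matrix(x), y, n_iter=200, seed=1)
        expected = (1 + np.count_nonzero(nd.null_values >= nd.observed)) / 201
        assert nd.p_value == pytest.approx(expected, abs=1e-15)
        assert len(nd.null_values) == 200

    def test_planted_signal_significant_noise_not(self, planted_dataset):
        x, truth, _ = planted_dataset
        f1 = truth.spatial_factors["factor_1"]
        y_signal = f1 + 0.3 * np.random.default_rng(21).normal(size=len(f1))
        nd = null_variance_explained(x, y_signal, n_iter=1000, seed=21)
        assert nd.p_value <= 0.01
        y_noise = pd.Series(
            np.random.default_rng(22).normal(size=x.n), index=x.regions
        )
        nd0 = null_variance_explained(x, y_noise, n_iter=1000, seed=22)
        assert nd0.p_value > 0.05

    def test_bootstrap_method_runs(self):
        x, y = _random_instance(5, n=15, p=8)
        nd = null_variance_explained(_as_matrix(x), y, n_iter=100, method="bootstrap")
        assert nd.method == "bootstrap"

    def test_unknown_method_rejected(self):
        x, y = _random_instance(5)
        with pytest.raises(ValueError, match="unknown method"):
            null_variance_explained(_as_matrix(x), y, n_iter=100, method="spin")


class TestBootstrapGeneWeights:
    def test_reproducible_bit_for_bit(self):
        x, y = _random_instance(6, n=20, p=15)
        a = bootstrap_gene_weights(_as_matrix(x), y, n_boot=150, seed=9)
        b = bootstrap_gene_weights(_as_matrix(x), y, n_boot=150, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_zero_variance_weight_flagged_degenerate(self):
        """A gene with identical aligned weight in every replicate (SE=0) and a
        nonzero weight gets the degeneracy flag and p = 0."""
        from plscortex.pls import _bootstrap_zscores

        w0 = np.array([0.5, 0.0, -0.3])
        se = np.array([0.0, 0.0, 0.1])
        z, p, degenerate = _bootstrap_zscores(w0, se)
        assert degenerate.tolist() == [True, False, False]
        assert p[0] == 0.0 and np.isinf(z[0])
        assert p[1] == pytest.approx(1.0)  # zero weight, zero SE: no evidence
        assert np.isfinite(z[2])

    def test_normal_data_has_positive_se(self):
        x, y = _random_instance(8, n=20, p=6)
        stats_ = bootstrap_gene_weights(_as_matrix(x), y, n_boot=100, seed=1)
        assert (stats_.table["se"] > 0).all()
        assert not stats_.table["degenerate"].any()

    def test_planted_genes_have_larger_z(self, planted_dataset):
        x, truth, _ = planted_dataset
        f1 = truth.spatial_factors["factor_1"]
        y = f1 + 0.3 * np.random.default_rng(42).normal(size=len(f1))
        stats_ = bootstrap_gene_weights(x, y, n_boot=300, seed=42)
        z = stats_.table["z"].abs()
        planted = list(truth.planted_gene_ids)
        other = [g for g in x.genes if g not in set(planted)]
        assert z[planted].median() > z[other].median()

    def test_percentile_replicates_available(self):
        x, y = _random_instance(7, n=15, p=6)
        stats_ = bootstrap_gene_weights(
            _as_matrix(x), y, n_boot=120, seed=3, keep_replicates=True
        )
        assert stats_.replicates.shape == (120, 6)
        # SE recomputed from the retained replicates matches the streaming SE
        np.testing.assert_allclose(
            stats_.replicates.std(ddof=1).to_numpy(),
            stats_.table["se"].to_numpy(),
            atol=1e-10,
        )


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        y = np.array([1.0, -2.0, 0.5, 3.0, -1.5, 0.3, 2.2, -0.7])
        x = np.column_stack([y, -y, y, -y]) + 0.0
        model = fit_pls1(x, y)
        vip = compute_vip(model)
        np.testing.assert_allclose(vip.to_numpy(), 1.0, atol=1e-12)

    @given(seed=st.integers(0, 500), k=st.integers(1, 3))
    def test_mean_squared_vip_is_one(self, seed, k):
        x, y = _random_instance(seed, n=25, p=50)
        model = fit_pls1(x, y, k=k)
        vip = compute_vip(model)
        assert np.mean(vip.to_numpy() ** 2) == pytest.approx(1.0, abs=1e-10)


class TestSelectGenes:
    def _stats(self, weights, vips, ps):
        from plscortex.pls import GeneStats

        table = pd.DataFrame(
            {
                "weight": weights,
                "se": 1.0,
                "z": weights,
                "p": ps,
                "vip": vips,
                "degenerate": False,
            },
            index=[f"G{i}" for i in range(len(weights))],
        )
        return GeneStats(table=table, n_boot=100, seed=0)

    def test_thresholds_strict(self):
        stats_ = self._stats([0.5, -0.5, 0.4, -0.4], [1.0, 1.0, 1.0, 1.0],
                             [0.01] * 4)
        sel = select_genes(stats_, vip_cut=1.0, alpha=0.05)
        assert sel.pls1_plus == [] and sel.pls1_minus == []

    def test_signs_partition(self):
        stats_ = self._stats([0.6, -0.7, 0.1], [1.5, 1.4, 0.2], [0.01, 0.02, 0.9])
        sel = select_genes(stats_)
        assert sel.pls1_plus == ["G0"]
        assert sel.pls1_minus == ["G1"]
        assert not (set(sel.pls1_plus) & set(sel.pls1_minus))

    def test_flipping_y_swaps_plus_and_minus(self, planted_dataset):
        x, truth, _ = planted_dataset
        f1 = truth.spatial_factors["factor_1"]
        y = f1 + 0.3 * np.random.default_rng(11).normal(size=len(f1))
        a = select_genes(bootstrap_gene_weights(x, y, n_boot=150, seed=4))
        b = select_genes(bootstrap_gene_weights(x, -y, n_boot=150, seed=4))
        assert set(a.pls1_plus) == set(b.pls1_minus)
        assert set(a.pls1_minus) == set(b.pls1_plus)
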