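"""Voxel-wise GLM, one-sided contrasts, permutation FWE, cluster report."""

import numpy as np
import pandas as pd
import pytest

from lesionrate import voxelstats as vs


def _table(n, rng):
    return pd.DataFrame({
        "wmh_rate": rng.normal(size=n),
        "gm_rate": rng.normal(size=n),
        "age_baseline": rng.normal(70, 10, n),
        "sex": rng.choice(["F", "M"], n),
        "lacune_volume": rng.gamma(2, 100, n),
        "tiv": rng.normal(1.4e6, 1e5, n),
        "wmh_baseline": rng.gamma(2, 1e4, n),
    })


class TestBuildDesign:
    def test_model1_shape_and_roles(self):
        t = _table(10, np.random.default_rng(0))
        d = vs.build_design(t, "gm_vs_wmhrate")
        assert d.X.shape == (10, 7)
        assert d.names[0] == "intercept"
        assert d.roles.count("effect_of_interest") == 1
        assert d.names[d.effect_index] == "wmh_rate"

    def test_model2_excludes_wmh_baseline(self):
        t = _table(10, np.random.default_rng(0))
        d = vs.build_design(t, "wmh_vs_gmrate")
        assert d.X.shape == (10, 6)
        assert "wmh_baseline" not in d.names

    def test_continuous_columns_centered(self):
        t = _table(20, np.random.default_rng(1))
        d = vs.build_design(t, "gm_vs_wmhrate")
        scale = np.maximum(np.abs(d.X[:, 1:]).max(axis=0), 1.0)
        assert np.all(np.abs(d.X[:, 1:].mean(axis=0)) <= 1e-12 * scale)

    def test_collinear_columns_rejected(self):
        t = _table(10, np.random.default_rng(2))
        t["tiv"] = t["age_baseline"]  # duplicate covariate
        with pytest.raises(ValueError, match="rank"):
            vs.build_design(t, "gm_vs_wmhrate")

    def test_missing_column_named(self):
        t = _table(10, np.random.default_rng(3)).drop(columns=["tiv"])
        with pytest.raises(ValueError, match="tiv"):
            vs.build_design(t, "gm_vs_wmhrate")


def _simple_design(x):
    n = len(x)
    X = np.column_stack([np.ones(n), np.asarray(x, dtype=float)])
    return vs.DesignMatrix(X, ["intercept", "x"], ["intercept",
                                                   "effect_of_interest"])


class TestGlmAndContrast:
    def test_single_voxel_slope(self):
        d = _simple_design([0.0, 1.0, 2.0])
        stack = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        betas, sigma2, *_ = vs.fit_voxelwise_glm(stack, d,
                                                 np.ones((1, 1, 1), bool))
        assert betas[1, 0] == pytest.approx(1.0)
        assert sigma2[0] == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_is_mean(self):
        rng = np.random.default_rng(0)
        stack = rng.normal(size=(8, 3, 3, 3))
        X = np.ones((8, 1))
        d = vs.DesignMatrix(X, ["intercept"], ["intercept"])
        betas, *_ = vs.fit_voxelwise_glm(stack, d, np.ones((3, 3, 3), bool))
        np.testing.assert_allclose(betas[0], stack.mean(axis=0).ravel(),
                                   atol=1e-12)

    def test_matches_per_voxel_lstsq_oracle(self):
        rng = np.random.default_rng(1)
        n = 15
        t = _table(n, rng)
        d = vs.build_design(t, "gm_vs_wmhrate")
        stack = rng.normal(size=(n, 4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        betas, sigma2, *_ = vs.fit_voxelwise_glm(stack, d, mask)
        flat = stack.reshape(n, -1)
        for v in range(0, 64, 7):
            b, res, *_ = np.linalg.lstsq(d.X, flat[:, v], rcond=None)
            np.testing.assert_allclose(betas[:, v], b, atol=1e-10)

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(2)
        n = 12
        t = _table(n, rng)
        d = vs.build_design(t, "gm_vs_wmhrate")
        stack = rng.normal(size=(n, 3, 3, 3))
        betas, sigma2, *_ = vs.fit_voxelwise_glm(stack, d,
                                                 np.ones((3, 3, 3), bool))
        c = np.zeros(7); c[d.effect_index] = 1.0
        t_pos = vs.t_contrast(betas, sigma2, d, c)
        t_neg = vs.t_contrast(betas, sigma2, d, -c)
        np.testing.assert_allclose(t_pos, -t_neg, atol=1e-12)

    def test_orthogonal_confound_leaves_t_unchanged(self):
        """Adding a confound orthogonal to both the effect and the data does
        not change the effect t-statistic."""
        rng = np.random.default_rng(3)
        n = 24
        x = rng.normal(size=n)
        y = rng.normal(size=(n, 10))
        X1 = np.column_stack([np.ones(n), x])
        d1 = vs.DesignMatrix(X1, ["i", "x"], ["intercept", "effect_of_interest"])
        # build a regressor orthogonal to [1, x] and to every y column
        basis = np.column_stack([X1, y])
        q, _ = np.linalg.qr(basis)
        z = rng.normal(size=n)
        z -= q @ (q.T @ z)
        X2 = np.column_stack([X1, z])
        d2 = vs.DesignMatrix(X2, ["i", "x", "z"],
                             ["intercept", "effect_of_interest", "confound"])
        stack = y.reshape(n, 10, 1, 1)
        mask = np.ones((10, 1, 1), bool)
        b1, s1, *_ = vs.fit_voxelwise_glm(stack, d1, mask)
        b2, s2, *_ = vs.fit_voxelwise_glm(stack, d2, mask)
        t1 = vs.t_contrast(b1, s1, d1, [0, 1])
        t2 = vs.t_contrast(b2, s2, d2, [0, 1, 0])
        # same contrast value and variance up to the df change
        np.testing.assert_allclose(t2 * np.sqrt((n - 2) / (n - 3)), t1, atol=1e-8)

    def test_perfect_fit_capped(self):
        d = _simple_design([0.0, 1.0, 2.0])
        stack = np.array([0.0, 2.0, 4.0]).reshape(3, 1, 1, 1)
        betas, sigma2, *_ = vs.fit_voxelwise_glm(stack, d,
                                                 np.ones((1, 1, 1), bool))
        t = vs.t_contrast(betas, sigma2, d, [0, 1])
        assert t[0] == vs.T_CAP

    def test_zero_contrast_rejected(self):
        d = _simple_design([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            vs.t_contrast(np.zeros((2, 1)), np.ones(1), d, [0, 0])

    def test_underdetermined_rejected(self):
        d = _simple_design([0.0, 1.0])
        with pytest.raises(ValueError):
            vs.fit_voxelwise_glm(np.zeros((2, 2, 2, 2)), d,
                                 np.ones((2, 2, 2), bool))


class TestPermutationFwe:
    def test_determinism(self):
        rng = np.random.default_rng(4)
        n = 16
        t = _table(n, rng)
        d = vs.build_design(t, "gm_vs_wmhrate")
        stack = rng.normal(size=(n, 6, 6, 6))
        c = np.zeros(7); c[d.effect_index] = 1.0
        r1 = vs.permutation_fwe(stack, d, c, "positive", 150, seed=9)
        r2 = vs.permutation_fwe(stack, d, c, "positive", 150, seed=9)
        np.testing.assert_array_equal(r1.p_fwe, r2.p_fwe)
        np.testing.assert_array_equal(r1.max_null, r2.max_null)

    def test_corrected_p_geq_uncorrected_semantics(self):
        rng = np.random.default_rng(5)
        n = 20
        t = _table(n, rng)
        d = vs.build_design(t, "gm_vs_wmhrate")
        stack = rng.normal(size=(n, 5, 5, 5))
        c = np.zeros(7); c[d.effect_index] = 1.0
        res = vs.permutation_fwe(stack, d, c, "positive", 200, seed=3)
        # voxel-wise permutation p against the same null's per-voxel tail
        # cannot exceed the max-statistic corrected p
        assert res.p_fwe.min() >= 1.0 / 201
        assert np.all(res.p_fwe <= 1.0)
        assert (res.uncorrected_mask.sum() >=
                (res.p_fwe <= res.alpha).sum())

    def test_alpha_unattainable_rejected(self):
        rng = np.random.default_rng(6)
        t = _table(12, rng)
        d = vs.build_design(t, "gm_vs_wmhrate")
        stack = rng.normal(size=(12, 3, 3, 3))
        c = np.zeros(7); c[d.effect_index] = 1.0
        with pytest.raises(ValueError):
            vs.permutation_fwe(stack, d, c, "positive", 100, seed=1, alpha=0.001)
        with pytest.raises(ValueError):
            vs.permutation_fwe(stack, d, c, "positive", 50, seed=1)

    def test_strong_effect_detected(self):
        """An injected effect at 3x noise SD in a small region is significant
        while the rest of the volume is not."""
        rng = np.random.default_rng(7)
        n = 40
        x = rng.normal(size=n)
        stack = rng.normal(size=(n, 10, 10, 10))
        stack[:, 4:6, 4:6, 4:6] += 3.0 * (x / x.std())[:, None, None, None]
        t = _table(n, rng)
        t["wmh_rate"] = x
        d = vs.build_design(t, "gm_vs_wmhrate")
        c = np.zeros(7); c[d.effect_index] = 1.0
        res = vs.permutation_fwe(stack, d, c, "positive", 300, seed=2)
        sig = res.p_fwe <= 0.05
        assert sig[4:6, 4:6, 4:6].all()
        assert sig.sum() <= 8 + 5


class TestClusterReport:
    def test_empty(self):
        out = vs.cluster_report(np.zeros((5, 5, 5)), threshold=3.0)
        assert len(out) == 0

    def test_two_blobs_sorted(self):
        t = np.zeros((10, 10, 10))
        t[1:3, 1:3, 1:3] = 4.0
        t[7:9, 7:9, 7:9] = 6.0
        out = vs.cluster_report(t, threshold=3.0)
        assert len(out) == 2
        assert out.loc[0, "peak_t"] == 6.0
        assert out.loc[0, "n_voxels"] == 8

    def test_diagonal_connectivity_merges_with_26(self):
        t = np.zeros((6, 6, 6))
        t[1, 1, 1] = 5.0
        t[2, 2, 2] = 5.0
        assert len(vs.cluster_report(t, 3.0, connectivity=26)) == 1
        assert len(vs.cluster_report(t, 3.0, connectivity=6)) == 2

    def test_sizes_match_independent_labeling_oracle(self):
        rng = np.random.default_rng(8)
        t = rng.normal(size=(12, 12, 12))
        thr = 1.0
        out = vs.cluster_report(t, thr)
        from skimage import measure

        lab = measure.label(t > thr, connectivity=3)
        sizes = sorted(np.bincount(lab.ravel())[1:], reverse=True)
        assert sorted(out["n_voxels"], reverse=True) == sizes

    def test_world_coordinates_scaled(self):
        t = np.zeros((5, 5, 5)); t[2, 3, 4] = 9.0
        out = vs.cluster_report(t, 1.0, voxel_size=2.0)
        assert (out.loc[0, ["peak_x_mm", "peak_y_mm", "peak_z_mm"]].tolist()
                == [4.0, 6.0, 8.0])
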