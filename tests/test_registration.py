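"""SVF registration, divergence and rate-map contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lesionrate import phantom as ph
from lesionrate import registration as reg
from conftest import truth_channels


class TestDivergence:
    def test_linear_field_exact(self):
        """v = alpha*(x-c): divergence is exactly 3*alpha at interior voxels."""
        shape = (64, 64, 64)
        alpha = 0.013
        grid = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                    indexing="ij"))
        c = (np.asarray(shape) - 1) / 2.0
        v = alpha * (grid - c[:, None, None, None])
        div = reg.divergence(v, 1.0)
        interior = div[1:-1, 1:-1, 1:-1]
        assert np.max(np.abs(interior - 3 * alpha)) < 1e-10

    def test_constant_field_zero(self):
        v = np.ones((3, 20, 20, 20)) * 2.5
        assert np.all(reg.divergence(v, 1.0) == 0)

    def test_matches_independent_fd_oracle(self):
        """Random smooth field: divergence equals a separately coded
        finite-difference computation to 1e-10."""
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        v = np.stack([gaussian_filter(rng.normal(size=(24, 24, 24)), 2)
                      for _ in range(3)])
        vox = 0.8
        got = reg.divergence(v, vox)
        expected = sum(np.gradient(v[i], vox)[i] for i in range(3))
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestFitRateMap:
    def test_exact_linear_series(self):
        d = [np.full((4, 4, 4), x) for x in (0.0, 0.1, 0.2)]
        rate = reg.fit_rate_map(d, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(rate, 0.1, atol=1e-14)

    def test_two_point_slope(self):
        d = [np.full((3, 3, 3), 0.05), np.full((3, 3, 3), 0.23)]
        rate = reg.fit_rate_map(d, [0.5, 2.0])
        np.testing.assert_allclose(rate, (0.23 - 0.05) / 1.5, atol=1e-14)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(1)
        t = np.array([0.0, 0.9, 2.1, 3.0])
        stack = rng.normal(size=(4, 6, 6, 6))
        rate = reg.fit_rate_map(list(stack), t)
        tc = t - t.mean()
        expected = np.tensordot(tc, stack - stack.mean(0), axes=(0, 0)) \
            / np.sum(tc ** 2)
        np.testing.assert_allclose(rate, expected, atol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 10.0), n=st.integers(2, 4))
    def test_time_rescaling_property(self, scale, n):
        """Scaling all intervals by k scales the fitted slope by 1/k."""
        rng = np.random.default_rng(42)
        t = np.sort(rng.uniform(0, 3, size=n))
        while np.unique(t).size < n:
            t = np.sort(rng.uniform(0, 3, size=n))
        stack = rng.normal(size=(n, 3, 3, 3))
        r1 = reg.fit_rate_map(list(stack), t)
        r2 = reg.fit_rate_map(list(stack), t * scale)
        np.testing.assert_allclose(r2, r1 / scale, rtol=1e-9, atol=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            reg.fit_rate_map([np.zeros((2, 2, 2))], [0.0])
        with pytest.raises(ValueError):
            reg.fit_rate_map([np.zeros((2, 2, 2))] * 2, [1.0, 1.0])


class TestExponentiateAndJacobian:
    def test_zero_velocity_identity(self):
        v = reg.VelocityField(np.zeros((3, 12, 12, 12)), 1.0)
        d = reg.exponentiate(v)
        assert np.all(d.disp_vox == 0)
        np.testing.assert_allclose(d.jacobian(), 1.0, atol=1e-12)

    def test_linear_contraction_flow(self):
        """exp of v = a*(x-c) is the map c + e^a (x-c) with Jacobian e^{3a}."""
        shape = (32, 32, 32)
        a = -0.05
        grid = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                    indexing="ij"))
        c = (np.asarray(shape) - 1) / 2.0
        v = reg.VelocityField(a * (grid - c[:, None, None, None]), 1.0)
        d = reg.exponentiate(v)
        expected_disp = (np.exp(a) - 1.0) * (grid - c[:, None, None, None])
        inner = (slice(4, -4),) * 3
        np.testing.assert_allclose(d.disp_vox[(slice(None),) + inner],
                                   expected_disp[(slice(None),) + inner],
                                   atol=2e-3)
        jac = d.jacobian()
        assert jac[inner].mean() == pytest.approx(np.exp(3 * a), rel=1e-3)

    def test_inverse_consistency(self):
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter

        v_arr = np.stack([gaussian_filter(rng.normal(size=(24, 24, 24)), 3) * 10
                          for _ in range(3)])
        v = reg.VelocityField(v_arr, 1.0)
        d = reg.exponentiate(v)
        comp = reg._compose_disp(d.inverse().disp_vox, d.disp_vox)
        rms = np.sqrt(np.mean(np.sum(comp[:, 4:-4, 4:-4, 4:-4] ** 2, axis=0)))
        assert rms < 0.5

    def test_jacobian_matches_simpleitk_oracle(self):
        """Cross-check the Jacobian determinant against SimpleITK on a random
        smooth displacement field (interior voxels, same-stencil tolerance)."""
        sitk = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(7)
        from scipy.ndimage import gaussian_filter

        disp = np.stack([gaussian_filter(rng.normal(size=(20, 20, 20)), 2.5) * 3
                         for _ in range(3)])
        ours = reg.jacobian_determinant(disp)
        # SimpleITK expects (z, y, x) vector order on an (z, y, x) grid
        field = np.stack([disp[2], disp[1], disp[0]], axis=-1)
        img = sitk.GetImageFromArray(field.astype(np.float64), isVector=True)
        ref = sitk.GetArrayFromImage(sitk.DisplacementFieldJacobianDeterminant(img))
        inner = (slice(2, -2),) * 3
        np.testing.assert_allclose(ours[inner], ref[inner], atol=5e-3)


class TestRegisterPair:
    def test_identity(self, clean_subject, fast_reg_config):
        _, truth = clean_subject
        chans = truth_channels(truth.labels[0])
        vf, d, jac = reg.register_pair(chans, chans, fast_reg_config)
        assert float(np.sqrt((vf.v_mm ** 2).mean())) < 1e-3
        np.testing.assert_allclose(jac, 1.0, atol=1e-6)

    def test_analytic_contraction_jacobian(self, fast_reg_config):
        """Recover mean Jacobian within 5% of e^{3a} for a = -0.02."""
        p = ph.PhantomParams(grid_shape=(48, 48, 48), noise_sd=(0.0, 0.0),
                             times_years=(0.0, 1.0), random_seed=5)
        _, truth = ph.generate_subject(p, 0, (-0.02, 0.0))
        vf, d, jac = reg.register_pair(truth_channels(truth.labels[0]),
                                       truth_channels(truth.labels[1]),
                                       fast_reg_config)
        target = np.exp(3 * -0.02)
        assert jac[truth.brain_masks[0]].mean() == pytest.approx(target, rel=0.05)
        assert jac.min() > 0

    def test_known_warp_recovery(self, clean_subject, fast_reg_config):
        """A small random smooth warp applied to the phantom is recovered
        with sub-voxel target registration error at 90% of interior voxels."""
        _, truth = clean_subject
        chans = truth_channels(truth.labels[0])
        rng = np.random.default_rng(11)
        from scipy.ndimage import gaussian_filter

        # correlation length of ~10 voxels: comparable to the spacing of the
        # phantom's tissue interfaces, so the field is observable everywhere
        true_disp = np.stack([gaussian_filter(rng.normal(size=chans[0].shape), 10)
                              for _ in range(3)])
        true_disp *= 2.0 / max(np.abs(true_disp).max(), 1e-9)  # max 2 voxels
        warped = [reg.warp_image(c, true_disp) for c in chans]
        # moving = deformed image: the forward map deformed -> original then
        # has displacement exactly true_disp (pull-back convention)
        vf, d, jac = reg.register_pair(warped, chans, fast_reg_config)
        err = np.sqrt(np.sum((d.disp_vox - true_disp) ** 2, axis=0))
        interior = np.zeros(chans[0].shape, dtype=bool)
        interior[4:-4, 4:-4, 4:-4] = True
        interior &= sum(chans) > 0.5
        assert (err[interior] < 1.0).mean() >= 0.90

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reg.register_pair([np.zeros((8, 8, 8))], [np.zeros((10, 10, 10))])


class TestSubjectAverage:
    def test_identical_timepoints(self, clean_subject, fast_reg_config):
        _, truth = clean_subject
        chans = truth_channels(truth.labels[0])
        tmpl, vfs, defs, jacs = reg.build_subject_average(
            [chans, chans], n_outer_iters=2, config=fast_reg_config)
        for t, c in zip(tmpl, chans):
            np.testing.assert_allclose(t, c, atol=1e-6)
        for v in vfs:
            assert float(np.sqrt((v.v_mm ** 2).mean())) < 1e-3

    def test_contraction_symmetry(self, fast_reg_config):
        """Two time points related by contraction: the template sits at the
        temporal midpoint, so the velocities are nearly equal and opposite."""
        p = ph.PhantomParams(grid_shape=(48, 48, 48), noise_sd=(0.0, 0.0),
                             times_years=(0.0, 2.0), random_seed=5)
        _, truth = ph.generate_subject(p, 0, (-0.015, 0.0))
        maps = [truth_channels(l) for l in truth.labels]
        tmpl, vfs, defs, jacs = reg.build_subject_average(
            maps, n_outer_iters=3, config=fast_reg_config)
        resid = np.abs(vfs[0].v_mm + vfs[1].v_mm).mean()
        scale = np.abs(vfs[0].v_mm).mean()
        assert resid < 0.10 * scale

    def test_timepoint_order_invariance(self, clean_subject, fast_reg_config):
        _, truth = clean_subject
        maps = [truth_channels(l) for l in truth.labels]
        t1, *_ = reg.build_subject_average(maps, 2, fast_reg_config)
        t2, *_ = reg.build_subject_average(maps[::-1], 2, fast_reg_config)
        for a, b in zip(t1, t2):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            reg.build_subject_average([[np.zeros((8, 8, 8))]])


class TestGroupTemplate:
    def test_identical_subjects(self, clean_subject, fast_reg_config):
        _, truth = clean_subject
        chans = truth_channels(truth.labels[0])
        tmpl, vfs, defs, jacs = reg.build_group_template(
            [chans, chans], n_outer_iters=2, config=fast_reg_config)
        for t, c in zip(tmpl, chans):
            np.testing.assert_allclose(t, c, atol=1e-6)
        for d in defs:
            assert np.abs(d.disp_vox).max() < 1e-2

    def test_template_volume_bracketed(self, fast_reg_config):
        """For a cohort of contracted copies of one anatomy, the template's
        brain volume lies between the smallest and largest subject."""
        p = ph.PhantomParams(grid_shape=(40, 40, 40), noise_sd=(0.0, 0.0),
                             times_years=(0.0, 1.0), random_seed=5)
        subjects = []
        vols = []
        for a in (0.0, -0.03, -0.06):
            _, truth = ph.generate_subject(p, 0, (a, 0.0))
            ch = truth_channels(truth.labels[1])
            subjects.append(ch)
            vols.append(float(ch[1].sum() + ch[2].sum()))
        tmpl, *_ = reg.build_group_template(subjects, n_outer_iters=2,
                                            config=fast_reg_config)
        tv = float(tmpl[1].sum() + tmpl[2].sum())
        assert min(vols) <= tv <= max(vols)

    def test_subject_order_invariance(self, fast_reg_config):
        p = ph.PhantomParams(grid_shape=(40, 40, 40), noise_sd=(0.0, 0.0),
                             times_years=(0.0, 1.0), random_seed=5)
        subs = []
        for a in (0.0, -0.04):
            _, truth = ph.generate_subject(p, 0, (a, 0.0))
            subs.append(truth_channels(truth.labels[1]))
        t1, *_ = reg.build_group_template(subs, 2, fast_reg_config)
        t2, *_ = reg.build_group_template(subs[::-1], 2, fast_reg_config)
        for a, b in zip(t1, t2):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            reg.build_group_template([[np.zeros((8, 8, 8))]])
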