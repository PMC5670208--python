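from itertools import product

import numpy as np
import pytest
from scipy.integrate import quad

from cb1pipe import (KineticParams, SpectralAnalysisModel, SpectralBasis,
                     TimeCurve, TissueTAC, build_basis, fit_spectral,
                     gen_tissue_tac, roi_mean_tac)
from cb1pipe.kinetics import exp_conv, frame_average


def brute_force_bounded_ls(A, y, upper_last=None):
    """Exact solution of min ||A x - y||^2, x >= 0 (last bound optional).

    Enumerates every face of the feasible region: each coefficient is
    either clamped at a bound or free, the free ones solved by ordinary
    least squares; the feasible candidate with the smallest objective is
    the global optimum of this convex problem.  Independent of the
    package's BVLS path; exponential in n, for tiny instances only.
    """
    n = A.shape[1]
    best_x, best_obj = None, np.inf
    choices = []
    for j in range(n):
        opts = ["free", "zero"]
        if upper_last is not None and j == n - 1:
            opts.append("upper")
        choices.append(opts)
    for combo in product(*choices):
        free = [j for j, c in enumerate(combo) if c == "free"]
        x = np.zeros(n)
        rhs = y.copy()
        for j, c in enumerate(combo):
            if c == "upper":
                x[j] = upper_last
                rhs = rhs - upper_last * A[:, j]
        if free:
            sol, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
            x[free] = sol
        if np.any(x < -1e-12):
            continue
        if upper_last is not None and x[-1] > upper_last + 1e-12:
            continue
        r = y - A @ x
        obj = float(r @ r)
        if obj < best_obj - 1e-15:
            best_obj, best_x = obj, x
    return best_x, best_obj


class TestExpConv:
    def test_matches_quadrature(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0.0, 50.0, 101)
        f = np.abs(rng.standard_normal(t.size)).cumsum()  # piecewise linear
        betas = np.array([0.001, 0.05, 0.5])
        C = exp_conv(t, f, betas)
        interp = lambda s: np.interp(s, t, f)
        for j, b in enumerate(betas):
            for k in (30, 70, 100):
                want, _ = quad(lambda s: interp(s) * np.exp(-b * (t[k] - s)),
                               0, t[k], limit=400)
                assert C[k, j] == pytest.approx(want, rel=1e-6, abs=1e-9)

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            exp_conv(np.arange(5.0), np.ones(5), np.array([0.0]))


class TestBuildBasis:
    def test_column_count(self, input_fn, schedule, whole_blood):
        b = build_basis(input_fn, schedule, n_beta=2, whole_blood=whole_blood)
        assert b.basis_matrix.shape == (35, 2)
        assert b.n_columns == 3  # 2 tissue frequencies + blood

    def test_slow_beta_approaches_running_integral(self, input_fn, schedule):
        b = build_basis(input_fn, schedule, beta_slow=1e-8, beta_fast=1e-7,
                        n_beta=2)
        t = np.arange(0.0, schedule.total_duration + 1.0)
        integral = np.concatenate([[0.0], np.cumsum(
            (input_fn(t)[1:] + input_fn(t)[:-1]) / 2.0)])
        want = frame_average(t, integral, schedule)
        got = b.basis_matrix[:, 0]
        assert np.allclose(got, want, rtol=1e-3)

    def test_invalid_bounds(self, input_fn, schedule):
        with pytest.raises(ValueError):
            build_basis(input_fn, schedule, beta_slow=0.1, beta_fast=0.01)
        with pytest.raises(ValueError):
            build_basis(input_fn, schedule, n_beta=1)

    def test_slow_boundary_above_isotope_decay(self, basis):
        from cb1pipe import decay_constant
        assert basis.beta_grid[0] > decay_constant(20.4)


class TestSpectralFit:
    def test_one_tissue_vt_recovery(self, input_fn, schedule, whole_blood, basis):
        params = KineticParams(model="one-tissue", K1=0.1, k2=0.025, vb=0.0)
        tac = gen_tissue_tac(input_fn, params, schedule)
        res = fit_spectral(tac, basis)
        assert res.vt == pytest.approx(4.0, rel=0.01)

    def test_two_tissue_vt_recovery(self, input_fn, schedule, whole_blood, basis):
        params = KineticParams(model="two-tissue", K1=0.1, k2=0.05,
                               k3=0.02, k4=0.01, vb=0.05)
        tac = gen_tissue_tac(input_fn, params, schedule, whole_blood=whole_blood)
        res = fit_spectral(tac, basis)
        assert res.vt == pytest.approx(params.vt, rel=0.01)
        assert res.vb == pytest.approx(0.05, abs=0.02)

    def test_pure_blood_tac(self, basis):
        tac = basis.blood_column.copy()
        res = fit_spectral(tac, basis)
        assert res.vb > 0.99
        assert res.vt_uncorrected == pytest.approx(0.0, abs=1e-6)

    def test_scaling_properties(self, input_fn, schedule, basis):
        params = KineticParams(model="one-tissue", K1=0.1, k2=0.025, vb=0.0)
        tac = gen_tissue_tac(input_fn, params, schedule)
        res1 = fit_spectral(tac, basis)
        res2 = fit_spectral(TissueTAC(schedule, 2 * tac.activity), basis)
        assert res2.vt == pytest.approx(2 * res1.vt, rel=1e-6)
        # scaling input and TAC together leaves the ratio VT unchanged
        scaled_input = TimeCurve(input_fn.time, 2 * input_fn.parent_plasma_activity)
        basis2 = build_basis(scaled_input, schedule)
        res3 = fit_spectral(TissueTAC(schedule, 2 * tac.activity), basis2)
        assert res3.vt == pytest.approx(res1.vt, rel=1e-6)

    def test_rank_shaping_filter_smooths_but_preserves_vt(self, input_fn,
                                                          schedule, basis):
        params = KineticParams(model="one-tissue", K1=0.1, k2=0.025, vb=0.0)
        tac = gen_tissue_tac(input_fn, params, schedule)
        plain = fit_spectral(tac, basis, regularisation="none")
        smooth = fit_spectral(tac, basis, regularisation="rank_shaping_filter")
        assert smooth.n_components >= plain.n_components
        assert smooth.vt == pytest.approx(plain.vt, rel=0.10)

    def test_all_zero_weights_rejected(self, basis):
        tac = np.ones(35)
        with pytest.raises(ValueError):
            SpectralAnalysisModel(tac, basis, weights=np.zeros(35))

    def test_mismatched_lengths_rejected(self, basis):
        with pytest.raises(ValueError):
            SpectralAnalysisModel(np.ones(10), basis)

    def test_matches_brute_force_oracle(self):
        """The weighted bounded-NNLS fit equals exhaustive face enumeration."""
        from cb1pipe.frames import FrameSchedule

        rng = np.random.default_rng(42)
        n_frames, n_beta = 12, 5
        sched = FrameSchedule(np.arange(n_frames) * 10.0,
                              np.full(n_frames, 10.0))
        betas = np.logspace(-3, -1, n_beta)
        for _ in range(5):
            basis = SpectralBasis(
                betas, np.abs(rng.standard_normal((n_frames, n_beta))),
                np.abs(rng.standard_normal(n_frames)), sched)
            y = np.abs(rng.standard_normal(n_frames))
            w = rng.uniform(0.5, 2.0, n_frames)
            res = SpectralAnalysisModel(y, basis, weights=w).fit()
            got = np.concatenate([res.alpha_raw, [res.vb]])
            sw = np.sqrt(w)
            Afull = np.hstack([basis.basis_matrix,
                               basis.blood_column[:, None]]) * sw[:, None]
            x_oracle, _ = brute_force_bounded_ls(Afull, y * sw, upper_last=1.0)
            assert np.allclose(got, x_oracle, atol=1e-6)


class TestRoiMeanTac:
    def test_single_voxel(self, schedule):
        img = np.random.default_rng(0).random((2, 2, 2, 35))
        labels = np.zeros((2, 2, 2), int)
        labels[1, 0, 1] = 7
        tac = roi_mean_tac(img, labels, 7, schedule)
        assert np.allclose(tac.activity, img[1, 0, 1])

    def test_uniform_image(self, schedule):
        img = np.full((3, 3, 3, 35), 2.5)
        labels = np.ones((3, 3, 3), int)
        tac = roi_mean_tac(img, labels, 1, schedule)
        assert np.allclose(tac.activity, 2.5)

    def test_two_voxel_mean(self, schedule):
        img = np.zeros((2, 1, 1, 35))
        img[0, 0, 0] = 1.0
        img[1, 0, 0] = 3.0
        labels = np.full((2, 1, 1), 4, int)
        tac = roi_mean_tac(img, labels, 4, schedule)
        assert np.allclose(tac.activity, 2.0)

    def test_absent_label(self, schedule):
        with pytest.raises(ValueError, match="absent"):
            roi_mean_tac(np.zeros((2, 2, 2, 35)), np.zeros((2, 2, 2), int),
                         9, schedule)

    def test_nibabel_inputs(self, schedule):
        nib = pytest.importorskip("nibabel")
        img = nib.Nifti1Image(np.full((2, 2, 2, 35), 1.5), np.eye(4))
        lab = nib.Nifti1Image(np.ones((2, 2, 2)), np.eye(4))
        tac = roi_mean_tac(img, lab, 1, schedule)
        assert np.allclose(tac.activity, 1.5)
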