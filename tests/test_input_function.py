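import numpy as np
import pytest

from cb1pipe import (BloodDataset, KineticParams, SigmoidModel, TimeCurve,
                     apply_parent_correction, build_plasma_curve,
                     build_whole_blood_curve, estimate_delay, fit_sigmoid,
                     gen_blood_dataset, gen_tissue_tac)
from cb1pipe.input_function import _logistic4
from cb1pipe.synthetic import BloodProfile

SIX_TIMES = np.array([3.0, 5.0, 10.0, 15.0, 20.0, 30.0])


class TestFitSigmoid:
    def test_exact_recovery(self):
        truth = (0.6, 1.4, 10.0, 3.0)
        values = _logistic4(SIX_TIMES, *truth)
        m = fit_sigmoid(SIX_TIMES, values)
        for got, want in zip((m.a, m.b, m.c, m.d), truth):
            assert got == pytest.approx(want, rel=1e-4)
        assert m.rss < 1e-12

    def test_constant_values(self):
        m = fit_sigmoid(SIX_TIMES, np.full(6, 0.7))
        assert np.allclose(m(np.linspace(0, 100, 50)), 0.7)
        assert m.rss == 0.0

    def test_underdetermined_raises(self):
        with pytest.raises(ValueError):
            fit_sigmoid([1, 2, 3, 4], [1, 2, 3, 4])

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            fit_sigmoid(SIX_TIMES, [1, 2, np.nan, 4, 5, 6])

    def test_order_invariance(self):
        values = _logistic4(SIX_TIMES, 0.3, 1.0, 12.0, 2.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(6)
        m1 = fit_sigmoid(SIX_TIMES, values)
        m2 = fit_sigmoid(SIX_TIMES[perm], values[perm])
        assert m1.a == pytest.approx(m2.a, rel=1e-6)
        assert m1.c == pytest.approx(m2.c, rel=1e-6)


def _flat_blood(value=2.0, ratio=1.0, parent=1.0):
    disc_t = np.array([3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0, 75.0])
    cont_t = np.arange(0.0, 901.0)
    return BloodDataset(cont_t, np.full(cont_t.size, value), disc_t,
                        np.full(8, value * ratio), np.full(8, value),
                        np.full(8, parent))


class TestPlasmaCurve:
    def test_unit_ratio_reproduces_whole_blood(self):
        blood = _flat_blood(value=2.0)
        curve = build_plasma_curve(blood, SigmoidModel.constant(1.0))
        t = np.arange(0.0, 900.0, 7.0)
        assert np.allclose(curve(t), 2.0)

    def test_zero_blood_gives_zero_curve(self):
        blood = _flat_blood(value=0.0)
        curve = build_plasma_curve(blood, SigmoidModel.constant(1.0))
        assert np.allclose(curve(np.arange(0, 4500.0, 10.0)), 0.0)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            build_plasma_curve(_flat_blood(), SigmoidModel.constant(-0.5))

    def test_junction_continuity(self, profile):
        blood = gen_blood_dataset(profile)
        t, r = blood.ratio_samples
        curve = build_plasma_curve(blood, fit_sigmoid(t, r))
        # the merged curve is continuous across the 15-min junction
        left, right = curve(899.0), curve(901.0)
        assert abs(right - left) < 0.05 * max(abs(left), 1e-9) + 1e-6

    def test_missing_late_sample_warns(self, profile):
        blood = gen_blood_dataset(profile)  # no 60-min sample in protocol
        with pytest.warns(UserWarning, match="60"):
            build_plasma_curve(blood, SigmoidModel.constant(1.0))


class TestParentCorrection:
    def test_identity(self):
        curve = TimeCurve(np.arange(10.0), np.arange(10.0) + 1.0)
        out = apply_parent_correction(curve, SigmoidModel.constant(1.0))
        assert np.allclose(out.parent_plasma_activity, curve.values)

    def test_half(self):
        curve = TimeCurve(np.arange(10.0), np.full(10, 4.0))
        out = apply_parent_correction(curve, SigmoidModel.constant(0.5))
        assert np.allclose(out.parent_plasma_activity, 2.0)

    def test_fraction_clipped_to_unit_interval(self):
        curve = TimeCurve(np.arange(10.0), np.full(10, 4.0))
        out = apply_parent_correction(curve, SigmoidModel.constant(1.7))
        assert np.allclose(out.parent_plasma_activity, 4.0)


class TestRoundTrip:
    """Generator -> fit -> reconstruction on noise-free data."""

    def test_sigmoids_recovered(self, profile):
        blood = gen_blood_dataset(profile)
        t, r = blood.ratio_samples
        ratio_m = fit_sigmoid(t, r)
        parent_m = fit_sigmoid(blood.discrete_time, blood.discrete_parent_fraction)
        grid = np.linspace(0.5, 90.0, 200)
        for model, truth in ((ratio_m, profile.ratio),
                             (parent_m, profile.parent_fraction)):
            rms = np.sqrt(np.mean((model(grid) - truth(grid)) ** 2))
            assert rms < 0.005 * np.sqrt(np.mean(truth(grid) ** 2))

    def test_continuous_segment_reconstruction(self, profile):
        blood = gen_blood_dataset(profile)
        t, r = blood.ratio_samples
        curve = build_plasma_curve(blood, fit_sigmoid(t, r))
        parent_m = fit_sigmoid(blood.discrete_time, blood.discrete_parent_fraction)
        inp = apply_parent_correction(curve, parent_m)
        tt = np.arange(0.0, 900.0, 2.0)
        truth = profile.parent_plasma(tt)
        rms = np.sqrt(np.mean((inp(tt) - truth) ** 2))
        assert rms < 0.005 * np.sqrt(np.mean(truth ** 2))

    def test_full_curve_within_interpolation_error(self, profile):
        # between the sparse late samples only piecewise-linear accuracy is
        # attainable; peak-normalised RMS stays below 0.5%
        blood = gen_blood_dataset(profile)
        t, r = blood.ratio_samples
        curve = build_plasma_curve(blood, fit_sigmoid(t, r))
        parent_m = fit_sigmoid(blood.discrete_time, blood.discrete_parent_fraction)
        inp = apply_parent_correction(curve, parent_m)
        tt = np.arange(0.0, 4500.0, 5.0)
        truth = profile.parent_plasma(tt)
        rms = np.sqrt(np.mean((inp(tt) - truth) ** 2))
        assert rms < 0.005 * truth.max()

    def test_linearity_in_blood_activity(self, profile):
        big = BloodProfile(peak_amplitude=profile.peak_amplitude * 3.0)
        b1, b2 = gen_blood_dataset(profile), gen_blood_dataset(big)
        m = SigmoidModel.constant(1.0)
        p1, p2 = build_plasma_curve(b1, m), build_plasma_curve(b2, m)
        tt = np.arange(0.0, 4500.0, 25.0)
        assert np.allclose(p2(tt), 3.0 * p1(tt), rtol=1e-9)


# a clearance rate lying exactly on the 40-point spectral grid, so the
# delay objective is free of basis-mismatch bias
ON_GRID_K2 = float(np.logspace(np.log10(0.00063), np.log10(0.1), 40)[10])


class TestEstimateDelay:
    @pytest.mark.parametrize("true_delay", [0.0, 5.0])
    def test_recovers_known_delay(self, input_fn, whole_blood, schedule,
                                  true_delay):
        on_grid_k2 = ON_GRID_K2
        params = KineticParams(model="one-tissue", K1=12.57 * on_grid_k2,
                               k2=on_grid_k2, vb=0.05, delay=true_delay)
        wb = TimeCurve(whole_blood.time + true_delay, whole_blood.values) \
            if true_delay else whole_blood
        tac = gen_tissue_tac(input_fn, params, schedule, whole_blood=wb)
        est = estimate_delay(input_fn, tac.activity, schedule,
                             whole_blood=whole_blood,
                             search_grid=np.arange(-10, 10.5, 0.5), n_beta=40)
        assert abs(est - true_delay) <= 0.5

    def test_pure_noise_warns(self, input_fn, schedule):
        noise = np.abs(np.random.default_rng(0).standard_normal(35))
        with pytest.warns(UserWarning):
            estimate_delay(input_fn, noise, schedule,
                           search_grid=np.arange(-5, 5.5, 0.5), n_beta=12)


class TestBloodDatasetValidation:
    def test_rejects_negative_activity(self):
        with pytest.raises(ValueError):
            _flat_blood(value=2.0, ratio=-1.0)

    def test_rejects_bad_parent_fraction(self):
        with pytest.raises(ValueError):
            _flat_blood(parent=1.5)

    def test_whole_blood_merge_uses_late_samples(self, profile):
        blood = gen_blood_dataset(profile)
        with pytest.warns(UserWarning):
            wb = build_whole_blood_curve(blood)
        assert wb.time[-1] == 75.0 * 60.0
        assert wb(75 * 60.0) == pytest.approx(
            profile.whole_blood(75 * 60.0), rel=1e-9)
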