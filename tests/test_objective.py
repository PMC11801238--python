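"""Losses, sigma map, moment constants, schedules and calibration reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vdnmr import objective as ob


class TestSigmaMap:
    def test_symmetry_point(self):
        # sigmoid(0) = 0.5 forces sigma = 1/(0.499 + 0.001) - 1 = 1 exactly
        assert ob.sigma_from_confidence(0.0) == pytest.approx(1.0, abs=1e-15)

    def test_saturation_limits(self):
        assert ob.sigma_from_confidence(1e3) == pytest.approx(ob.SIGMA_MIN, rel=1e-9)
        assert ob.sigma_from_confidence(-1e3) == pytest.approx(ob.SIGMA_MAX, rel=1e-9)

    def test_strictly_decreasing_and_bounded(self):
        # strictly decreasing where float64 resolves the logistic
        conf = np.linspace(-15, 15, 2001)
        sig = ob.sigma_from_confidence(conf)
        assert np.all(np.diff(sig) < 0)
        wide = ob.sigma_from_confidence(np.linspace(-40, 40, 801))
        assert np.all(np.diff(wide) <= 0)
        assert np.all(wide > ob.SIGMA_MIN - 1e-12)
        assert np.all(wide < ob.SIGMA_MAX + 1e-12)

    def test_probability_form_agrees(self):
        from scipy.special import expit

        conf = np.array([-3.0, 0.0, 2.5])
        assert ob.sigma_from_probability(expit(conf)) == pytest.approx(
            ob.sigma_from_confidence(conf)
        )


class TestPointwiseLosses:
    def test_loss1_identity_and_offset(self):
        t = np.zeros((5, 7))
        assert ob.loss1(t, t) == 0.0
        assert ob.loss1(t, np.ones_like(t)) == 1.0

    def test_loss1_brute_force(self, rng):
        t = rng.standard_normal((4, 4))
        p = rng.standard_normal((4, 4))
        expected = sum((t.ravel()[i] - p.ravel()[i]) ** 2 for i in range(16)) / 16
        assert ob.loss1(t, p) == pytest.approx(expected, rel=1e-13)

    def test_loss1_shape_mismatch(self):
        with pytest.raises(ValueError):
            ob.loss1(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_chi_map(self, rng):
        t = rng.standard_normal((6, 6))
        p = rng.standard_normal((6, 6))
        s = np.abs(rng.standard_normal((6, 6))) + 0.1
        chi = ob.chi_map(t, p, s)
        assert chi == pytest.approx((t - p) / s)
        assert ob.chi_map(t, t, s) == pytest.approx(np.zeros((6, 6)))
        assert ob.chi_map(p + s, p, s) == pytest.approx(np.ones((6, 6)))

    def test_chi_map_rejects_nonpositive_sigma(self):
        t = np.ones((2, 2))
        with pytest.raises(ValueError):
            ob.chi_map(t, t, np.zeros((2, 2)))


class TestGaussianMoments:
    def test_integer_orders_exact(self):
        assert ob.gaussian_moment_reference(1.0) == 0.0
        assert ob.gaussian_moment_reference(2.0) == 1.0
        assert ob.gaussian_moment_reference(3.0) == 0.0

    def test_half_order_closed_form(self):
        from scipy.special import gamma

        m12 = ob.gaussian_moment_reference(0.5)
        expected = (1 + 1j) * 2**-0.75 * gamma(0.75) / np.sqrt(np.pi)
        assert m12 == pytest.approx(expected, rel=1e-12)
        assert m12.real == pytest.approx(0.4110894793, rel=1e-9)
        m72 = ob.gaussian_moment_reference(3.5)
        expected72 = 2**0.75 * (1 - 1j) * gamma(2.25) / np.sqrt(np.pi)
        assert m72 == pytest.approx(expected72, rel=1e-12)

    def test_monte_carlo_agreement(self, rng):
        z = rng.standard_normal(2_000_000).astype(complex)
        for m in (0.5, 3.5):
            emp = np.mean(z**m)
            ref = ob.gaussian_moment_reference(m)
            assert abs(emp - ref) / abs(ref) < 0.01

    def test_unsupported_order(self):
        with pytest.raises(ValueError):
            ob.gaussian_moment_reference(1.5)


class TestLoss2:
    def test_plus_minus_one(self):
        # empirical moments of {-1, +1}: (0.5+0.5i, 0, 1, 0, 0.5-0.5i)
        chi = np.array([-1.0, 1.0])
        expected = (
            abs(0.5 + 0.5j - ob.gaussian_moment_reference(0.5)) ** 2
            + abs(0.5 - 0.5j - ob.gaussian_moment_reference(3.5)) ** 2
        )
        assert ob.loss2(chi) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0158 + 0.661, abs=5e-3)

    def test_all_zeros(self):
        chi = np.zeros(10)
        expected = (
            abs(ob.gaussian_moment_reference(0.5)) ** 2
            + 1.0
            + abs(ob.gaussian_moment_reference(3.5)) ** 2
        )
        assert ob.loss2(chi) == pytest.approx(expected, rel=1e-12)

    def test_standard_normal_converges(self, rng):
        chi = rng.standard_normal(1_000_000)
        assert ob.loss2(chi) < 1e-3

    def test_permutation_invariance(self, rng):
        chi = rng.standard_normal(512)
        assert ob.loss2(chi) == pytest.approx(ob.loss2(chi[::-1]), rel=1e-12)


class TestLoss3:
    def test_constant_sigma_identity_pred(self):
        t = np.zeros((10, 10))
        sigma = np.full((10, 10), 0.7)
        # all sigmas fall in the top bin; RMSD = 0, so loss3 = 0.7**2
        assert ob.loss3(t, t, sigma) == pytest.approx(0.49, rel=1e-12)

    def test_eight_point_brute_force(self):
        sigma = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0])
        resid = np.array([0.5, -1.2, 0.8, 1.0, 2.5, -1.5, 2.0, -2.2])
        # bins [0, 0.5, 1, 1.5, 2]: sigma=1 -> bin 2, sigma=2 -> bin 3
        expected = (1.0 - np.sqrt(np.mean(resid[:4] ** 2))) ** 2 + (
            2.0 - np.sqrt(np.mean(resid[4:] ** 2))
        ) ** 2
        got = ob.loss3(resid, np.zeros(8), sigma, n_bins=4)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.014406115447728528, rel=1e-9)

    def test_calibrated_sigma_converges(self, rng):
        sigma = rng.uniform(0.5, 2.0, size=1_000_000)
        resid = sigma * rng.standard_normal(1_000_000)
        assert ob.loss3(resid, np.zeros_like(resid), sigma) < 0.05

    def test_permutation_invariance(self, rng):
        sigma = np.abs(rng.standard_normal(256)) + 0.1
        resid = rng.standard_normal(256)
        perm = rng.permutation(256)
        a = ob.loss3(resid, np.zeros(256), sigma)
        b = ob.loss3(resid[perm], np.zeros(256), sigma[perm])
        assert a == pytest.approx(b, rel=1e-12)


class TestTotalLoss:
    def test_scaling_at_threshold(self):
        # at loss1 = 0.03 the blend factor is sigmoid(-e^3/0.268) ~ 0
        assert ob.loss_scaling(0.03) < 1e-30
        assert ob.total_loss(0.03, 5.0, 5.0) == pytest.approx(2 * 0.03, rel=1e-12)

    def test_scaling_at_zero(self):
        from scipy.special import expit

        assert ob.loss_scaling(0.0) == pytest.approx(float(expit(-1 / 0.268)), rel=1e-12)
        assert ob.loss_scaling(0.0) == pytest.approx(0.0234, abs=2e-4)

    def test_reduction_without_calibration_losses(self):
        for l1 in (0.0, 0.005, 0.02, 0.5):
            s = ob.loss_scaling(l1)
            assert ob.total_loss(l1, 0.0, 0.0) == pytest.approx((2 - s) * l1, rel=1e-12)

    def test_scaling_nonincreasing(self):
        vals = [ob.loss_scaling(x) for x in np.linspace(0, 0.05, 50)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_negative_losses_rejected(self):
        with pytest.raises(ValueError):
            ob.total_loss(-1.0, 0.0, 0.0)


class TestLearningRate:
    def test_step_one(self):
        assert ob.learning_rate(1) == pytest.approx(3.5e-7 / 2884, rel=1e-12)
        assert ob.learning_rate(1) == pytest.approx(1.2136e-10, rel=1e-4)

    def test_inverse_sqrt_tail(self):
        for s in (10**5, 4 * 10**5):
            assert ob.learning_rate(4 * s) / ob.learning_rate(s) == pytest.approx(0.5, rel=1e-12)

    def test_unimodal(self):
        steps = np.arange(1, 200_001)
        lr = ob.learning_rate(steps)
        peak = int(np.argmax(lr))
        assert np.all(np.diff(lr[: peak + 1]) >= 0)
        assert np.all(np.diff(lr[peak:]) <= 0)

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            ob.learning_rate(0)


class TestSineBell:
    def test_endpoint_values(self):
        w = ob.sine_bell(100, 0.4 * np.pi)
        assert w[0] == pytest.approx(np.sin(0.4 * np.pi), rel=1e-12)
        assert w[0] == pytest.approx(0.95106, abs=1e-5)
        assert abs(w[-1]) < 1e-12


class TestCalibrationReport:
    def test_perfect_prediction(self, rng):
        t = rng.standard_normal((16, 16))
        s = np.ones((16, 16))
        rep = ob.calibration_report([t], [t], [s])
        assert rep.chi_mean == 0.0
        assert rep.chi_sd == 0.0

    def test_simulated_calibration(self, rng):
        n = 1_000_000
        sigma = rng.uniform(0.5, 2.0, size=(1, n))
        resid = sigma * rng.standard_normal((1, n))
        rep = ob.calibration_report([resid[0]], [np.zeros(n)], [sigma[0]])
        se = 1.0 / np.sqrt(n)
        assert abs(rep.chi_mean) < 3 * se
        assert abs(rep.chi_sd - 1.0) < 3 * se * np.sqrt(2)
        big = rep.table[rep.table["n"] > 1000]
        assert np.all(
            np.abs(big["mean_sigma"] - big["rmsd"]) / big["mean_sigma"] < 0.05
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ob.calibration_report([np.zeros(3)], [], [np.ones(3)])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-5, 5), min_size=2, max_size=64))
def test_loss2_nonnegative_property(values):
    assert ob.loss2(np.array(values)) >= 0.0
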