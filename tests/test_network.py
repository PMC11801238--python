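"""Tensor contracts, layer gradients, training loop and inference."""

import numpy as np
import pytest

from vdnmr import network as net
from vdnmr import objective as ob
from vdnmr import simulate as sim


def _tiny_config(**kw):
    base = dict(width=0.25, depth=1, seed=3, batch_size=1)
    base.update(kw)
    return net.NetworkConfig(**base)


class TestPacking:
    def test_input_tensor_shape(self, rng):
        for n_h, n_c in ((128, 96), (256, 200), (180, 130)):
            pair = [
                rng.standard_normal((2, n_h, n_c)) + 1j * rng.standard_normal((2, n_h, n_c))
                for _ in range(2)
            ]
            x = net.zero_fill_input(pair)
            assert x.shape == (2, 400, 512)

    def test_padded_region_zero(self, rng):
        plane = rng.standard_normal((2, 128, 96)) + 1j * rng.standard_normal((2, 128, 96))
        x = net.zero_fill_input([plane, plane])
        # 96 of 200 13C points used in each half, 128 of 256 1H points
        assert np.all(x[:, 96:200, :] == 0.0)
        assert np.all(x[:, 296:400, :] == 0.0)
        assert np.all(x[:, :, 128:256] == 0.0)
        assert np.all(x[:, :, 384:512] == 0.0)

    def test_round_trip_unpack(self, rng):
        plane = rng.standard_normal((2, 256, 200)) + 1j * rng.standard_normal((2, 256, 200))
        x = net.zero_fill_input([plane, plane])
        assert net.unpack_input(x[0]) == pytest.approx(plane)

    def test_oversize_rejected(self, rng):
        plane = np.zeros((2, 300, 96), dtype=complex)
        with pytest.raises(ValueError):
            net.zero_fill_input([plane, plane])


class TestFourierStage:
    def test_adjoint_identity(self, rng):
        # <spectrum(x), g> == <x, adjoint(g)> for the packed transform
        x = rng.standard_normal((400, 512))
        gre = rng.standard_normal((512, 400))
        gim = rng.standard_normal((512, 400))
        spec = net.spectrum_from_packed(x)
        lhs = np.sum(spec.real * gre) + np.sum(spec.imag * gim)
        rhs = np.sum(x * net._spectrum_grad_to_packed(gre, gim))
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_apodize_self_adjoint(self, rng):
        p = rng.standard_normal((512, 400))
        q = rng.standard_normal((512, 400))
        assert np.sum(net.apodize_spectrum(p) * q) == pytest.approx(
            np.sum(p * net.apodize_spectrum(q)), rel=1e-10
        )


class TestConvGradients:
    def test_numerical_gradients(self, rng):
        conv = net.Conv2D(2, 3, 3, rng)
        x = rng.standard_normal((2, 9, 7))
        dy = rng.standard_normal((3, 9, 7))
        conv.forward(x)
        dx = conv.backward(dy)
        eps = 1e-6
        for idx in [(0, 2, 3), (1, 8, 0)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = ((conv.forward(xp) * dy).sum() - (conv.forward(xm) * dy).sum()) / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=1e-6, abs=1e-9)
        for widx in [(0, 1, 0, 0), (2, 0, 2, 1)]:
            orig = conv.W[widx]
            conv.W[widx] = orig + eps
            fp = (conv.forward(x) * dy).sum()
            conv.W[widx] = orig - eps
            fm = (conv.forward(x) * dy).sum()
            conv.W[widx] = orig
            conv.gW[...] = 0.0
            conv.forward(x)
            conv.backward(dy)
            assert conv.gW[widx] == pytest.approx((fp - fm) / (2 * eps), rel=1e-6, abs=1e-9)

    def test_bias_gradient(self, rng):
        conv = net.Conv2D(1, 2, 3, rng)
        x = rng.standard_normal((1, 5, 5))
        dy = rng.standard_normal((2, 5, 5))
        conv.forward(x)
        conv.backward(dy)
        assert conv.gb == pytest.approx(dy.sum(axis=(1, 2)))


class TestModelContracts:
    def test_output_shape_and_confidence_range(self, rng):
        model = net.build_model(_tiny_config())
        x = rng.standard_normal((2, 400, 512))
        out = model.output(x)
        assert out.shape == (512, 400, 2)
        assert np.all(out[..., 1] > 0) and np.all(out[..., 1] < 1)

    def test_sigma_bounds(self, rng):
        model = net.build_model(_tiny_config())
        _, conf = model.forward(rng.standard_normal((2, 400, 512)))
        sig = ob.sigma_from_confidence(conf)
        assert np.all(sig > ob.SIGMA_MIN) and np.all(sig < ob.SIGMA_MAX)

    def test_seeded_build_deterministic(self, rng):
        x = rng.standard_normal((2, 400, 512))
        a = net.build_model(_tiny_config(seed=11)).forward(x)
        b = net.build_model(_tiny_config(seed=11)).forward(x)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_bad_input_shape(self):
        model = net.build_model(_tiny_config())
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 100, 100)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            net.NetworkConfig(width=0.0)
        with pytest.raises(ValueError):
            net.NetworkConfig(depth=0)
        with pytest.raises(ValueError):
            net.NetworkConfig(kernel=4)

    def test_save_load_round_trip(self, rng, tmp_path):
        model = net.build_model(_tiny_config(seed=4))
        model.conf_bias[0] = 1.25
        path = tmp_path / "model.npz"
        model.save(path)
        clone = net.VDNet.load(path)
        x = rng.standard_normal((2, 400, 512))
        a, b = model.forward(x)
        c, d = clone.forward(x)
        assert np.array_equal(a, c) and np.array_equal(b, d)


class TestLossGradients:
    def test_full_chain_finite_difference(self, gen_config):
        model = net.build_model(_tiny_config(seed=1))
        sset = sim.generate_training_set(gen_config, 7)
        x, tspec, _ = net.prepare_set(sset)
        I0, C0 = model.forward(x)
        losses, d_int, d_conf = net._loss_and_grads(tspec, I0, C0)
        S = losses["scaling"]
        model.zero_grad()
        model.backward(d_int, d_conf)

        from scipy.special import expit

        def frozen_total():
            I, C = model.forward(x)
            p = net.apodize_spectrum(I)
            sig = 1.0 / (0.998 * expit(C) + 0.001) - 1.0
            l1 = float(np.mean((tspec - p) ** 2))
            return (2.0 - S) * l1 + S * (ob.loss2((tspec - p) / sig) + ob.loss3(tspec, p, sig))

        params = model.params()
        rng = np.random.default_rng(3)
        eps = 1e-6
        checked = 0
        # conv weights of both stages plus the intensity-gain scalar
        for pi in (0, 2, 4, 6, len(params) - 3):
            p, g = params[pi]
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                fp = frozen_total()
                p[idx] = orig - eps
                fm = frozen_total()
                p[idx] = orig
                num = (fp - fm) / (2 * eps)
                if abs(num) > 1e-10:
                    assert g[idx] == pytest.approx(num, rel=5e-2)
                    checked += 1
        assert checked >= 4


class TestTraining:
    def test_short_run_logs_schedule(self, gen_config):
        model = net.build_model(_tiny_config(seed=2))
        gen = iter([sim.generate_training_set(gen_config, 100 + i) for i in range(2)])
        log = net.train(model, gen, steps=2, lr_schedule=None)
        for entry in log:
            assert entry["lr"] == ob.learning_rate(entry["step"])
            assert np.isfinite(entry["total"])

    def test_nonfinite_loss_aborts(self, gen_config):
        model = net.build_model(_tiny_config(seed=2))
        sset = sim.generate_training_set(gen_config, 100)
        sset.input_nocoup[0, 0, 0] = np.nan

        def gen():
            while True:
                yield sset

        with pytest.raises(FloatingPointError):
            net.train(model, gen(), steps=1)


class TestInference:
    def test_deterministic(self, gen_config):
        model = net.build_model(_tiny_config())
        sset = sim.generate_training_set(gen_config, 55)
        a = net.infer(model, (sset.input_nocoup, sset.input_coup))
        b = net.infer(model, (sset.input_nocoup, sset.input_coup))
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.sigma, b.sigma)

    def test_null_input_no_hallucinated_peaks(self):
        model = net.build_model(_tiny_config())
        zero = np.zeros((2, 256, 200), dtype=complex)
        pred = net.infer(model, (zero, zero))
        assert np.all(np.abs(pred.intensity) <= 5 * pred.sigma)

    def test_sigma_positive(self, gen_config):
        model = net.build_model(_tiny_config())
        sset = sim.generate_training_set(gen_config, 56)
        pred = net.infer(model, (sset.input_nocoup, sset.input_coup))
        assert np.all(pred.sigma > 0)
        assert np.all((pred.confidence > 0) & (pred.confidence < 1))
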