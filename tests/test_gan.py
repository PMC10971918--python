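"""Adversarial reconstruction network: ops, architecture contracts, training."""

import numpy as np
import pytest

from cceit.gan import (Discriminator, DiscriminatorSpec, Generator, GeneratorSpec,
                       Standardizer, TrainConfig, batch_norm, leaky_relu,
                       linear_layer, mean_relative_error, train_cgan)
from cceit.gan import _BatchNorm, _bce_with_logits


class TestOps:
    def test_leaky_relu_positive_branch(self):
        assert leaky_relu(5.0, 0.2) == 5.0
        assert leaky_relu(5.0, 0.9) == 5.0

    def test_leaky_relu_negative_branch(self):
        assert leaky_relu(-2.0, 0.1) == pytest.approx(-0.2)

    def test_leaky_relu_alpha_one_is_identity(self, rng):
        x = rng.normal(size=50)
        assert np.allclose(leaky_relu(x, 1.0), x)

    def test_leaky_relu_rejects_negative_alpha(self):
        with pytest.raises(ValueError):
            leaky_relu(1.0, -0.1)

    def test_linear_layer_identity_and_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert np.allclose(linear_layer(x, np.eye(3), np.zeros(3)), x)
        b = np.array([4.0, 5.0])
        assert np.allclose(linear_layer(np.zeros(3), np.zeros((2, 3)), b), b)

    def test_linear_layer_matches_hand_computed_product(self, rng):
        x = rng.normal(size=(1, 2))
        W = rng.normal(size=(3, 2))
        b = rng.normal(size=3)
        expected = [sum(x[0, k] * W[j, k] for k in range(2)) + b[j] for j in range(3)]
        assert np.allclose(linear_layer(x, W, b)[0], expected)

    def test_linear_layer_shape_mismatch(self):
        with pytest.raises(ValueError):
            linear_layer(np.zeros(3), np.zeros((2, 4)), np.zeros(2))

    def test_batch_norm_at_running_mean_is_zero(self):
        x = np.array([1.5, -2.0, 0.3])
        out = batch_norm(x, W=1.0, b=0.0, running_mean=x, running_var=np.ones(3))
        assert np.allclose(out, 0.0)

    def test_batch_norm_unit_stats_scaling(self, rng):
        x = rng.normal(size=8)
        eps = 1e-5
        out = batch_norm(x, 1.0, 0.0, np.zeros(8), np.ones(8), eps)
        assert np.allclose(out, x / np.sqrt(1.0 + eps))

    def test_batch_statistics_path_matches_two_pass_oracle(self, rng):
        layer = _BatchNorm(4)
        x = rng.normal(size=(32, 4))
        out = layer.forward(x, training=True)
        mean = x.sum(axis=0) / 32.0
        var = ((x - mean) ** 2).sum(axis=0) / 32.0
        assert np.allclose(out, (x - mean) / np.sqrt(var + layer.eps))

    def test_mean_relative_error_limits(self, rng):
        y = rng.normal(size=100)
        assert mean_relative_error(y, y) == 0.0
        assert mean_relative_error(2 * y, y) == pytest.approx(1.0)
        e1 = np.zeros(100)
        e1[0] = np.linalg.norm(y)
        assert mean_relative_error(y + e1, y) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            mean_relative_error(y, np.zeros(100))


class TestArchitectureContracts:
    def test_generator_output_shape_and_range(self, rng):
        gen = Generator(GeneratorSpec(), rng_seed=0)
        x = rng.normal(size=(2, 240))
        img = gen.forward(x)
        assert img.shape == (64, 64)
        assert np.all((img >= 0) & (img <= 1)) and np.all(np.isfinite(img))

    def test_generator_deterministic_at_inference(self, rng):
        gen = Generator(GeneratorSpec(), rng_seed=0)
        x = rng.normal(size=(2, 240))
        assert np.array_equal(gen.forward(x), gen.forward(x))

    def test_batched_and_single_inputs_agree(self, rng):
        gen = Generator(GeneratorSpec(), rng_seed=0)
        x = rng.normal(size=(3, 2, 240))
        batch = gen.forward(x)
        assert batch.shape == (3, 64, 64)
        assert np.allclose(batch[1], gen.forward(x[1]))

    def test_only_first_layer_depends_on_input_length(self):
        """Going from the 16-electrode (2x240) to the 32-electrode (2x992)
        input changes only the entry layer's weight count."""
        s16 = Generator(GeneratorSpec(input_len=480), rng_seed=0).weight_shapes()
        s32 = Generator(GeneratorSpec(input_len=1984), rng_seed=0).weight_shapes()
        assert s16[0] != s32[0]
        assert s16[0][0] == s32[0][0]  # same width, different fan-in
        assert s16[1:] == s32[1:]
        d16 = Discriminator(DiscriminatorSpec(cond_len=480), rng_seed=0).weight_shapes()
        d32 = Discriminator(DiscriminatorSpec(cond_len=1984), rng_seed=0).weight_shapes()
        assert d16[0] != d32[0] and d16[1:] == d32[1:]

    def test_discriminator_outputs_probability(self, rng):
        disc = Discriminator(DiscriminatorSpec(), rng_seed=0)
        p = disc.forward(rng.uniform(0, 1, (5, 64, 64)), rng.normal(size=(5, 480)))
        assert p.shape == (5,)
        assert np.all((p >= 0) & (p <= 1))

    def test_discriminator_deterministic(self, rng):
        disc = Discriminator(DiscriminatorSpec(), rng_seed=0)
        img = np.zeros((64, 64))
        cond = np.zeros(480)
        assert disc.forward(img, cond) == disc.forward(img, cond)

    def test_wrong_input_length_raises(self, rng):
        gen = Generator(GeneratorSpec(), rng_seed=0)
        with pytest.raises(ValueError):
            gen.forward(rng.normal(size=(2, 100)))


class TestGradients:
    def test_generator_backward_matches_finite_differences(self, rng):
        """Full backprop check through dense + batch-norm + leaky-ReLU +
        sigmoid stack against central differences on a smooth loss."""
        spec = GeneratorSpec(input_len=6, hidden=(5, 4), out_shape=(2, 2), dtype="float64")
        gen = Generator(spec, rng_seed=1)
        x = rng.normal(size=(3, 6))
        R = rng.normal(size=(3, 4))

        def loss():
            return float((gen.net.forward(x, training=True) * R).sum())

        gen.net.zero_grad()
        gen.net.forward(x, training=True)
        gen.net.backward(R)
        eps = 1e-6
        for p, grad in gen.net.params():
            flat_idx = rng.integers(0, p.size, size=min(p.size, 5))
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grad[idx]) < 1e-6 + 1e-4 * abs(fd)

    def test_discriminator_backward_matches_finite_differences(self, rng):
        spec = DiscriminatorSpec(image_shape=(2, 2), cond_len=6, hidden=(5, 3), dtype="float64")
        disc = Discriminator(spec, rng_seed=2)
        img = rng.uniform(0, 1, (3, 2, 2))
        cond = rng.normal(size=(3, 6))

        def loss():
            z = disc.forward_logits(img, cond, training=True)
            return _bce_with_logits(z, 1.0)[0]

        disc.net.zero_grad()
        z = disc.forward_logits(img, cond, training=True)
        _, gz = _bce_with_logits(z, 1.0)
        disc.net.backward(gz.reshape(-1, 1))
        eps = 1e-6
        for p, grad in disc.net.params():
            for fi in rng.integers(0, p.size, size=min(p.size, 5)):
                idx = np.unravel_index(fi, p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grad[idx]) < 1e-6 + 1e-4 * abs(fd)


class TestTraining:
    def test_single_sample_overfit(self, rng):
        """The generator can drive L1 loss below 0.05 on one sample within
        500 steps (capacity / optimisation sanity)."""
        from cceit.gan import _Adam

        gen = Generator(GeneratorSpec(), rng_seed=0)
        opt = _Adam(gen.net.params(), 1e-3)
        x = rng.standard_normal((1, 480))
        y = rng.uniform(0, 1, (1, 4096))
        final = np.inf
        for step in range(500):
            gen.net.zero_grad()
            out = gen.net.forward(x, training=True)
            gen.net.backward(np.sign(out - y) / out.size)
            opt.step()
            if step % 25 == 24:
                final = np.abs(gen.net.forward(x, training=True) - y).mean()
                if final < 0.05:
                    break
        assert final < 0.05

    @pytest.fixture(scope="class")
    def toy_data(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(40, 2, 240))
        y = rng.uniform(0, 1, (40, 64, 64)).astype(np.float32)
        return x[:32], y[:32], x[32:], y[32:]

    def test_smoke_training_runs_and_logs(self, toy_data):
        xtr, ytr, xte, yte = toy_data
        cfg = TrainConfig(epochs=2, batch_size=8, snr_db=np.inf, seed=0)
        gen, disc, log = train_cgan(xtr, ytr, xte, yte, cfg)
        assert len(log.test_ie) == 2
        assert len(log.generator_loss) == 2
        assert all(np.isfinite(v) for v in log.generator_loss + log.discriminator_loss)

    def test_training_is_reproducible(self, toy_data):
        xtr, ytr, xte, yte = toy_data
        cfg = TrainConfig(epochs=1, batch_size=8, snr_db=30.0, seed=3)
        g1, _, l1 = train_cgan(xtr, ytr, xte, yte, cfg)
        g2, _, l2 = train_cgan(xtr, ytr, xte, yte, cfg)
        assert l1.test_ie == l2.test_ie
        for (pa, _), (pb, _) in zip(g1.net.params(), g2.net.params()):
            assert np.array_equal(pa, pb)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_generator=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_standardizer_fits_on_train_only(self, toy_data):
        xtr, _, xte, _ = toy_data
        std = Standardizer.fit(xtr)
        z = std(xtr)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert not np.allclose(std(xte).mean(axis=0), 0.0, atol=1e-3)


class TestCheckpointing:
    def test_roundtrip(self, tmp_path, rng):
        from cceit.gan import load_checkpoint

        x = rng.normal(size=(16, 2, 240))
        y = rng.uniform(0, 1, (16, 64, 64)).astype(np.float32)
        cfg = TrainConfig(epochs=1, batch_size=8, snr_db=np.inf, seed=0)
        gen, disc, _ = train_cgan(x[:12], y[:12], x[12:], y[12:], cfg,
                                  out_dir=tmp_path)
        gen2, disc2, std = load_checkpoint(tmp_path)
        probe = rng.normal(size=(2, 2, 240))
        assert np.allclose(gen.forward(std(probe).reshape(2, -1)),
                           gen2.forward(std(probe).reshape(2, -1)))
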