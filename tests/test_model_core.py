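"""Loss oracles, generator contracts, and checkpoint persistence."""

import numpy as np
import pytest
from scipy.signal import correlate

from singanseg._autodiff import Tensor, mul, sum_
from singanseg._nn import Discriminator, Generator
from singanseg.model_core import (
    CheckpointError,
    ScaleModelConfig,
    TrainConfig,
    compute_noise_amplitude,
    critic_losses,
    generator_forward,
    gradient_penalty,
    init_scale_models,
    load_checkpoint,
    reconstruction_loss,
    save_checkpoint,
    width_at,
)

from conftest import numeric_grad


# ---------------------------------------------------------------------------
# independent critic oracle (scipy convolutions, no autodiff)
# ---------------------------------------------------------------------------

def _oracle_conv(x, w, b):
    out = np.stack(
        [
            sum(correlate(x[c], w[o, c], mode="valid") for c in range(x.shape[0])) + b[o]
            for o in range(w.shape[0])
        ]
    )
    return out


def _oracle_norm(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def _oracle_lrelu(x, s=0.2):
    return np.where(x >= 0, x, s * x)


def _oracle_disc_forward(sd, x, n_body):
    x = _oracle_lrelu(_oracle_conv(x, sd["head.conv.weight"], sd["head.conv.bias"]))
    for i in range(n_body):
        x = _oracle_conv(x, sd[f"body.{i}.conv.weight"], sd[f"body.{i}.conv.bias"])
        x = _oracle_norm(x, sd[f"body.{i}.norm.gamma"], sd[f"body.{i}.norm.beta"])
        x = _oracle_lrelu(x)
    return _oracle_conv(x, sd["tail.weight"], sd["tail.bias"])


def _f64_disc(seed=0, width=8, n_blocks=3):
    disc = Discriminator(4, width, n_blocks, 3, np.random.default_rng(seed))
    for p in disc.parameters():
        p.data = p.data.astype(np.float64)
    return disc


class _LinearCritic:
    """f(x) = c * sum(x) / sqrt(d): analytic gradient norm c everywhere."""

    def __init__(self, c, shape):
        d = int(np.prod(shape))
        self.w = Tensor(np.full(shape, c / np.sqrt(d)), requires_grad=True)

    def __call__(self, x):
        return sum_(mul(self.w, x))

    def parameters(self):
        return [self.w]


class TestGradientPenalty:
    def test_unit_gradient_critic_penalty_exactly_zero(self):
        rng = np.random.default_rng(0)
        real = rng.normal(size=(4, 8, 8))
        fake = rng.normal(size=(4, 8, 8))
        p = gradient_penalty(_LinearCritic(1.0, real.shape), real, fake, 0.1,
                             np.random.default_rng(1))
        assert float(p.data) == 0.0

    def test_gradient_norm_two_penalty_hand_value(self):
        rng = np.random.default_rng(0)
        real = rng.normal(size=(4, 8, 8))
        fake = rng.normal(size=(4, 8, 8))
        p = gradient_penalty(_LinearCritic(2.0, real.shape), real, fake, 0.1,
                             np.random.default_rng(1))
        assert float(p.data) == pytest.approx(0.1, abs=1e-6)

    def test_penalty_independent_of_interpolation_when_real_equals_fake(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 8, 8))
        disc = _f64_disc(5)
        vals = [
            float(gradient_penalty(disc, x, x, 0.1, np.random.default_rng(s)).data)
            for s in range(4)
        ]
        assert np.ptp(vals) < 1e-12

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            gradient_penalty(_f64_disc(), np.zeros((4, 8, 8)), np.zeros((4, 6, 6)),
                             0.1, np.random.default_rng(0))

    def test_matches_numeric_gradient_oracle(self):
        rng = np.random.default_rng(3)
        real = rng.normal(size=(4, 8, 8))
        fake = rng.normal(size=(4, 8, 8))
        disc = _f64_disc(7)
        sd = disc.state_dict()
        gp_seed = 11
        p = gradient_penalty(disc, real, fake, 0.1, np.random.default_rng(gp_seed))

        eps = np.random.default_rng(gp_seed).uniform()
        xhat = (eps * real + (1 - eps) * fake).astype(np.float64)
        g = numeric_grad(lambda a: float(_oracle_disc_forward(sd, a, 1).sum()), xhat)
        expected = 0.1 * (np.linalg.norm(g.ravel()) - 1.0) ** 2
        assert float(p.data) == pytest.approx(expected, abs=1e-6)


class TestCriticLosses:
    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(4)
        real = rng.normal(size=(4, 8, 8))
        fake = rng.normal(size=(4, 8, 8))
        disc = _f64_disc(9)
        sd = disc.state_dict()
        gp_seed = 13
        d_loss, g_adv = critic_losses(disc, real, fake, 0.1, np.random.default_rng(gp_seed))

        o_fake = _oracle_disc_forward(sd, fake, 1)
        o_real = _oracle_disc_forward(sd, real, 1)
        eps = np.random.default_rng(gp_seed).uniform()
        xhat = eps * real + (1 - eps) * fake
        g = numeric_grad(lambda a: float(_oracle_disc_forward(sd, a, 1).sum()), xhat)
        gp = 0.1 * (np.linalg.norm(g.ravel()) - 1.0) ** 2
        assert float(d_loss.data) == pytest.approx(
            o_fake.mean() - o_real.mean() + gp, abs=1e-6
        )
        assert float(g_adv.data) == pytest.approx(-o_fake.mean(), abs=1e-9)

    def test_constant_critic(self):
        rng = np.random.default_rng(5)
        real = rng.normal(size=(4, 8, 8))
        fake = rng.normal(size=(4, 8, 8))

        class Const:
            def __call__(self, x):
                return Tensor(np.array(3.5))

        d_loss, g_adv = critic_losses(Const(), real, fake, 0.1, np.random.default_rng(0))
        # fake/real terms cancel; penalty is gp_weight * (0 - 1)^2 for a
        # zero-gradient critic
        assert float(d_loss.data) == pytest.approx(0.1)
        assert float(g_adv.data) == pytest.approx(-3.5)


class TestReconstructionLoss:
    def test_identical_grids_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 6, 6))
        assert reconstruction_loss(x, x, 10.0) == 0.0

    def test_constant_offset_hand_value(self):
        x = np.zeros((4, 5, 5))
        assert reconstruction_loss(x + 0.1, x, 10.0) == pytest.approx(0.1)

    def test_mask_channel_participates(self):
        x = np.zeros((4, 5, 5))
        y = x.copy()
        y[3] += 0.5
        assert reconstruction_loss(y, x, 10.0) > 0


class TestNoiseAmplitude:
    def test_coarsest_scale_is_one(self):
        assert compute_noise_amplitude(0, None, np.zeros((4, 5, 5)), 0.1) == 1.0

    def test_perfect_reconstruction_zero(self):
        x = np.random.default_rng(1).normal(size=(4, 5, 5))
        assert compute_noise_amplitude(2, x, x, 0.1) == 0.0

    def test_constant_offset_rmse(self):
        x = np.zeros((4, 5, 5))
        assert compute_noise_amplitude(1, x + 0.2, x, 0.1) == pytest.approx(0.02)


class TestGenerator:
    def test_identity_on_prior_with_zero_tail(self):
        rng = np.random.default_rng(6)
        gen = Generator(4, 8, 5, 3, rng)
        gen.zero_init_tail()
        prior = rng.uniform(-1, 1, (4, 20, 20)).astype(np.float32)
        noise = rng.normal(size=(4, 20, 20)).astype(np.float32)
        out = generator_forward(gen, noise, prior)
        assert np.array_equal(out, prior)

    def test_output_four_channels_and_bounded(self):
        rng = np.random.default_rng(7)
        gen = Generator(4, 8, 5, 3, rng)
        out = generator_forward(gen, rng.normal(size=(4, 16, 16)).astype(np.float32))
        assert out.shape == (4, 16, 16)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_deterministic_given_inputs(self):
        rng = np.random.default_rng(8)
        gen = Generator(4, 8, 5, 3, rng)
        noise = rng.normal(size=(4, 16, 16)).astype(np.float32)
        a = generator_forward(gen, noise)
        b = generator_forward(gen, noise)
        assert np.array_equal(a, b)

    def test_misaligned_shapes_raise(self):
        gen = Generator(4, 8, 5, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            generator_forward(gen, np.zeros((4, 16, 16)), np.zeros((4, 12, 12)))


class TestInitScaleModels:
    CFG = ScaleModelConfig(base_channels=8, channel_growth_every=2)

    def test_width_schedule(self):
        assert [width_at(i, self.CFG) for i in range(5)] == [8, 8, 16, 16, 32]

    def test_warm_start_same_width_copies_weights(self):
        rng = np.random.default_rng(0)
        g0, d0 = init_scale_models(0, (20, 20), self.CFG, rng)
        g1, d1 = init_scale_models(1, (24, 24), self.CFG, rng, prev_gen=g0, prev_disc=d0)
        for k, v in g0.state_dict().items():
            assert np.array_equal(v, g1.state_dict()[k])

    def test_width_doubling_reinitializes_randomly(self):
        rng = np.random.default_rng(0)
        g1, d1 = init_scale_models(1, (20, 20), self.CFG, rng)
        g2, d2 = init_scale_models(2, (24, 24), self.CFG, rng, prev_gen=g1, prev_disc=d1)
        # widths differ, so no weight of g1 can have been copied
        assert g2.state_dict()["head.conv.weight"].shape[0] == 16
        assert g1.state_dict()["head.conv.weight"].shape[0] == 8

    def test_too_small_level_raises(self):
        with pytest.raises(ValueError):
            init_scale_models(0, (8, 8), ScaleModelConfig(), np.random.default_rng(0))


class TestTraining:
    def test_history_shows_reconstruction_improvement(self, tiny_bundle):
        for scale_hist in tiny_bundle.history:
            assert scale_hist[-1]["recon_mse"] < scale_hist[0]["recon_mse"]

    def test_sigma_layout(self, tiny_bundle):
        assert tiny_bundle.sigmas[0] == 1.0
        assert all(s > 0 for s in tiny_bundle.sigmas)
        assert len(tiny_bundle.sigmas) == tiny_bundle.n_scales

    def test_same_seed_identical_checkpoints(self, toy_pyramid):
        from singanseg.model_core import train_pyramid

        cfg = TrainConfig(epochs_per_scale=2, seed=42)
        scfg = ScaleModelConfig(base_channels=8)
        b1 = train_pyramid(toy_pyramid, scfg, cfg)
        b2 = train_pyramid(toy_pyramid, scfg, cfg)
        for s1, s2 in zip(b1.gen_states, b2.gen_states):
            for k in s1:
                assert np.array_equal(s1[k], s2[k]), k


class TestCheckpointRoundTrip:
    def test_round_trip_preserves_generation(self, tiny_bundle, tmp_path):
        from singanseg.sampling import GenerationRequest, generate_samples

        save_checkpoint(tiny_bundle, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        a = generate_samples(GenerationRequest(tiny_bundle, n_samples=2, seed=7))
        b = generate_samples(GenerationRequest(loaded, n_samples=2, seed=7))
        for x, y in zip(a, b):
            assert np.array_equal(x.grid, y.grid)

    def test_missing_scale_raises(self, tiny_bundle, tmp_path):
        save_checkpoint(tiny_bundle, tmp_path / "ckpt")
        (tmp_path / "ckpt" / "scale_0001.npz").unlink()
        with pytest.raises(CheckpointError):
            load_checkpoint(tmp_path / "ckpt")

    def test_version_mismatch_raises(self, tiny_bundle, tmp_path):
        import json

        save_checkpoint(tiny_bundle, tmp_path / "ckpt")
        meta = json.loads((tmp_path / "ckpt" / "meta.json").read_text())
        meta["version"] = 999
        (tmp_path / "ckpt" / "meta.json").write_text(json.dumps(meta))
        with pytest.raises(CheckpointError):
            load_checkpoint(tmp_path / "ckpt")

    def test_cross_process_reconstruction_identical(self, tiny_bundle, tmp_path):
        import subprocess
        import sys

        from singanseg.sampling import reconstruct

        save_checkpoint(tiny_bundle, tmp_path / "ckpt")
        rec = reconstruct(tiny_bundle)
        script = (
            "import sys, numpy as np\n"
            "from singanseg.model_core import load_checkpoint\n"
            "from singanseg.sampling import reconstruct\n"
            f"b = load_checkpoint(r'{tmp_path / 'ckpt'}')\n"
            f"np.save(r'{tmp_path / 'rec.npy'}', reconstruct(b).grid)\n"
        )
        subprocess.run([sys.executable, "-c", script], check=True)
        other = np.load(tmp_path / "rec.npy")
        assert np.array_equal(rec.grid, other)
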