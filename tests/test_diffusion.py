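"""Noise schedule, forward process, training objective, and the denoiser contract."""

import numpy as np
import pandas as pd
import pytest

from pdiff.autograd import Tensor
from pdiff.diffusion import (
    IdentityCodec,
    PoolCodec,
    TrainConfig,
    build_denoiser,
    forward_noise,
    load_checkpoint,
    make_schedule,
    save_checkpoint,
    train,
    training_loss,
)
from pdiff.diffusion.training import min_snr_weight
from pdiff.synthetic import Phenotype, make_dataset, render_field, sample_library


class TestSchedule:
    def test_single_step_alpha_bar(self):
        s = make_schedule(T=1, beta_start=0.1, beta_end=0.1)
        assert s.alpha_bars[1] == pytest.approx(0.9)
        assert s.alpha_bars[0] == 1.0

    def test_linear_endpoints_match_config(self):
        s = make_schedule(T=100, beta_start=1e-3, beta_end=0.02)
        assert s.betas[0] == pytest.approx(1e-3)
        assert s.betas[-1] == pytest.approx(0.02)

    def test_default_schedule_ends_deep_in_noise(self):
        s = make_schedule()
        # pinned product of (1 - beta_t) for the default linear schedule
        assert s.alpha_bars[-1] == pytest.approx(1.579e-3, rel=1e-3)
        assert np.all(np.diff(s.alpha_bars) < 0)

    def test_non_monotone_request_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            make_schedule(T=10, beta_start=0.02, beta_end=0.001)


class TestForwardNoise:
    def test_low_t_keeps_signal(self):
        s = make_schedule(T=10, beta_start=1e-8, beta_end=1e-7)
        z0 = np.ones((2, 1, 2, 2))
        zt = forward_noise(z0, 1, np.zeros_like(z0), s)
        np.testing.assert_allclose(zt, z0, rtol=1e-6)

    def test_deep_noise_limit_returns_eps(self):
        s = make_schedule(T=500, beta_start=0.05, beta_end=0.2)
        z0 = np.full((1, 1, 2, 2), 5.0)
        eps = np.random.default_rng(0).standard_normal(z0.shape)
        zt = forward_noise(z0, 500, eps, s)
        np.testing.assert_allclose(zt, eps, atol=1e-4)

    def test_marginal_variance_matches_closed_form(self):
        s = make_schedule(T=100)
        t = 60
        rng = np.random.default_rng(1)
        z0 = np.zeros((10_000, 1, 1, 1))
        eps = rng.standard_normal(z0.shape)
        zt = forward_noise(z0, t, eps, s)
        target = 1 - s.alpha_bars[t]
        assert zt.var() == pytest.approx(target, rel=0.05)

    def test_shape_mismatch_rejected(self):
        s = make_schedule(T=10)
        with pytest.raises(ValueError, match="shape"):
            forward_noise(np.zeros((2, 1, 2, 2)), 1, np.zeros((1, 1, 2, 2)), s)


class _TrueNoiseOracle:
    """Recovers the exact eps from (z_t, t) given the known constant z0."""

    def __init__(self, z0, schedule):
        self.z0 = z0
        self.schedule = schedule
        self._last_t = None

    def forward_tensor(self, z_t, t, cond):
        ab = self.schedule.alpha_bar(np.asarray(t)).reshape(-1, 1, 1, 1)
        return Tensor((z_t.data - np.sqrt(ab) * self.z0) / np.sqrt(1 - ab))


class _ZeroModel:
    def forward_tensor(self, z_t, t, cond):
        return Tensor(np.zeros_like(z_t.data))


class TestTrainingLoss:
    def test_perfect_oracle_has_zero_loss(self):
        s = make_schedule(T=50)
        z0 = np.random.default_rng(2).standard_normal((8, 1, 2, 2))
        cfg = TrainConfig(steps=1, offset_noise_scale=0.0, cond_dropout_p=0.0, seed=0)
        model = _TrueNoiseOracle(z0, s)
        loss = training_loss(z0, np.zeros((8, 4)), model, s, cfg, np.random.default_rng(3))
        assert loss.item() == pytest.approx(0.0, abs=1e-18)

    def test_infinite_gamma_reduces_to_plain_mse(self):
        s = make_schedule(T=50)
        z0 = np.random.default_rng(2).standard_normal((16, 1, 2, 2))
        base = dict(steps=1, offset_noise_scale=0.0, cond_dropout_p=0.0, seed=0)
        l_inf = training_loss(
            z0, np.zeros((16, 4)), _ZeroModel(), s,
            TrainConfig(minsnr_gamma=np.inf, **base), np.random.default_rng(5),
        )
        # identical rng stream: the only difference is the per-step weight
        rng = np.random.default_rng(5)
        t = rng.integers(1, 51, size=16)
        eps = rng.standard_normal(z0.shape)
        plain = (eps.reshape(16, -1) ** 2).sum(axis=1).mean()
        assert l_inf.item() == pytest.approx(plain)

    def test_zero_model_matches_closed_form_expectation(self):
        """E[loss] for the zero predictor is mean_t w(t) * d (+ offset term)."""
        s = make_schedule(T=8, beta_start=0.01, beta_end=0.3)
        d = 4
        cfg = TrainConfig(minsnr_gamma=5.0, offset_noise_scale=0.0,
                          cond_dropout_p=0.0, seed=0)
        w = min_snr_weight(s.snr(np.arange(1, 9)), 5.0)
        expected = w.mean() * d
        rng = np.random.default_rng(11)
        vals = [
            training_loss(np.zeros((64, 1, 2, 2)), np.zeros((64, 2)), _ZeroModel(),
                          s, cfg, rng).item()
            for _ in range(60)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(expected, abs=4 * se)

    def test_offset_noise_inflates_zero_model_loss(self):
        s = make_schedule(T=8)
        rng_a, rng_b = np.random.default_rng(1), np.random.default_rng(1)
        z0 = np.zeros((256, 2, 2, 2))
        cond = np.zeros((256, 2))
        quiet = training_loss(z0, cond, _ZeroModel(), s,
                              TrainConfig(offset_noise_scale=0.0, cond_dropout_p=0.0,
                                          seed=0), rng_a)
        loud = training_loss(z0, cond, _ZeroModel(), s,
                             TrainConfig(offset_noise_scale=0.5, cond_dropout_p=0.0,
                                         seed=0), rng_b)
        assert loud.item() > quiet.item()

    def test_empty_batch_rejected(self):
        s = make_schedule(T=5)
        with pytest.raises(ValueError, match="empty"):
            training_loss(np.zeros((0, 1, 2, 2)), np.zeros((0, 2)), _ZeroModel(), s,
                          TrainConfig(seed=0), np.random.default_rng(0))


class TestDenoiser:
    def test_output_shape_matches_latent(self):
        model = build_denoiser((3, 8, 8), 16, "toy", seed=0)
        z = np.random.default_rng(0).standard_normal((4, 3, 8, 8))
        out = model(z, 10, np.zeros((4, 16)))
        assert out.shape == z.shape

    def test_profile_changes_prediction(self):
        model = build_denoiser((3, 8, 8), 16, "toy", seed=0)
        z = np.random.default_rng(1).standard_normal((1, 3, 8, 8))
        a = model(z, 5, np.zeros((1, 16)))
        b = model(z, 5, np.full((1, 16), 2.0))
        assert np.abs(a - b).max() > 0

    def test_toy_parameter_count_under_budget(self):
        model = build_denoiser((3, 8, 8), 64, "toy", seed=0)
        assert model.n_parameters() == 160_251  # pinned once
        assert model.n_parameters() < 200_000

    def test_odd_latent_dims_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_denoiser((3, 7, 8), 16, "toy")

    def test_null_profile_accepted(self):
        model = build_denoiser((3, 8, 8), 16, "toy", seed=0)
        z = np.zeros((2, 3, 8, 8))
        assert model(z, 3, None).shape == z.shape


class TestPosteriorIdentity:
    def test_one_step_with_true_noise_recovers_posterior_mean(self):
        """DDPM update fed the exact eps reproduces the algebraic posterior mean."""
        s = make_schedule(T=100)
        rng = np.random.default_rng(3)
        z0 = rng.standard_normal((5, 1, 2, 2))
        eps = rng.standard_normal(z0.shape)
        t = 40
        ab_t, ab_prev = s.alpha_bars[t], s.alpha_bars[t - 1]
        zt = forward_noise(z0, t, eps, s)
        beta_eff = 1 - ab_t / ab_prev
        mean_update = (
            np.sqrt(ab_prev) * beta_eff / (1 - ab_t) * z0
            + np.sqrt(ab_t / ab_prev) * (1 - ab_prev) / (1 - ab_t) * zt
        )
        z0_hat = (zt - np.sqrt(1 - ab_t) * eps) / np.sqrt(ab_t)
        mean_from_eps = (
            np.sqrt(ab_prev) * beta_eff / (1 - ab_t) * z0_hat
            + np.sqrt(ab_t / ab_prev) * (1 - ab_prev) / (1 - ab_t) * zt
        )
        np.testing.assert_allclose(mean_from_eps, mean_update, atol=1e-5)


def _tiny_manifest(n_images=8, size=32, seed=0):
    lib = sample_library(1, 1, profile_width=8, seed=seed)
    return lib, make_dataset(lib, images_per_compound=n_images, train_images=n_images,
                             seed=seed + 1, image_size=size)


class TestTrain:
    def test_memorizes_single_compound(self):
        lib, manifest = _tiny_manifest()
        profiles = {c.compound_id: c.profile.values for c in lib}
        ckpt = train(
            manifest, profiles,
            TrainConfig(steps=120, batch_size=8, lr=3e-3, seed=0),
            codec=PoolCodec(factor=8), schedule=make_schedule(T=200),
            size_preset="toy", log_every=10,
        )
        assert ckpt.loss_history[-1] < ckpt.loss_history[0] / 3

    def test_training_is_deterministic_given_seed(self):
        lib, manifest = _tiny_manifest(n_images=4)
        profiles = {c.compound_id: c.profile.values for c in lib}
        kw = dict(codec=PoolCodec(factor=8), schedule=make_schedule(T=100),
                  size_preset="toy")
        a = train(manifest, profiles, TrainConfig(steps=10, batch_size=4, seed=3), **kw)
        b = train(manifest, profiles, TrainConfig(steps=10, batch_size=4, seed=3), **kw)
        for k in a.state:
            assert np.array_equal(a.state[k], b.state[k])

    def test_missing_profile_error_lists_compounds(self):
        lib, manifest = _tiny_manifest(n_images=2)
        with pytest.raises(ValueError, match=lib[0].compound_id):
            train(manifest, {}, TrainConfig(steps=1, seed=0), codec=IdentityCodec())

    def test_checkpoint_round_trip(self, tmp_path):
        lib, manifest = _tiny_manifest(n_images=4)
        profiles = {c.compound_id: c.profile.values for c in lib}
        ckpt = train(manifest, profiles, TrainConfig(steps=5, batch_size=4, seed=1),
                     codec=PoolCodec(factor=8), schedule=make_schedule(T=50),
                     size_preset="toy")
        path = tmp_path / "ckpt.npz"
        save_checkpoint(ckpt, path)
        back = load_checkpoint(path)
        assert back.conditioning_width == ckpt.conditioning_width
        assert back.schedule_spec == ckpt.schedule_spec
        for k in ckpt.state:
            assert np.array_equal(back.state[k], ckpt.state[k])
        np.testing.assert_allclose(back.profile_mean, ckpt.profile_mean)
        model = back.build_model()
        z = np.zeros((1,) + tuple(back.latent_shape))
        assert model(z, 1, None).shape == z.shape
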