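"""Ancestral (DDPM) sampling with classifier-free guidance.

Sampling starts from pure Gaussian noise in the latent space and walks the
reverse chain.  At each step the network is evaluated twice — once with the
compound's profile, once with the null profile — and the two predictions are
combined as

    eps_guided = (1 + w) * eps(z_t, c) - w * eps(z_t, null)

where ``w`` is the guidance scale (0 disables guidance).  The sampler may use
fewer steps than the training schedule by striding the timestep sequence; the
posterior update then uses the effective alpha between visited steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codec import LatentCodec
from .schedule import DiffusionSchedule
from .training import Checkpoint

__all__ = ["GuidanceConfig", "cfg_noise", "sample_timesteps", "ddpm_sample", "generate"]

DEFAULT_GUIDANCE_W = 4.0
DEFAULT_SAMPLER_STEPS = 100
DEFAULT_IMAGES_PER_COMPOUND = 12


@dataclass(frozen=True)
class GuidanceConfig:
    w: float = DEFAULT_GUIDANCE_W
    steps: int = DEFAULT_SAMPLER_STEPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("sampler steps must be >= 1")


def cfg_noise(eps_cond: np.ndarray, eps_uncond: np.ndarray, w: float) -> np.ndarray:
    """Classifier-free-guided noise: (1+w)*eps_cond - w*eps_uncond."""
    eps_cond = np.asarray(eps_cond)
    eps_uncond = np.asarray(eps_uncond)
    if eps_cond.shape != eps_uncond.shape:
        raise ValueError(
            f"shape mismatch: cond {eps_cond.shape} vs uncond {eps_uncond.shape}"
        )
    return (1.0 + w) * eps_cond - w * eps_uncond


def sample_timesteps(T: int, steps: int) -> np.ndarray:
    """Strictly decreasing timestep subsequence from T toward 1."""
    if steps > T:
        raise ValueError(f"sampler steps ({steps}) exceed schedule length ({T})")
    ts = np.unique(np.round(np.linspace(T, 1, steps)).astype(int))[::-1]
    return ts


def ddpm_sample(
    model,
    profile: np.ndarray,
    schedule: DiffusionSchedule,
    guidance: GuidanceConfig,
    n_images: int,
    codec: LatentCodec,
    latent_shape: tuple[int, int, int],
    seed: int | None = None,
) -> np.ndarray:
    """Generate images for one profile (or a stack of profiles).

    ``profile`` of shape (width,) yields (n_images, H, W, 3); shape
    (M, width) yields (M, n_images, H, W, 3), all M trajectories advanced in
    one batch.  Given the same seed the output is bit-reproducible.
    """
    profile = np.asarray(profile, dtype=np.float64)
    single = profile.ndim == 1
    profs = profile[None] if single else profile
    m = len(profs)
    rng = np.random.default_rng(guidance.seed if seed is None else seed)
    ts = sample_timesteps(schedule.T, guidance.steps)

    b = m * n_images
    cond = np.repeat(profs, n_images, axis=0)
    z = rng.standard_normal((b,) + tuple(latent_shape))
    for i, t in enumerate(ts):
        t_prev = int(ts[i + 1]) if i + 1 < len(ts) else 0
        eps_c = model(z, int(t), cond)
        if guidance.w != 0.0:
            eps_u = model(z, int(t), None)
            eps = cfg_noise(eps_c, eps_u, guidance.w)
        else:
            eps = eps_c
        ab_t = schedule.alpha_bar(int(t))
        ab_prev = schedule.alpha_bar(t_prev)
        z0_hat = (z - np.sqrt(1.0 - ab_t) * eps) / np.sqrt(ab_t)
        alpha_eff = ab_t / ab_prev
        beta_eff = 1.0 - alpha_eff
        mean = (
            np.sqrt(ab_prev) * beta_eff / (1.0 - ab_t) * z0_hat
            + np.sqrt(alpha_eff) * (1.0 - ab_prev) / (1.0 - ab_t) * z
        )
        if t_prev > 0:
            var = beta_eff * (1.0 - ab_prev) / (1.0 - ab_t)
            z = mean + np.sqrt(var) * rng.standard_normal(z.shape)
        else:
            z = mean
    images = codec.decode(z)
    images = images.reshape((m, n_images) + images.shape[1:])
    return images[0] if single else images


def generate(
    ckpt: Checkpoint,
    profiles: dict[str, np.ndarray],
    n_images: int = DEFAULT_IMAGES_PER_COMPOUND,
    guidance: GuidanceConfig | None = None,
    seed: int | None = None,
    batch_compounds: int = 8,
) -> dict[str, np.ndarray]:
    """Generate ``n_images`` images per compound from a trained checkpoint.

    Profiles are standardized with the statistics stored at training time.
    Returns {compound_id: (n_images, H, W, 3)}.  Compounds are processed in
    batches purely for speed; each compound's noise stream is derived from a
    per-compound seed so results do not depend on the batching.
    """
    if guidance is None:
        guidance = GuidanceConfig()
    model = ckpt.build_model()
    schedule = ckpt.build_schedule()
    codec = ckpt.build_codec()
    base_seed = guidance.seed if seed is None else seed
    ids = sorted(profiles)
    raw = np.stack([np.asarray(profiles[i], dtype=np.float64) for i in ids])
    cond = ckpt.standardize(raw)
    out: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(base_seed)
    comp_seeds = ss.generate_state(len(ids))
    for start in range(0, len(ids), batch_compounds):
        chunk = slice(start, start + batch_compounds)
        chunk_ids = ids[chunk]
        # one batch, but per-compound reproducible streams: stack noise drawn
        # from each compound's own generator
        imgs = _sample_chunk(
            model, cond[chunk], schedule, guidance, n_images, codec,
            tuple(ckpt.latent_shape), comp_seeds[chunk],
        )
        for cid, im in zip(chunk_ids, imgs):
            out[cid] = im
    return out


def _sample_chunk(model, profs, schedule, guidance, n_images, codec, latent_shape, seeds):
    rngs = [np.random.default_rng(int(s)) for s in seeds]
    m = len(profs)
    b = m * n_images
    cond = np.repeat(profs, n_images, axis=0)
    ts = sample_timesteps(schedule.T, guidance.steps)
    z = np.concatenate([r.standard_normal((n_images,) + latent_shape) for r in rngs])
    for i, t in enumerate(ts):
        t_prev = int(ts[i + 1]) if i + 1 < len(ts) else 0
        eps_c = model(z, int(t), cond)
        if guidance.w != 0.0:
            eps_u = model(z, int(t), None)
            eps = cfg_noise(eps_c, eps_u, guidance.w)
        else:
            eps = eps_c
        ab_t = schedule.alpha_bar(int(t))
        ab_prev = schedule.alpha_bar(t_prev)
        z0_hat = (z - np.sqrt(1.0 - ab_t) * eps) / np.sqrt(ab_t)
        alpha_eff = ab_t / ab_prev
        beta_eff = 1.0 - alpha_eff
        mean = (
            np.sqrt(ab_prev) * beta_eff / (1.0 - ab_t) * z0_hat
            + np.sqrt(alpha_eff) * (1.0 - ab_prev) / (1.0 - ab_t) * z
        )
        if t_prev > 0:
            var = beta_eff * (1.0 - ab_prev) / (1.0 - ab_t)
            noise = np.concatenate(
                [r.standard_normal((n_images,) + latent_shape) for r in rngs]
            )
            z = mean + np.sqrt(var) * noise
        else:
            z = mean
    images = codec.decode(z)
    return images.reshape((m, n_images) + images.shape[1:])
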