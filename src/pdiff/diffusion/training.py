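"""Training: the noise-prediction objective and the optimization loop.

The loss is the mean squared error between the true noise eps drawn for the
forward process and the network's prediction eps_theta(z_t, t, c), with three
standard refinements:

* min-SNR weighting — each sample's squared error is scaled by
  min(SNR_t, gamma) / SNR_t with SNR_t = alpha_bar_t / (1 - alpha_bar_t),
  which downweights very-low-noise steps and speeds convergence;
* offset noise — a per-image-channel constant N(0,1) draw scaled by
  ``offset_noise_scale`` is added to eps so the model can reach very dark or
  empty fields;
* conditioning dropout — with probability ``cond_dropout_p`` the profile is
  replaced by the null (all-zero) profile, training the unconditional branch
  that classifier-free guidance needs at inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ..autograd import Tensor
from ..nn import Adam
from ..profiles import standardize_profiles
from .codec import LatentCodec, PCACodec, build_codec
from .denoiser import Denoiser, build_denoiser
from .schedule import DiffusionSchedule, forward_noise, make_schedule

__all__ = ["TrainConfig", "Checkpoint", "training_loss", "train", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    steps: int = 600
    batch_size: int = 16
    lr: float = 2e-3
    minsnr_gamma: float = 5.0
    offset_noise_scale: float = 0.1
    cond_dropout_p: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cond_dropout_p < 1.0:
            raise ValueError("cond_dropout_p must be in [0, 1)")
        for name in ("steps", "batch_size", "lr", "minsnr_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.offset_noise_scale < 0:
            raise ValueError("offset_noise_scale must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory: training must be reproducible")


def min_snr_weight(snr: np.ndarray, gamma: float) -> np.ndarray:
    return np.minimum(snr, gamma) / snr


def training_loss(
    z0: np.ndarray,
    cond: np.ndarray,
    model: Denoiser,
    schedule: DiffusionSchedule,
    config: TrainConfig,
    rng: np.random.Generator,
) -> Tensor:
    """One stochastic evaluation of the weighted noise-prediction loss.

    Returns the mean over the batch of min_snr_weight(t) * ||eps - eps_hat||^2
    (squared L2 over all latent entries of each sample).
    """
    z0 = np.asarray(z0, dtype=np.float64)
    if len(z0) == 0:
        raise ValueError("empty batch")
    b = len(z0)
    t = rng.integers(1, schedule.T + 1, size=b)
    eps = rng.standard_normal(z0.shape)
    if config.offset_noise_scale > 0:
        eta = rng.standard_normal((b, z0.shape[1]) + (1,) * (z0.ndim - 2))
        eps = eps + config.offset_noise_scale * eta
    cond = np.array(cond, dtype=np.float64, copy=True)
    if config.cond_dropout_p > 0:
        drop = rng.random(b) < config.cond_dropout_p
        cond[drop] = 0.0
    z_t = forward_noise(z0, t, eps, schedule)

    pred = model.forward_tensor(Tensor(z_t), t, cond)
    weights = min_snr_weight(schedule.snr(t), config.minsnr_gamma)
    err = pred - Tensor(eps)
    per_sample = (err * err).sum(axis=tuple(range(1, z0.ndim)))
    loss = (per_sample * Tensor(weights)).mean()
    if not np.isfinite(loss.data):
        raise FloatingPointError(
            f"non-finite training loss at t={t.tolist()} (weights {weights.tolist()})"
        )
    return loss


@dataclass
class Checkpoint:
    """Everything needed to resume or sample: weights plus run provenance."""

    state: dict[str, np.ndarray]
    latent_shape: tuple[int, int, int]
    conditioning_width: int
    size_preset: str
    schedule_spec: dict
    codec_spec: dict
    codec_state: dict[str, np.ndarray] = field(default_factory=dict)
    profile_mean: np.ndarray | None = None
    profile_std: np.ndarray | None = None
    config: TrainConfig | None = None
    loss_history: list[float] = field(default_factory=list)
    model_seed: int = 0

    def build_model(self) -> Denoiser:
        model = build_denoiser(
            tuple(self.latent_shape), self.conditioning_width, self.size_preset, self.model_seed
        )
        model.load_state_dict(self.state)
        return model

    def build_schedule(self) -> DiffusionSchedule:
        return make_schedule(**self.schedule_spec)

    def build_codec(self) -> LatentCodec:
        codec = build_codec(self.codec_spec)
        if isinstance(codec, PCACodec) and self.codec_state:
            codec.load_state(self.codec_state)
        return codec

    def standardize(self, values: np.ndarray) -> np.ndarray:
        if self.profile_mean is None:
            return np.asarray(values, dtype=np.float64)
        out, _ = standardize_profiles(values, (self.profile_mean, self.profile_std))
        return out


def _load_train_images(manifest: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    from ..io import read_image

    rows = manifest[manifest["role"] == "train_img"]
    if rows.empty:
        raise ValueError("manifest has no train_img rows")
    ids = rows["compound_id"].astype(str).tolist()
    if "image" in rows.columns and rows["image"].notna().all():
        images = np.stack([np.asarray(im, dtype=np.float64) for im in rows["image"]])
    else:
        images = np.stack([read_image(p)[0] for p in rows["image_path"]])
    return ids, images


def train(
    manifest: pd.DataFrame,
    profiles: dict[str, np.ndarray],
    config: TrainConfig,
    codec: LatentCodec | None = None,
    schedule: DiffusionSchedule | None = None,
    size_preset: str = "toy",
    standardize: bool = True,
    log_every: int = 50,
) -> Checkpoint:
    """Fit the conditional denoiser on the train-role images of a manifest.

    ``profiles`` maps compound_id to the (unpadded or padded) raw profile
    vector; per-assay standardization statistics are computed here over the
    training compounds and stored in the checkpoint so inference can replay
    the identical transform.
    """
    if codec is None:
        from .codec import IdentityCodec

        codec = IdentityCodec()
    if schedule is None:
        schedule = make_schedule()

    ids, images = _load_train_images(manifest)
    missing = sorted({i for i in ids if i not in profiles})
    if missing:
        raise ValueError(f"manifest compounds without profiles: {missing}")

    if isinstance(codec, PCACodec) and codec.components_ is None:
        codec.fit(images)
    latents = codec.encode(images)
    latent_shape = latents.shape[1:]

    uniq = sorted(set(ids))
    raw = np.stack([np.asarray(profiles[i], dtype=np.float64) for i in uniq])
    if standardize:
        std_vals, (mean, std) = standardize_profiles(raw)
    else:
        std_vals, (mean, std) = raw, (None, None)
    cond_by_id = {i: std_vals[j] for j, i in enumerate(uniq)}
    cond = np.stack([cond_by_id[i] for i in ids])
    width = cond.shape[1]

    rng = np.random.default_rng(config.seed)
    model = build_denoiser(latent_shape, width, size_preset, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    history: list[float] = []
    for step in range(config.steps):
        idx = rng.integers(0, len(latents), size=min(config.batch_size, len(latents)))
        loss = training_loss(latents[idx], cond[idx], model, schedule, config, rng)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step % log_every == 0 or step == config.steps - 1:
            history.append(loss.item())

    codec_state = codec.state() if isinstance(codec, PCACodec) else {}
    return Checkpoint(
        state=model.state_dict(),
        latent_shape=tuple(latent_shape),
        conditioning_width=width,
        size_preset=size_preset,
        schedule_spec=schedule.to_dict(),
        codec_spec=codec.spec(),
        codec_state=codec_state,
        profile_mean=mean,
        profile_std=std,
        config=config,
        loss_history=history,
        model_seed=config.seed,
    )


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    """Single-file archive: weights as arrays plus a JSON metadata entry."""
    meta = {
        "latent_shape": list(ckpt.latent_shape),
        "conditioning_width": ckpt.conditioning_width,
        "size_preset": ckpt.size_preset,
        "schedule_spec": ckpt.schedule_spec,
        "codec_spec": ckpt.codec_spec,
        "config": asdict(ckpt.config) if ckpt.config else None,
        "loss_history": ckpt.loss_history,
        "model_seed": ckpt.model_seed,
        "has_standardization": ckpt.profile_mean is not None,
    }
    arrays = {f"w.{k}": v for k, v in ckpt.state.items()}
    arrays.update({f"c.{k}": v for k, v in ckpt.codec_state.items()})
    if ckpt.profile_mean is not None:
        arrays["profile_mean"] = ckpt.profile_mean
        arrays["profile_std"] = ckpt.profile_std
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        state = {k[2:]: z[k] for k in z.files if k.startswith("w.")}
        codec_state = {k[2:]: z[k] for k in z.files if k.startswith("c.")}
        mean = z["profile_mean"] if meta["has_standardization"] else None
        std = z["profile_std"] if meta["has_standardization"] else None
    return Checkpoint(
        state=state,
        latent_shape=tuple(meta["latent_shape"]),
        conditioning_width=meta["conditioning_width"],
        size_preset=meta["size_preset"],
        schedule_spec=meta["schedule_spec"],
        codec_spec=meta["codec_spec"],
        codec_state=codec_state,
        profile_mean=mean,
        profile_std=std,
        config=TrainConfig(**meta["config"]) if meta["config"] else None,
        loss_history=list(meta["loss_history"]),
        model_seed=meta["model_seed"],
    )
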