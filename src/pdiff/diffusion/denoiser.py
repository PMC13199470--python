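"""The conditional epsilon-prediction network.

A compact U-Net: one downsampling level, residual conv blocks with additive
timestep embeddings, and a cross-attention block at the bottleneck where the
spatial features attend to the projected bioactivity-profile tokens.  The
profile vector is linearly projected to ``n_tokens`` context tokens; an
all-zero profile is the null conditioning used for classifier-free guidance.

Presets keep the network small enough to train on one CPU; the architecture
(timestep embedding + cross-attention over profile tokens) mirrors the
full-scale text-free latent-diffusion backbone it stands in for.
"""

from __future__ import annotations

import numpy as np

from ..autograd import Tensor, concat, upsample_nearest
from ..nn import Conv2d, CrossAttention, Linear, Module, timestep_embedding

__all__ = ["Denoiser", "build_denoiser", "PRESETS"]

PRESETS = {
    "toy": {"base": 24, "n_tokens": 4, "temb_dim": 32, "param_budget": 200_000},
    "small": {"base": 48, "n_tokens": 4, "temb_dim": 64, "param_budget": 800_000},
}


class _ConvBlock(Module):
    """conv -> +timestep projection -> SiLU -> conv, with residual add."""

    def __init__(self, c_in: int, c_out: int, temb_dim: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.time_proj = Linear(temb_dim, c_out, rng)
        self.skip = Conv2d(c_in, c_out, 1, rng, pad=0) if c_in != c_out else None

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(x).silu()
        tvec = self.time_proj(temb)  # (B, c_out)
        h = h + tvec.reshape(tvec.shape[0], tvec.shape[1], 1, 1)
        h = self.conv2(h.silu())
        res = x if self.skip is None else self.skip(x)
        return h + res


class Denoiser(Module):
    """eps_theta(z_t, t, c): predicts the noise added to a latent at step t."""

    def __init__(
        self,
        latent_shape: tuple[int, int, int],
        conditioning_width: int,
        size_preset: str = "toy",
        seed: int = 0,
    ):
        if size_preset not in PRESETS:
            raise ValueError(f"unknown preset {size_preset!r}; have {sorted(PRESETS)}")
        if conditioning_width < 1:
            raise ValueError("conditioning_width must be >= 1")
        c, h, w = latent_shape
        if h % 2 or w % 2:
            raise ValueError(
                f"latent spatial dims {h}x{w} must be divisible by the downsampling factor 2"
            )
        p = PRESETS[size_preset]
        base, self.n_tokens, self.temb_dim = p["base"], p["n_tokens"], p["temb_dim"]
        self.latent_shape = latent_shape
        self.conditioning_width = conditioning_width
        self.size_preset = size_preset
        ctx_dim = 2 * base
        rng = np.random.default_rng(seed)

        self.time_mlp = Linear(self.temb_dim, self.temb_dim, rng)
        self.ctx_proj = Linear(conditioning_width, self.n_tokens * ctx_dim, rng)
        self.conv_in = Conv2d(c, base, 3, rng)
        self.enc = _ConvBlock(base, base, self.temb_dim, rng)
        self.down = Conv2d(base, 2 * base, 3, rng, stride=2)
        self.mid1 = _ConvBlock(2 * base, 2 * base, self.temb_dim, rng)
        self.attn = CrossAttention(2 * base, ctx_dim, rng)
        self.mid2 = _ConvBlock(2 * base, 2 * base, self.temb_dim, rng)
        self.up = Conv2d(2 * base, base, 3, rng)
        self.dec = _ConvBlock(2 * base, base, self.temb_dim, rng)
        self.conv_out = Conv2d(base, c, 3, rng)
        # small output init: near-zero initial prediction without killing gradients
        self.conv_out.weight.data *= 0.1

    def forward_tensor(self, z_t: Tensor, t: np.ndarray, cond: np.ndarray) -> Tensor:
        b = z_t.shape[0]
        temb = Tensor(timestep_embedding(np.asarray(t), self.temb_dim))
        temb = self.time_mlp(temb).silu()
        ctx = self.ctx_proj(Tensor(cond))
        ctx = ctx.reshape(b, self.n_tokens, -1)

        h1 = self.enc(self.conv_in(z_t), temb)
        h2 = self.down(h1)
        h2 = self.mid1(h2, temb)
        bb, cc, hh, ww = h2.shape
        tokens = h2.reshape(bb, cc, hh * ww).transpose(0, 2, 1)
        tokens = self.attn(tokens, ctx)
        h2 = tokens.transpose(0, 2, 1).reshape(bb, cc, hh, ww)
        h2 = self.mid2(h2, temb)
        u = self.up(upsample_nearest(h2, 2))
        u = self.dec(concat([u, h1], axis=1), temb)
        return self.conv_out(u)

    def __call__(
        self, z_t: np.ndarray, t: np.ndarray | int, cond: np.ndarray | None
    ) -> np.ndarray:
        """Inference path: numpy in, numpy out; None conditioning means null."""
        z_t = np.asarray(z_t, dtype=np.float64)
        if z_t.ndim == 3:
            z_t = z_t[None]
        b = z_t.shape[0]
        t = np.full(b, t) if np.isscalar(t) else np.asarray(t)
        if cond is None:
            cond = np.zeros((b, self.conditioning_width))
        cond = np.asarray(cond, dtype=np.float64)
        if cond.ndim == 1:
            cond = np.broadcast_to(cond, (b, cond.shape[0]))
        if cond.shape != (b, self.conditioning_width):
            raise ValueError(
                f"conditioning shape {cond.shape} != ({b}, {self.conditioning_width})"
            )
        return self.forward_tensor(Tensor(z_t), t, cond).data


def build_denoiser(
    latent_shape: tuple[int, int, int],
    conditioning_width: int,
    size_preset: str = "toy",
    seed: int = 0,
) -> Denoiser:
    """Construct an epsilon predictor for the given latent geometry."""
    return Denoiser(latent_shape, conditioning_width, size_preset, seed)
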