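"""Neural-network layers and the Adam optimizer for the diffusion denoiser.

Layers hold their parameters as named ``Tensor`` objects; ``Module.parameters``
walks submodules recursively so optimizers and checkpoints see one flat dict.
Initialization draws from a caller-supplied ``numpy.random.Generator`` so that
model construction is fully reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "CrossAttention",
    "timestep_embedding",
    "Adam",
]


class Module:
    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor) and attr.requires_grad:
                params[name] = attr
            elif isinstance(attr, Module):
                for sub, p in attr.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(n_in)
        self.weight = Tensor(rng.normal(0, scale or 1e-8, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        zero_init: bool = False,
    ):
        fan_in = c_in * kernel * kernel
        scale = 0.0 if zero_init else 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(
            rng.normal(0, scale or 1e-8, (c_out, c_in, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class LayerNorm(Module):
    """Normalizes over the last axis; used on token sequences in attention."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class CrossAttention(Module):
    """Single-head cross-attention: spatial queries attend to profile tokens.

    Queries come from the flattened latent feature map, keys and values from
    the conditioning context (the projected bioactivity profile).  This is the
    channel through which the compound's profile steers denoising.
    """

    def __init__(self, dim: int, ctx_dim: int, rng: np.random.Generator):
        self.norm = LayerNorm(dim)
        self.to_q = Linear(dim, dim, rng)
        self.to_k = Linear(ctx_dim, dim, rng)
        self.to_v = Linear(ctx_dim, dim, rng)
        self.to_out = Linear(dim, dim, rng, zero_init=True)
        self.scale = 1.0 / np.sqrt(dim)

    def __call__(self, x: Tensor, ctx: Tensor) -> Tensor:
        # x: (B, L, dim); ctx: (B, m, ctx_dim)
        h = self.norm(x)
        q = self.to_q(h)
        k = self.to_k(ctx)
        v = self.to_v(ctx)
        attn = (q @ k.transpose(0, 2, 1) * self.scale).softmax(axis=-1)
        return x + self.to_out(attn @ v)


def timestep_embedding(t: np.ndarray, dim: int, max_period: float = 10_000.0) -> np.ndarray:
    """Sinusoidal embedding of (integer) diffusion timesteps, shape (B, dim)."""
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = np.asarray(t, dtype=np.float64)[:, None] * freqs[None, :]
    emb = np.concatenate([np.cos(args), np.sin(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], 1))], axis=1)
    return emb


class Adam:
    """Adam with bias correction; operates on a Module's parameter dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
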