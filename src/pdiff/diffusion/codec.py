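"""Pluggable latent codecs: image <-> latent-space mappings for the diffusion.

The generative model operates in a latent space; the codec decides what that
space is.  Three codecs are provided behind one interface:

* ``IdentityCodec`` — the latent is the image itself (exact round trip);
* ``PoolCodec`` — block average-pooling with nearest-neighbor decode, a fixed
  lossy compression that keeps diffusion cheap at desk scale;
* ``PCACodec`` — a linear autoencoder fit to training images, the learned
  stand-in for a pretrained variational autoencoder.

Latents are NCHW float arrays; images are (H, W, 3) floats in [0, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = ["LatentCodec", "IdentityCodec", "PoolCodec", "PCACodec", "build_codec"]


class LatentCodec:
    """encode: (N, H, W, 3) images -> (N, C, h, w) latents; decode inverts."""

    name: str = "base"
    scale_factor: float = 1.0

    def encode(self, images: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def decode(self, latents: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def latent_shape(self, height: int, width: int) -> tuple[int, int, int]:
        raise NotImplementedError

    def spec(self) -> dict:
        return {"name": self.name}


class IdentityCodec(LatentCodec):
    """Latent == image (channel-first); decode(encode(x)) is exact."""

    name = "identity"

    def encode(self, images: np.ndarray) -> np.ndarray:
        return np.transpose(np.asarray(images, dtype=np.float64), (0, 3, 1, 2))

    def decode(self, latents: np.ndarray) -> np.ndarray:
        return np.clip(np.transpose(latents, (0, 2, 3, 1)), 0.0, 1.0)

    def latent_shape(self, height: int, width: int) -> tuple[int, int, int]:
        return (3, height, width)


class PoolCodec(LatentCodec):
    """Average-pool by an integer factor; decode by nearest-neighbor upsample.

    ``scale_factor`` rescales latents to roughly unit variance so the
    diffusion prior N(0, I) matches the latent scale (images in [0, 1] pooled
    to blocks have small variance around their mean; we center at 0.5).
    """

    name = "pool"

    def __init__(self, factor: int = 8, scale_factor: float = 4.0):
        if factor < 1:
            raise ValueError("pool factor must be >= 1")
        self.factor = factor
        self.scale_factor = scale_factor

    def encode(self, images: np.ndarray) -> np.ndarray:
        x = np.transpose(np.asarray(images, dtype=np.float64), (0, 3, 1, 2))
        n, c, h, w = x.shape
        f = self.factor
        if h % f or w % f:
            raise ValueError(f"image size {h}x{w} not divisible by pool factor {f}")
        pooled = x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))
        return (pooled - 0.5) * self.scale_factor

    def decode(self, latents: np.ndarray) -> np.ndarray:
        x = latents / self.scale_factor + 0.5
        x = x.repeat(self.factor, axis=2).repeat(self.factor, axis=3)
        return np.clip(np.transpose(x, (0, 2, 3, 1)), 0.0, 1.0)

    def latent_shape(self, height: int, width: int) -> tuple[int, int, int]:
        return (3, height // self.factor, width // self.factor)

    def spec(self) -> dict:
        return {"name": self.name, "factor": self.factor, "scale_factor": self.scale_factor}


class PCACodec(LatentCodec):
    """Linear autoencoder: PCA on flattened images, latent reshaped to a grid.

    ``fit`` learns the components from training images; the latent is the
    top-k principal coordinates (whitened to unit variance) arranged as a
    1-channel (g x g) map so the convolutional denoiser can consume it.
    """

    name = "pca"

    def __init__(self, grid: int = 8):
        self.grid = grid
        self.k = grid * grid
        self.mean_: np.ndarray | None = None
        self.components_: np.ndarray | None = None
        self.scales_: np.ndarray | None = None

    def fit(self, images: np.ndarray) -> "PCACodec":
        from sklearn.decomposition import PCA

        flat = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
        if len(flat) <= self.k:
            raise ValueError(f"need more than {self.k} images to fit a {self.k}-D codec")
        pca = PCA(n_components=self.k, svd_solver="randomized", random_state=0)
        pca.fit(flat)
        self.mean_ = pca.mean_
        self.components_ = pca.components_
        self.scales_ = np.sqrt(np.maximum(pca.explained_variance_, 1e-8))
        return self

    def _check(self) -> None:
        if self.components_ is None:
            raise RuntimeError("PCACodec must be fit before use")

    def encode(self, images: np.ndarray) -> np.ndarray:
        self._check()
        flat = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
        z = (flat - self.mean_) @ self.components_.T / self.scales_
        return z.reshape(len(images), 1, self.grid, self.grid)

    def decode(self, latents: np.ndarray) -> np.ndarray:
        self._check()
        z = latents.reshape(len(latents), self.k) * self.scales_
        flat = z @ self.components_ + self.mean_
        side = int(np.sqrt(flat.shape[1] / 3))
        return np.clip(flat.reshape(len(latents), side, side, 3), 0.0, 1.0)

    def latent_shape(self, height: int, width: int) -> tuple[int, int, int]:
        return (1, self.grid, self.grid)

    def spec(self) -> dict:
        return {"name": self.name, "grid": self.grid}

    def state(self) -> dict[str, np.ndarray]:
        self._check()
        return {
            "pca_mean": self.mean_,
            "pca_components": self.components_,
            "pca_scales": self.scales_,
        }

    def load_state(self, state: dict[str, np.ndarray]) -> "PCACodec":
        self.mean_ = state["pca_mean"]
        self.components_ = state["pca_components"]
        self.scales_ = state["pca_scales"]
        self.k = len(self.scales_)
        self.grid = int(np.sqrt(self.k))
        return self


def build_codec(spec: dict) -> LatentCodec:
    name = spec.get("name", "identity")
    if name == "identity":
        return IdentityCodec()
    if name == "pool":
        return PoolCodec(factor=spec.get("factor", 8), scale_factor=spec.get("scale_factor", 4.0))
    if name == "pca":
        return PCACodec(grid=spec.get("grid", 8))
    raise ValueError(f"unknown codec {name!r}")
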