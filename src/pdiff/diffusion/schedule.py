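"""Noise schedules and the closed-form forward (noising) process.

A schedule fixes the per-step Gaussian noise variances beta_t of the forward
diffusion; alpha_t = 1 - beta_t and alpha_bar_t = prod_{s<=t} alpha_s give the
closed form q(z_t | z_0) = N(sqrt(alpha_bar_t) z_0, (1 - alpha_bar_t) I).
Timesteps are 1-based; alpha_bar_0 := 1 (no noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiffusionSchedule", "make_schedule", "forward_noise"]

DEFAULT_T = 1000
DEFAULT_BETA_START = 8.5e-4
DEFAULT_BETA_END = 0.012


@dataclass(frozen=True)
class DiffusionSchedule:
    T: int
    betas: np.ndarray        # betas[t-1] is beta_t, t = 1..T
    alphas: np.ndarray
    alpha_bars: np.ndarray   # alpha_bars[t] is alpha_bar_t, t = 0..T; alpha_bars[0] = 1

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        b = self.betas
        if len(b) != self.T or len(self.alpha_bars) != self.T + 1:
            raise ValueError("schedule arrays inconsistent with T")
        if not (np.all(b > 0) and np.all(b < 1)):
            raise ValueError("betas must lie in (0, 1)")
        if np.any(np.diff(b) < 0):
            raise ValueError("betas must be non-decreasing")
        if np.any(np.diff(self.alpha_bars) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")

    def alpha_bar(self, t) -> np.ndarray:
        """alpha_bar_t for integer t in 0..T (vectorized)."""
        return self.alpha_bars[np.asarray(t)]

    def snr(self, t) -> np.ndarray:
        ab = self.alpha_bar(t)
        return ab / (1.0 - ab)

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "beta_start": float(self.betas[0]),
            "beta_end": float(self.betas[-1]),
        }


def make_schedule(
    T: int = DEFAULT_T,
    kind: str = "linear",
    beta_start: float = DEFAULT_BETA_START,
    beta_end: float = DEFAULT_BETA_END,
) -> DiffusionSchedule:
    """Build a noise schedule; ``linear`` interpolates beta from start to end."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    if beta_end < beta_start:
        raise ValueError("beta_end < beta_start would give non-monotone betas")
    if T == 1:
        betas = np.array([beta_start])
    else:
        betas = np.linspace(beta_start, beta_end, T)
    alphas = 1.0 - betas
    alpha_bars = np.concatenate([[1.0], np.cumprod(alphas)])
    return DiffusionSchedule(T=T, betas=betas, alphas=alphas, alpha_bars=alpha_bars)


def forward_noise(
    z0: np.ndarray, t: np.ndarray | int, eps: np.ndarray, schedule: DiffusionSchedule
) -> np.ndarray:
    """Noise clean latents to step t: z_t = sqrt(ab_t) z0 + sqrt(1-ab_t) eps.

    ``t`` may be a scalar or a per-sample vector (one timestep per batch item).
    """
    z0 = np.asarray(z0)
    eps = np.asarray(eps)
    if z0.shape != eps.shape:
        raise ValueError(f"shape mismatch: z0 {z0.shape} vs eps {eps.shape}")
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > schedule.T):
        raise ValueError(f"t must be in 1..{schedule.T}")
    ab = schedule.alpha_bar(t)
    if t.ndim == 1:  # per-sample timesteps: broadcast over trailing axes
        ab = ab.reshape((-1,) + (1,) * (z0.ndim - 1))
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps
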