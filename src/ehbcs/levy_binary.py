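"""Lévy-flight step sampling (Mantegna) and sigmoid transfer functions.

Cuckoo search perturbs candidate solutions with Lévy flights — random walks
whose step lengths are heavy-tailed, so the search mixes many short local
moves with occasional long jumps. The Mantegna algorithm simulates a
symmetric Lévy-stable step of index beta as s = u / |v|^(1/beta) with
u ~ N(0, sigma_mu^2), v ~ N(0, 1) and

    sigma_mu = { Gamma(1+beta) sin(pi beta / 2)
                 / [ Gamma((1+beta)/2) beta 2^((beta-1)/2) ] }^(1/beta).

For feature selection the search space is binary, so the real step never
moves a coordinate directly: it is squashed through a sigmoid transfer
function into a probability of setting that bit to 1. The weighted variant
replaces the fixed sigmoid slope by a per-feature coefficient gamma taken
from the Relief weights:

    step >= 0:  p = 1 / (1 + exp(-gamma * step))
    step <  0:  p = 1 - 1 / (1 + exp(-gamma * step))

Both branches give p = 0.5 at step = 0 and p(-s) = p(s), so a heavier
(more discriminative) feature has a selection probability above 0.5 for any
nonzero step when gamma > 0, and below 0.5 when its Relief weight is
negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn

__all__ = [
    "LevyConfig",
    "mantegna_sigma_mu",
    "sample_steps",
    "transfer_probability",
    "binarize",
]

_EXP_CLAMP = 700.0  # exp overflow guard; beyond this p is exactly 0 or 1


@dataclass
class LevyConfig:
    """Step-size scale alpha and stability exponent beta of the flight."""

    alpha: float = 1.0
    levy_beta: float = 1.5

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 < self.levy_beta <= 2:
            raise ValueError("levy_beta must be in (0, 2]")


def mantegna_sigma_mu(levy_beta: float) -> float:
    """Closed-form numerator scale of the Mantegna sampler (sigma_nu = 1)."""
    if not 0 < levy_beta <= 2:
        raise ValueError("levy_beta must be in (0, 2]")
    b = levy_beta
    num = gamma_fn(1 + b) * np.sin(np.pi * b / 2)
    den = gamma_fn((1 + b) / 2) * b * 2 ** ((b - 1) / 2)
    return float((num / den) ** (1 / b))


def sample_steps(
    d: int, config: LevyConfig, rng: np.random.Generator, u_override=None
) -> np.ndarray:
    """Draw d independent Lévy steps, scaled by alpha.

    ``u_override`` substitutes the Gaussian numerator draws (test hook).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    sigma = mantegna_sigma_mu(config.levy_beta)
    u = rng.normal(0.0, sigma, size=d) if u_override is None else np.asarray(u_override)
    v = rng.normal(0.0, 1.0, size=d)
    v = np.where(np.abs(v) < 1e-300, 1e-300, v)  # avoid 0-divide; prob-0 event
    s = u / np.abs(v) ** (1.0 / config.levy_beta)
    return config.alpha * s


def transfer_probability(step, gamma):
    """Weighted sigmoid transfer: probability that a bit is set to 1.

    Vectorized over broadcastable ``step`` and ``gamma``. Numerically stable
    for arbitrarily large |gamma * step| (argument clamped at +-700).
    """
    step = np.asarray(step, dtype=float)
    g = np.asarray(gamma, dtype=float)
    z = g * step
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -_EXP_CLAMP, _EXP_CLAMP)))
    # beyond the clamp the sigmoid saturates exactly
    sig = np.where(z >= _EXP_CLAMP, 1.0, np.where(z <= -_EXP_CLAMP, 0.0, sig))
    p = np.where(step >= 0, sig, 1.0 - sig)
    if p.ndim == 0:
        return float(p)
    return p


def binarize(
    steps: np.ndarray, gammas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Map a real step vector to bits: bit_j = 1 iff U_j <= p(step_j, gamma_j).

    One independent uniform draw per dimension; the tie ``rand <= p`` is
    inclusive.
    """
    steps = np.asarray(steps, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    if steps.shape != gammas.shape:
        raise ValueError("gammas length must match steps")
    p = transfer_probability(steps, gammas)
    return (rng.random(steps.shape) <= p).astype(np.int8)
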