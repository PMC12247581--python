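"""Denoising-diffusion machinery for scalar (age) regression.

The forward process gradually corrupts a normalized age ``y0`` with Gaussian
noise under a linear variance schedule; the reverse process reconstructs it
by ancestral sampling with a learned (conditional) noise predictor.

Conventions
-----------
* beta is linearly spaced from ``beta_start`` to ``beta_end`` inclusive
  (defaults 1e-4 and 0.02); ``alpha_bar`` is the running product of
  ``1 - beta``.
* Timesteps are 1-based: ``t`` ranges over ``[1, T]``.
* Ages are mapped affinely to [-1, 1] over configured bounds before entering
  the diffusion process and mapped back after sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionSchedule", "build_schedule", "normalize_age", "denormalize_age",
    "forward_noise", "reverse_sample",
]


@dataclass(frozen=True)
class DiffusionSchedule:
    """Linear beta schedule and derived alpha / alpha-bar sequences."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray = field(repr=False, default=None)
    alpha_bar: np.ndarray = field(repr=False, default=None)

    def coeffs(self, t):
        """(sqrt(alpha_bar_t), sqrt(1 - alpha_bar_t)) for 1-based t."""
        ab = self.alpha_bar[np.asarray(t) - 1]
        return np.sqrt(ab), np.sqrt(1.0 - ab)


def build_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02) -> DiffusionSchedule:
    """Construct the linear noise schedule.

    ``beta`` contains ``T`` values linearly spaced from ``beta_start`` to
    ``beta_end`` inclusive; with ``T == 1`` the single value is ``beta_start``.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError("require 0 < beta_start <= beta_end < 1")
    beta = np.full(1, beta_start) if T == 1 else np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    return DiffusionSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha))


def normalize_age(age, bounds: tuple[float, float]):
    """Affine map of age in years onto [-1, 1] over ``bounds``."""
    lo, hi = bounds
    if not hi > lo:
        raise ValueError(f"degenerate age bounds {bounds}")
    age = np.asarray(age, dtype=np.float64)
    y = 2.0 * (age - lo) / (hi - lo) - 1.0
    if np.any(np.abs(y) > 1.0):
        warnings.warn("age outside configured bounds maps outside [-1, 1]",
                      stacklevel=2)
    return y if y.ndim else float(y)


def denormalize_age(y, bounds: tuple[float, float]):
    lo, hi = bounds
    if not hi > lo:
        raise ValueError(f"degenerate age bounds {bounds}")
    y = np.asarray(y, dtype=np.float64)
    age = lo + (y + 1.0) * (hi - lo) / 2.0
    return age if age.ndim else float(age)


def forward_noise(y0, t, epsilon, schedule: DiffusionSchedule):
    """Forward diffusion: ``y_t = sqrt(abar_t) y0 + sqrt(1-abar_t) eps``."""
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > schedule.T):
        raise ValueError(f"timestep out of range [1, {schedule.T}]")
    s_sig, s_noise = schedule.coeffs(t)
    return s_sig * np.asarray(y0) + s_noise * np.asarray(epsilon)


def reverse_sample(eps_fn, schedule: DiffusionSchedule, *,
                   n_chains: int = 1, rng: np.random.Generator | None = None,
                   inject_noise: bool = True, y_T: np.ndarray | None = None) -> np.ndarray:
    """Run DDPM ancestral sampling on a batch of chains.

    ``eps_fn(y_t, t)`` returns the predicted noise for the vector of chain
    states at (1-based) timestep ``t``.  The reverse update is

        y_{t-1} = (y_t - beta_t / sqrt(1-abar_t) * eps_hat) / sqrt(alpha_t)
                  + sigma_t * z,

    with ``sigma_t^2 = beta_t``; no noise is injected at the final step
    (t == 1), and noise injection can be disabled entirely for deterministic
    diagnostics.  Returns the vector of ``y_0`` states.
    """
    if y_T is None:
        if rng is None:
            raise ValueError("reverse_sample requires an rng when y_T is not fixed")
        y = rng.standard_normal(n_chains)
    else:
        y = np.array(y_T, dtype=np.float64, copy=True).reshape(-1)
    if inject_noise and rng is None:
        raise ValueError("noise injection requires an rng")
    for t in range(schedule.T, 0, -1):
        beta_t = schedule.beta[t - 1]
        alpha_t = schedule.alpha[t - 1]
        abar_t = schedule.alpha_bar[t - 1]
        eps_hat = np.asarray(eps_fn(y, t), dtype=np.float64).reshape(y.shape)
        y = (y - beta_t / np.sqrt(1.0 - abar_t) * eps_hat) / np.sqrt(alpha_t)
        if inject_noise and t > 1:
            y = y + np.sqrt(beta_t) * rng.standard_normal(y.shape)
    return y
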