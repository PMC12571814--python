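"""Metabolic-cost signal and control reward.

Energy expenditure is a weighted sum of synchrony, its rate of change, and
normalized EEG/BOLD activity features,

    E(t) = α R(t) + β |dR/dt| + γ P_EEG(t) + δ S_fMRI(t),

with default weights α=10.01, β=5.00, γ=3.00, δ=2.00 balancing synchrony,
transition cost, and local/global activity.  Values are normalized model
outputs, not Joules.  The literal signed derivative form (which can go
negative during desynchronization) is available via ``signed=True``; the
default takes |dR/dt| so that E ≥ 0 for non-negative inputs.

The control reward penalizes both tracking error and metabolic load,

    r = −(|R_target − R(t)| + E(t)),

so r ≤ 0 always, with 0 attained only at perfect tracking with zero cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnergyWeights", "RewardSpec", "estimate_derivative", "energy", "reward"]


@dataclass(frozen=True)
class EnergyWeights:
    """Weights of the energy function. gamma_w is the EEG weight (the name
    avoids collision with the reinforcement-learning discount factor γ)."""

    alpha: float = 10.01
    beta: float = 5.00
    gamma_w: float = 3.00
    delta: float = 2.00

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma_w", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RewardSpec:
    """Target synchrony level for the controller."""

    r_target: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_target <= 1.0):
            raise ValueError("r_target must lie in [0, 1]")


def estimate_derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """Finite-difference derivative: central in the interior, one-sided at the
    ends; output length equals input length."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("need at least two samples to differentiate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.gradient(x, dt)


def energy(
    R,
    dRdt,
    p_eeg,
    s_fmri,
    weights: EnergyWeights = EnergyWeights(),
    signed: bool = False,
):
    """Instantaneous metabolic cost E(t). Vectorized over array inputs."""
    R = np.asarray(R, float)
    dRdt = np.asarray(dRdt, float)
    transition = dRdt if signed else np.abs(dRdt)
    out = (
        weights.alpha * R
        + weights.beta * transition
        + weights.gamma_w * np.asarray(p_eeg, float)
        + weights.delta * np.asarray(s_fmri, float)
    )
    return float(out) if out.ndim == 0 else out


def reward(R, spec: RewardSpec, E):
    """Control reward r = −(|R_target − R| + E). Vectorized over array inputs."""
    out = -(np.abs(spec.r_target - np.asarray(R, float)) + np.asarray(E, float))
    return float(out) if out.ndim == 0 else out
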