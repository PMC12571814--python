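"""The synchrony-control environment.

An agent observes the synchronization level R(t), the metabolic cost E(t)
and the task context, and acts on the oscillator population once per
decision interval (default 0.1 s = 10 dynamics steps at dt = 0.01 s).  The
default action set adjusts the coupling constant K by {−1, 0, +1} — the one
lever that provably moves the order parameter, since a common-mode external
input cancels in the phase differences.  An alternative ``split_input`` mode
instead applies a stimulus amplitude to the first half of the population
(targeted stimulation); ``uniform_input`` applies it to every oscillator and
is retained for fidelity demonstrations of the common-input invariance.

The per-step reward is r = −(|R_target − R| + energy_scale · E): the two
penalties — tracking error and metabolic load — are brought onto a common
scale by ``energy_scale`` (default 1/20 ≈ 1/(α+β+γ+δ)), reflecting equal
baseline weighting of the two terms.  R_target depends on the task context:
focused 0.9, multitasking 0.5, resting 0.1, so the optimal policy is
condition-dependent.  The DQN's state includes a condition one-hot; the
tabular agent sees only (R, E) bins and therefore faces genuine state
aliasing across contexts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..energy import EnergyWeights, energy
from ..kuramoto import (
    TWO_PI,
    FrequencyModel,
    get_preset,
    order_parameter,
    sample_frequencies,
    stimulus_profile,
    _phase_velocity,
)
from ..signals import BOLD_RANGE, EEG_POWER_RANGE, canonical_hrf

__all__ = ["EnvConfig", "SyncControlEnv", "DEFAULT_CONDITION_TARGETS"]

#: Desired synchrony per cognitive context.
DEFAULT_CONDITION_TARGETS: dict[str, float] = {
    "focused": 0.9,
    "multitasking": 0.5,
    "resting": 0.1,
}


@dataclass(frozen=True)
class EnvConfig:
    """Configuration of the closed-loop control environment."""

    model: FrequencyModel = field(default_factory=FrequencyModel)
    n_oscillators: int = 10
    dt: float = 0.01
    decision_interval: float = 0.1
    episode_steps: int = 200  # decision steps per episode (20 s simulated)
    conditions: tuple[str, ...] = ("focused", "multitasking", "resting")
    targets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONDITION_TARGETS))
    action_mode: str = "coupling"  # coupling | split_input | uniform_input
    coupling_actions: tuple[float, ...] = (-1.0, 0.0, 1.0)
    input_actions: tuple[float, ...] = (-5.0, -2.5, 0.0, 2.5, 5.0)
    k_bounds: tuple[float, float] = (0.0, 15.0)
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    energy_scale: float = 0.05
    e_clip: float = 20.0

    def __post_init__(self) -> None:
        if self.episode_steps < 1:
            raise ValueError("episode_steps must be >= 1")
        if self.action_mode not in ("coupling", "split_input", "uniform_input"):
            raise ValueError(f"unknown action_mode {self.action_mode!r}")
        if len(self.actions) == 0:
            raise ValueError("action set must be non-empty")
        for cond in self.conditions:
            if cond not in self.targets:
                raise ValueError(f"no R_target for condition {cond!r}")

    @property
    def actions(self) -> tuple[float, ...]:
        return self.coupling_actions if self.action_mode == "coupling" else self.input_actions

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    @property
    def substeps(self) -> int:
        return int(round(self.decision_interval / self.dt))


class SyncControlEnv:
    """Oscillator population wrapped as a sequential decision process.

    Observations are dicts with keys ``R`` (interval-mean synchrony), ``E``
    (interval-mean energy), ``condition`` (context index), ``K`` and
    ``r_target``.  With the null action selected at every step the phase
    dynamics reduce exactly to the open-loop condition simulation.
    """

    def __init__(self, config: EnvConfig):
        self.config = config
        # S_fMRI proxy: running HRF convolution of interval-mean R, sampled
        # at the decision interval (the HRF is far slower than 0.1 s)
        self._hrf = canonical_hrf(config.decision_interval)
        self._hrf_gain = float(np.sum(self._hrf.samples) * self._hrf.dt)
        self._omega: np.ndarray | None = None

    @property
    def n_actions(self) -> int:
        return self.config.n_actions

    @property
    def null_action(self) -> int:
        actions = self.config.actions
        return int(np.argmin(np.abs(np.asarray(actions))))

    def reset(self, condition: str, seed: int | np.random.Generator) -> dict:
        cfg = self.config
        if condition not in cfg.conditions:
            raise ValueError(f"condition {condition!r} not in {cfg.conditions}")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        preset = get_preset(condition)
        self._condition = condition
        self._omega = sample_frequencies(cfg.model, cfg.n_oscillators, rng)
        self._theta = rng.uniform(0.0, TWO_PI, size=cfg.n_oscillators)
        self._K = preset.K
        self._base_input = stimulus_profile(preset, cfg.n_oscillators)
        self._r_history: list[float] = []
        self._prev_R, _ = order_parameter(self._theta)
        self._t_step = 0
        return self._observe(self._prev_R, self._energy_interval(self._prev_R))

    # -- internals ---------------------------------------------------------

    def _s_fmri(self) -> float:
        """Streaming HRF response to the R history, mapped into [0.3, 0.7]."""
        h = self._hrf.samples
        hist = self._r_history[-len(h) :]
        if not hist:
            return BOLD_RANGE[0]
        seg = np.asarray(hist[::-1])
        conv = float(np.dot(h[: len(seg)], seg) * self._hrf.dt)
        frac = np.clip(conv / self._hrf_gain, 0.0, 1.0)
        return BOLD_RANGE[0] + (BOLD_RANGE[1] - BOLD_RANGE[0]) * frac

    def _energy_interval(self, mean_R: float) -> float:
        """Interval-level energy: all cost-function inputs evaluated at the decision
        timescale, so the transition cost β|dR/dt| measures movement of the
        interval-mean synchrony rather than the fast within-interval
        oscillation of R(t)."""
        cfg = self.config
        prev = self._r_history[-1] if self._r_history else mean_R
        dRdt = (mean_R - prev) / cfg.decision_interval
        # envelope of the mean-field signal tracks R directly
        p_eeg = EEG_POWER_RANGE[0] + (EEG_POWER_RANGE[1] - EEG_POWER_RANGE[0]) * mean_R
        return float(energy(mean_R, dRdt, p_eeg, self._s_fmri(), cfg.weights))

    def _observe(self, mean_R: float, mean_E: float) -> dict:
        return {
            "R": float(mean_R),
            "E": float(mean_E),
            "condition": self.config.conditions.index(self._condition),
            "K": float(self._K),
            "r_target": self.config.targets[self._condition],
        }

    # -- stepping ----------------------------------------------------------

    def step(self, action: int) -> tuple[dict, float, dict]:
        cfg = self.config
        if not (0 <= action < cfg.n_actions):
            raise ValueError(f"invalid action index {action}")
        amp = cfg.actions[action]
        ext = self._base_input
        if cfg.action_mode == "coupling":
            self._K = float(np.clip(self._K + amp, *cfg.k_bounds))
        elif cfg.action_mode == "split_input":
            extra = np.zeros(cfg.n_oscillators)
            extra[: (cfg.n_oscillators + 1) // 2] = amp
            ext = self._base_input + extra
        else:  # uniform_input: provably leaves R(t) unchanged
            ext = self._base_input + amp

        R_sub = np.empty(cfg.substeps)
        theta = self._theta
        for i in range(cfg.substeps):
            theta = np.mod(
                theta + cfg.dt * _phase_velocity(theta, self._omega, self._K, ext, TWO_PI),
                TWO_PI,
            )
            R_sub[i], _ = order_parameter(theta)
        self._theta = theta

        mean_R = float(np.mean(R_sub))
        mean_E = self._energy_interval(mean_R)
        self._prev_R = float(R_sub[-1])
        self._r_history.append(mean_R)
        self._t_step += 1

        target = cfg.targets[self._condition]
        r = -(abs(target - mean_R) + cfg.energy_scale * mean_E)
        obs = self._observe(mean_R, mean_E)
        info = {
            "mean_R": mean_R,
            "mean_E": mean_E,
            "sync_error": abs(target - mean_R),
            "K": self._K,
            "done": self._t_step >= cfg.episode_steps,
        }
        return obs, float(r), info

    # -- state encodings ---------------------------------------------------

    def encode_continuous(self, obs: dict) -> np.ndarray:
        """DQN state: (R, E/e_clip, condition one-hot)."""
        onehot = np.zeros(len(self.config.conditions))
        onehot[obs["condition"]] = 1.0
        e = min(obs["E"], self.config.e_clip) / self.config.e_clip
        return np.concatenate([[obs["R"], e], onehot])

    @property
    def n_state_features(self) -> int:
        return 2 + len(self.config.conditions)
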