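"""Coupled phase-oscillator (Kuramoto) dynamics and global synchrony.

The population model is the classic mean-field Kuramoto system with an
additive external drive,

    dθ_i/dt = 2π ω_i + (2π K / N) Σ_j sin(θ_j − θ_i) + 2π I_i(t),

where ω_i are natural frequencies in Hz, K a coupling strength and I_i a
per-oscillator input, both also expressed in Hz and scaled to angular units
internally.  Keeping every rate parameter in Hz preserves the dimensionless
ratios K/σ_ω and I/σ_ω that determine synchronization, while placing the
mean-field rhythm near 10 Hz (the EEG alpha band) for the signal-synthesis
layer.  The scaling can be disabled (``angular_units=True``) for sensitivity
studies.

Global synchrony is summarized by the order parameter

    R(t) e^{iψ(t)} = (1/N) Σ_j e^{iθ_j(t)},

with R ∈ [0, 1] (0 incoherent, 1 phase-locked) and ψ the collective phase.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyModel",
    "ConditionPreset",
    "OscillatorPopulation",
    "SyncTrajectory",
    "CONDITION_PRESETS",
    "sample_frequencies",
    "stimulus_profile",
    "kuramoto_step",
    "order_parameter",
    "simulate_condition",
]

TWO_PI = 2.0 * np.pi


class FrequencyKind(str, enum.Enum):
    """Generating law for natural frequencies."""

    INTRINSIC = "intrinsic"
    GAUSSIAN = "gaussian"
    POISSON_MODEL = "poisson_model"


@dataclass(frozen=True)
class FrequencyModel:
    """Distribution of oscillator natural frequencies (Hz).

    Three firing-rate laws are supported:

    - ``intrinsic``: N(10, 2) Hz, a fixed baseline of natural alpha-range
      oscillation with moderate variability.
    - ``gaussian``: N(mu, sigma) with mu in [5, 20] Hz and sigma in [1, 5] Hz,
      clustered firing typical of organized populations.
    - ``poisson_model``: uniform on [low, high] = [5, 20] Hz.  Despite the
      name (kept from the framing of high-variability, Poisson-like firing)
      this is a uniform law; it models unstructured variability.
    """

    kind: FrequencyKind = FrequencyKind.INTRINSIC
    mu: float = 10.0
    sigma: float = 2.0
    low: float = 5.0
    high: float = 20.0

    def __post_init__(self) -> None:
        kind = FrequencyKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is FrequencyKind.INTRINSIC:
            object.__setattr__(self, "mu", 10.0)
            object.__setattr__(self, "sigma", 2.0)
        elif kind is FrequencyKind.GAUSSIAN:
            if not (5.0 <= self.mu <= 20.0):
                raise ValueError(f"gaussian model requires mu in [5, 20] Hz, got {self.mu}")
            if not (1.0 <= self.sigma <= 5.0):
                raise ValueError(f"gaussian model requires sigma in [1, 5] Hz, got {self.sigma}")
        elif kind is FrequencyKind.POISSON_MODEL:
            object.__setattr__(self, "low", 5.0)
            object.__setattr__(self, "high", 20.0)
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.low >= self.high:
            raise ValueError(f"require low < high, got [{self.low}, {self.high}]")

    @classmethod
    def gaussian(cls, mu: float = 12.5, sigma: float = 3.0) -> "FrequencyModel":
        return cls(kind=FrequencyKind.GAUSSIAN, mu=mu, sigma=sigma)


class ConditionName(str, enum.Enum):
    FOCUSED = "focused"
    MULTITASKING = "multitasking"
    RESTING = "resting"


@dataclass(frozen=True)
class ConditionPreset:
    """A cognitive-condition preset: coupling strength plus stimulus layout.

    focused      — strong coupling (K=10), uniform +5 Hz drive.
    multitasking — moderate coupling (K=5), +5 Hz to the first half of the
                   population and −5 Hz to the second half (competing inputs).
    resting      — weak coupling (K=1), no external input.
    """

    name: ConditionName
    K: float
    stimulus_amplitude: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", ConditionName(self.name))


CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "focused": ConditionPreset(ConditionName.FOCUSED, K=10.0, stimulus_amplitude=5.0),
    "multitasking": ConditionPreset(ConditionName.MULTITASKING, K=5.0, stimulus_amplitude=5.0),
    "resting": ConditionPreset(ConditionName.RESTING, K=1.0, stimulus_amplitude=0.0),
}


def get_preset(name: str | ConditionPreset) -> ConditionPreset:
    if isinstance(name, ConditionPreset):
        return name
    try:
        return CONDITION_PRESETS[str(ConditionName(name).value)]
    except ValueError as exc:
        raise ValueError(
            f"unknown condition preset {name!r}; expected one of {sorted(CONDITION_PRESETS)}"
        ) from exc


@dataclass
class OscillatorPopulation:
    """State of N coupled phase oscillators."""

    omega: np.ndarray  # natural frequencies, Hz
    theta: np.ndarray  # phases, radians in [0, 2π)
    t: float = 0.0

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.omega.shape != self.theta.shape or self.omega.ndim != 1:
            raise ValueError("omega and theta must be 1-d arrays of equal length")
        if self.n < 1:
            raise ValueError("population needs at least one oscillator")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("phases must be finite")

    @property
    def n(self) -> int:
        return self.omega.size


@dataclass
class SyncTrajectory:
    """Time course of a simulated population: phases, R(t) and ψ(t)."""

    dt: float
    theta_series: np.ndarray  # (time, oscillator)
    R_series: np.ndarray
    psi_series: np.ndarray
    omega: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n_t = self.theta_series.shape[0]
        if not (len(self.R_series) == len(self.psi_series) == n_t):
            raise ValueError("series lengths must match")

    @property
    def n_steps(self) -> int:
        return self.theta_series.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def stationary_mean_R(self, fraction: float = 0.5) -> float:
        """Mean R over the trailing ``fraction`` of the run (default second half)."""
        start = int(round(self.n_steps * (1.0 - fraction)))
        return float(np.mean(self.R_series[start:]))

    def to_dataframe(self, include_phases: bool = False):
        """Tidy table with columns time_s, R, psi (plus theta_0..theta_{N-1})."""
        import pandas as pd

        data = {"time_s": self.time, "R": self.R_series, "psi": self.psi_series}
        if include_phases:
            for j in range(self.theta_series.shape[1]):
                data[f"theta_{j}"] = self.theta_series[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path, include_phases: bool = False) -> None:
        self.to_dataframe(include_phases).to_csv(path, index=False)


def sample_frequencies(model: FrequencyModel, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw n natural frequencies (Hz) from the model's law. Seeded, reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kind = FrequencyKind(model.kind)
    if kind is FrequencyKind.POISSON_MODEL:
        return rng.uniform(model.low, model.high, size=n)
    return rng.normal(model.mu, model.sigma, size=n)


def stimulus_profile(preset: ConditionPreset | str, n: int) -> np.ndarray:
    """Per-oscillator external input (Hz) for a condition preset.

    focused: uniform +amplitude; resting: zeros; multitasking: +amplitude to
    the first ⌈n/2⌉ oscillators and −amplitude to the rest.
    """
    preset = get_preset(preset)
    if n < 1:
        raise ValueError("n must be >= 1")
    if preset.name is ConditionName.FOCUSED:
        return np.full(n, preset.stimulus_amplitude)
    if preset.name is ConditionName.RESTING:
        return np.zeros(n)
    if n < 2:
        raise ValueError("multitasking split requires n >= 2")
    out = np.full(n, -preset.stimulus_amplitude)
    out[: (n + 1) // 2] = preset.stimulus_amplitude
    return out


def order_parameter(theta: np.ndarray) -> tuple[float, float]:
    """Return (R, ψ): modulus and argument of the population-mean phasor."""
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("order parameter of an empty phase vector is undefined")
    z = np.mean(np.exp(1j * theta))
    return float(np.abs(z)), float(np.angle(z))


def _phase_velocity(
    theta: np.ndarray, omega: np.ndarray, K: float, ext: np.ndarray, scale: float
) -> np.ndarray:
    # Mean-field form: Σ_j sin(θ_j − θ_i) = N·R·sin(ψ − θ_i), O(N) per step.
    z = np.mean(np.exp(1j * theta))
    coupling = K * np.abs(z) * np.sin(np.angle(z) - theta)
    return scale * (omega + coupling + ext)


def kuramoto_step(
    pop: OscillatorPopulation,
    K: float,
    external_input: np.ndarray,
    dt: float,
    angular_units: bool = False,
) -> OscillatorPopulation:
    """Advance the population one explicit-Euler step of length dt.

    Rates (ω, K, input) are in Hz and multiplied by 2π internally unless
    ``angular_units`` is set.  Phases are reduced mod 2π after the step; the
    order parameter is invariant to that reduction.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ext = np.asarray(external_input, dtype=float)
    if ext.shape != pop.theta.shape:
        raise ValueError("external input length must match the population size")
    scale = 1.0 if angular_units else TWO_PI
    theta = pop.theta + dt * _phase_velocity(pop.theta, pop.omega, K, ext, scale)
    if not np.all(np.isfinite(theta)):
        raise FloatingPointError("non-finite phases after integration step")
    return OscillatorPopulation(omega=pop.omega, theta=np.mod(theta, TWO_PI), t=pop.t + dt)


def simulate_condition(
    model: FrequencyModel,
    preset: ConditionPreset | str,
    n: int = 10,
    dt: float = 0.01,
    duration: float = 10.0,
    seed: int | np.random.Generator = 0,
    angular_units: bool = False,
    external_input: np.ndarray | None = None,
    K: float | None = None,
) -> SyncTrajectory:
    """Simulate a cognitive-condition preset and record phases, R(t), ψ(t).

    Initial phases are uniform on [0, 2π) from the seed; the run covers
    ⌈duration/dt⌉ explicit-Euler steps and records the state after each.
    ``external_input`` and ``K`` override the preset when given (used by the
    closed-loop control environment).
    """
    if duration < dt:
        raise ValueError("duration must be at least one step")
    preset = get_preset(preset)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    omega = sample_frequencies(model, n, rng)
    theta0 = rng.uniform(0.0, TWO_PI, size=n)
    ext = stimulus_profile(preset, n) if external_input is None else np.asarray(external_input, float)
    coupling = preset.K if K is None else float(K)

    n_steps = int(np.ceil(duration / dt))
    scale = 1.0 if angular_units else TWO_PI
    theta_series = np.empty((n_steps, n))
    R_series = np.empty(n_steps)
    psi_series = np.empty(n_steps)
    theta = theta0
    for step in range(n_steps):
        theta = np.mod(theta + dt * _phase_velocity(theta, omega, coupling, ext, scale), TWO_PI)
        if not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"non-finite phases at step {step}")
        theta_series[step] = theta
        R_series[step], psi_series[step] = order_parameter(theta)
    return SyncTrajectory(
        dt=dt, theta_series=theta_series, R_series=R_series, psi_series=psi_series, omega=omega
    )
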