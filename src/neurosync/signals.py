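"""Synthesis of EEG-like and BOLD-like signals from oscillator trajectories.

The mean-field signal of a phase-oscillator population, (1/N) Σ cos θ_j(t),
plays the role of a raw EEG trace: when the population synchronizes near
10 Hz it is an alpha-band near-sinusoid, and its envelope tracks the order
parameter R(t).  Slow hemodynamic (BOLD-like) signals are produced by
convolving a neural time course with a canonical double-gamma hemodynamic
response function (peak ≈ 5 s, post-peak undershoot).  Multi-region and
voxel-level BOLD data are generated as linear mixtures of an HRF-convolved
task block design and an HRF-convolved EEG-power regressor, plus Gaussian
noise — the generative model the GLM analyses are meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert
from scipy.stats import gamma as gamma_dist

from .kuramoto import SyncTrajectory

__all__ = [
    "HrfKernel",
    "RegionMixture",
    "MultimodalSeries",
    "DEFAULT_REGION_MIXTURES",
    "EEG_POWER_RANGE",
    "BOLD_RANGE",
    "synthesize_eeg",
    "canonical_hrf",
    "hrf_convolve",
    "task_block_design",
    "simulate_region_bold",
    "simulate_voxel_bold",
    "apply_onset_delay",
    "rescale_to_range",
]

# Biologically plausible normalized feature ranges.
EEG_POWER_RANGE = (0.4, 0.8)
BOLD_RANGE = (0.3, 0.7)


@dataclass(frozen=True)
class HrfKernel:
    """Sampled canonical hemodynamic response function, peak-normalized to 1."""

    dt: float
    samples: np.ndarray
    peak_time: float

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class RegionMixture:
    """Generative weights for one simulated brain region.

    region(t) = w_task·HRF*task(t) + w_eeg·HRF*eeg(t) + noise_sd·ε(t)
    """

    name: str
    w_task: float
    w_eeg: float
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w_task) and np.isfinite(self.w_eeg)):
            raise ValueError("mixture weights must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


#: Default generative mixtures: prefrontal strongly task-driven, parietal
#: strongly EEG-driven, motor/visual weakly driven by both, ACC intermediate.
DEFAULT_REGION_MIXTURES: tuple[RegionMixture, ...] = (
    RegionMixture("Prefrontal", 0.6, 0.3),
    RegionMixture("Parietal", 0.3, 0.6),
    RegionMixture("Motor", 0.1, 0.1),
    RegionMixture("Visual", 0.1, 0.1),
    RegionMixture("ACC", 0.45, 0.45),
)


@dataclass
class MultimodalSeries:
    """Paired EEG-power / BOLD feature series for one condition."""

    dt: float
    p_eeg: np.ndarray
    s_fmri: np.ndarray
    condition: str
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        self.p_eeg = np.asarray(self.p_eeg, float)
        self.s_fmri = np.asarray(self.s_fmri, float)
        if self.p_eeg.shape != self.s_fmri.shape:
            raise ValueError("p_eeg and s_fmri must have equal length")
        if not (np.all(np.isfinite(self.p_eeg)) and np.all(np.isfinite(self.s_fmri))):
            raise ValueError("multimodal series must be finite")


def rescale_to_range(x: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, bool]:
    """Affinely map x onto [lo, hi]; a constant input maps to the midpoint.

    Returns (rescaled, degenerate_flag).
    """
    x = np.asarray(x, float)
    xmin, xmax = float(np.min(x)), float(np.max(x))
    if xmax - xmin < 1e-12:
        return np.full_like(x, 0.5 * (lo + hi)), True
    return lo + (hi - lo) * (x - xmin) / (xmax - xmin), False


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    window = min(window, len(x))
    if window <= 1:
        return x.copy()
    # reflect-padded so the smoothed series keeps the input length
    return uniform_filter1d(x, size=window, mode="reflect")


def synthesize_eeg(
    traj: SyncTrajectory, smooth_window_s: float = 0.25
) -> tuple[np.ndarray, MultimodalSeries]:
    """Derive a raw EEG-like trace and its normalized power feature P_EEG.

    raw(t) is the mean-field cosine signal (1/N) Σ cos θ_j; its analytic-signal
    envelope squared — the instantaneous alpha power when the population
    oscillates near 10 Hz — is smoothed with a moving average (default 0.25 s)
    and affinely rescaled into the plausible EEG-power range [0.4, 0.8].
    """
    if traj.n_steps == 0:
        raise ValueError("empty trajectory")
    raw = np.mean(np.cos(traj.theta_series), axis=1)
    envelope = np.abs(hilbert(raw - np.mean(raw)))
    power = _moving_average(envelope**2, max(1, int(round(smooth_window_s / traj.dt))))
    p_eeg, degenerate = rescale_to_range(power, *EEG_POWER_RANGE)
    series = MultimodalSeries(
        dt=traj.dt, p_eeg=p_eeg, s_fmri=np.zeros_like(p_eeg), condition="", degenerate=degenerate
    )
    return raw, series


def canonical_hrf(dt: float, length: float = 32.0) -> HrfKernel:
    """Double-gamma canonical HRF sampled at dt, peak-normalized to 1.

    The response gamma density peaks at 5 s; a second gamma (peak 15 s,
    amplitude ratio 1:6) produces the post-peak undershoot before return to
    baseline.  ``length`` must cover the peak.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if length <= 6.0:
        raise ValueError("kernel length must exceed the ~5 s response peak")
    t = np.arange(0.0, length, dt)
    # gamma pdf with scale 1 peaks at (shape − 1): shapes 6 and 16 put the
    # response peak at 5 s and the undershoot trough near 15 s
    response = gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = response - undershoot / 6.0
    h = h / np.max(h)
    return HrfKernel(dt=dt, samples=h, peak_time=float(t[np.argmax(h)]))


def hrf_convolve(x: np.ndarray, kernel: HrfKernel) -> np.ndarray:
    """Causal discrete convolution with the HRF, truncated to the input length."""
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d series")
    return np.convolve(x, kernel.samples * kernel.dt)[: len(x)]


def task_block_design(n_samples: int, dt: float, block_s: float = 20.0) -> np.ndarray:
    """Boxcar task regressor: alternating on/off blocks (default 20 s), on first."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(n_samples) * dt
    return ((t // block_s).astype(int) % 2 == 0).astype(float)


def simulate_region_bold(
    task: np.ndarray,
    eeg: np.ndarray,
    mixtures: tuple[RegionMixture, ...] | list[RegionMixture] = DEFAULT_REGION_MIXTURES,
    kernel: HrfKernel | None = None,
    dt: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Generate region-level BOLD as linear mixtures of convolved regressors.

    Returns (regions: region × time, names, conv_task, conv_eeg): each row is
    w_task·HRF*task + w_eeg·HRF*eeg + noise_sd·N(0,1).
    """
    if len(mixtures) == 0:
        raise ValueError("need at least one region mixture")
    task = np.asarray(task, float)
    eeg = np.asarray(eeg, float)
    if task.shape != eeg.shape:
        raise ValueError("task and eeg series must share length")
    if kernel is None:
        kernel = canonical_hrf(dt)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conv_task = hrf_convolve(task, kernel)
    conv_eeg = hrf_convolve(eeg, kernel)
    regions = np.empty((len(mixtures), len(task)))
    for i, mix in enumerate(mixtures):
        noise = mix.noise_sd * rng.standard_normal(len(task)) if mix.noise_sd > 0 else 0.0
        regions[i] = mix.w_task * conv_task + mix.w_eeg * conv_eeg + noise
    return regions, [m.name for m in mixtures], conv_task, conv_eeg


def simulate_voxel_bold(
    regions: np.ndarray,
    per_region: int = 10,
    voxel_noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Expand region series into voxels: region signal + independent noise.

    Rows are grouped by region (region 0's voxels first).
    """
    if per_region < 1:
        raise ValueError("per_region must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_regions, n_t = regions.shape
    voxels = np.repeat(regions, per_region, axis=0)
    if voxel_noise_sd > 0:
        voxels = voxels + voxel_noise_sd * rng.standard_normal((n_regions * per_region, n_t))
    return voxels


def apply_onset_delay(x: np.ndarray, delay: float, dt: float) -> np.ndarray:
    """Right-shift a series by ``delay`` seconds, zero-filling the onset.

    Emulates biological signal latency at stimulus onset; the output keeps
    the input length.
    """
    x = np.asarray(x, float)
    if delay < 0:
        raise ValueError("delay must be non-negative")
    shift = delay / dt
    k = int(round(shift))
    if abs(shift - k) > 1e-6:
        raise ValueError(f"delay {delay} s is not a multiple of dt {dt} s")
    if k >= len(x):
        raise ValueError("delay must be shorter than the series")
    if k == 0:
        return x.copy()
    out = np.zeros_like(x)
    out[k:] = x[:-k]
    return out
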