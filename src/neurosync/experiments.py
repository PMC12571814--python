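"""Reproducible experiment drivers and multimodal file IO.

Three drivers mirror the study's result sections: a condition suite (three
firing-rate models × three cognitive conditions, stationary synchrony and
energy over seeds), a reinforcement-learning comparison (tabular Q-learning
vs DQN on the shared control environment), and a simulated-fMRI GLM /
connectivity / ICA experiment on 1,000-timepoint region and voxel data.
Every driver is fully seeded and writes plain CSV/JSON; a manifest (config
hash, seeds, version) makes runs replayable bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .control import (
    DqnConfig,
    EnvConfig,
    QTableConfig,
    SyncControlEnv,
    convergence_episode,
    evaluate_policy,
    run_episode,
    train_dqn,
    train_q_learning,
)
from .energy import EnergyWeights, energy, estimate_derivative
from .kuramoto import FrequencyModel, FrequencyKind, simulate_condition
from .metrics import correlation_matrix, glm_fit, ica_decompose
from .signals import (
    BOLD_RANGE,
    DEFAULT_REGION_MIXTURES,
    canonical_hrf,
    hrf_convolve,
    rescale_to_range,
    simulate_region_bold,
    simulate_voxel_bold,
    synthesize_eeg,
    task_block_design,
)

__all__ = [
    "RunConfig",
    "run_condition_suite",
    "run_rl_experiment",
    "run_glm_experiment",
    "make_multimodal_fixture",
    "write_multimodal_csv",
    "read_multimodal_csv",
    "write_manifest",
]

CONDITIONS = ("focused", "multitasking", "resting")
MODELS = ("intrinsic", "gaussian", "poisson_model")


@dataclass
class RunConfig:
    """Top-level experiment configuration; round-trips through YAML."""

    experiment: str = "condition_suite"
    n_oscillators: int = 10
    dt: float = 0.01
    duration: float = 10.0
    n_seeds: int = 20
    base_seed: int = 0
    q_episodes: int = 100
    dqn_episodes: int = 300
    eval_episodes: int = 20
    glm_timepoints: int = 1000
    out_dir: str = "runs"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(yaml.safe_dump(asdict(self)).encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: str | Path, seeds) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "experiment": config.experiment,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seeds": [int(s) for s in seeds],
        "version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _frequency_model(name: str) -> FrequencyModel:
    if name == "gaussian":
        return FrequencyModel.gaussian()
    return FrequencyModel(kind=FrequencyKind(name))


def energy_trace(traj, weights: EnergyWeights = EnergyWeights()) -> np.ndarray:
    """E(t) along a trajectory, using the trajectory's own EEG/BOLD features."""
    _, eeg = synthesize_eeg(traj)
    dRdt = estimate_derivative(traj.R_series, traj.dt)
    s_fmri, _ = rescale_to_range(hrf_convolve(traj.R_series, canonical_hrf(traj.dt)), *BOLD_RANGE)
    return energy(traj.R_series, dRdt, eeg.p_eeg, s_fmri, weights)


def run_condition_suite(config: RunConfig) -> pd.DataFrame:
    """Stationary synchrony and energy for all 9 model × condition cells.

    For each cell, ``n_seeds`` runs are simulated and the mean R and mean E
    over the stationary second half are averaged; the table carries
    mean/sd across seeds.
    """
    rows = []
    for model_name in MODELS:
        model = _frequency_model(model_name)
        for cond in CONDITIONS:
            Rs, Es, inst = [], [], []
            for s in range(config.n_seeds):
                traj = simulate_condition(
                    model,
                    cond,
                    n=config.n_oscillators,
                    dt=config.dt,
                    duration=config.duration,
                    seed=config.base_seed + s,
                )
                half = traj.n_steps // 2
                Rs.append(traj.stationary_mean_R())
                Es.append(float(np.mean(energy_trace(traj)[half:])))
                inst.append(float(np.std(traj.R_series[half:])))
            rows.append(
                {
                    "model": model_name,
                    "condition": cond,
                    "mean_R": float(np.mean(Rs)),
                    "sd_R": float(np.std(Rs, ddof=1)),
                    "mean_E": float(np.mean(Es)),
                    "sd_E": float(np.std(Es, ddof=1)),
                    # within-run temporal std of stationary R: "instability"
                    "instability": float(np.mean(inst)),
                }
            )
    return pd.DataFrame(rows)


def run_rl_experiment(config: RunConfig, env_config: EnvConfig | None = None) -> dict:
    """Train and compare the tabular and DQN controllers.

    Both agents share the environment and training-seed set; each trained
    greedy policy (and an untrained random baseline) is evaluated on
    ``eval_episodes`` fresh episodes.  Returns per-seed logs, evaluation
    metrics, convergence episodes, and the relative sync-error reductions of
    the DQN versus both the tabular agent and the random baseline.
    """
    env_config = env_config or EnvConfig(n_oscillators=config.n_oscillators, dt=config.dt)
    seeds = [config.base_seed + s for s in range(config.n_seeds)]
    results = {"seeds": seeds, "q": [], "dqn": [], "random": [], "convergence_episode": []}
    for seed in seeds:
        env = SyncControlEnv(env_config)
        q_policy, q_log = train_q_learning(
            env, QTableConfig(), episodes=config.q_episodes, seed=seed
        )
        dqn_policy, dqn_log = train_dqn(env, DqnConfig(), episodes=config.dqn_episodes, seed=seed)

        q_eval = evaluate_policy(q_policy, env, config.eval_episodes, seed=seed + 10_000)
        dqn_eval = evaluate_policy(dqn_policy, env, config.eval_episodes, seed=seed + 10_000)
        rng = np.random.default_rng(seed + 20_000)
        rand_errs = []
        for ep in range(config.eval_episodes):
            cond = env_config.conditions[ep % len(env_config.conditions)]
            summary = run_episode(env, cond, lambda obs, r: int(r.integers(env.n_actions)), rng)
            rand_errs.append(summary["sync_error"])

        results["q"].append({"log": q_log, "eval": q_eval})
        results["dqn"].append({"log": dqn_log, "eval": dqn_eval})
        results["random"].append({"mean_sync_error": float(np.mean(rand_errs))})
        results["convergence_episode"].append(
            convergence_episode(dqn_log.cumulative_reward, window=20, tol=0.05)
        )

    err_q = float(np.mean([r["eval"]["mean_sync_error"] for r in results["q"]]))
    err_dqn = float(np.mean([r["eval"]["mean_sync_error"] for r in results["dqn"]]))
    err_rand = float(np.mean([r["mean_sync_error"] for r in results["random"]]))
    results["summary"] = {
        "mean_sync_error_q": err_q,
        "mean_sync_error_dqn": err_dqn,
        "mean_sync_error_random": err_rand,
        "error_reduction_vs_q_pct": 100.0 * (err_q - err_dqn) / err_q,
        "error_reduction_vs_random_pct": 100.0 * (err_rand - err_dqn) / err_rand,
        "median_convergence_episode": float(
            np.median([c for c in results["convergence_episode"] if c is not None])
        )
        if any(c is not None for c in results["convergence_episode"])
        else None,
    }
    return results


def run_glm_experiment(config: RunConfig, noise_sd: float | None = None, seed: int | None = None) -> dict:
    """Simulated-fMRI analysis: region/voxel generation, GLMs, connectivity, ICA.

    1,000 timepoints at 1 s resolution; the EEG-power regressor is the
    normalized envelope feature of a resting-condition oscillator run,
    block-averaged to the BOLD sampling rate.  Fits a task-only GLM and a
    task+EEG GLM per region, a 5×5 region and 50×50 voxel correlation
    matrix, and a 3-component ICA.
    """
    seed = config.base_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_t = config.glm_timepoints
    tr = 1.0

    # EEG-power regressor from oscillator dynamics, block-averaged to the TR
    traj = simulate_condition(
        _frequency_model("intrinsic"), "resting", n=config.n_oscillators,
        dt=config.dt, duration=n_t * tr, seed=rng,
    )
    _, eeg_series = synthesize_eeg(traj)
    per_tr = int(round(tr / config.dt))
    p_eeg = eeg_series.p_eeg[: n_t * per_tr].reshape(n_t, per_tr).mean(axis=1)

    task = task_block_design(n_t, tr)
    mixtures = DEFAULT_REGION_MIXTURES
    if noise_sd is not None:
        mixtures = tuple(
            type(m)(m.name, m.w_task, m.w_eeg, noise_sd) for m in mixtures
        )
    regions, names, conv_task, conv_eeg = simulate_region_bold(
        task, p_eeg, mixtures, dt=tr, seed=rng
    )
    voxels = simulate_voxel_bold(regions, per_region=10, voxel_noise_sd=0.05, seed=rng)

    task_only, task_eeg = {}, {}
    for name, y in zip(names, regions):
        task_only[name] = glm_fit(y, [conv_task], names=["task_hrf"])
        task_eeg[name] = glm_fit(y, [conv_task, conv_eeg], names=["task_hrf", "eeg_hrf"])

    comps, mixing, converged = ica_decompose(regions, k=3, seed=seed)
    return {
        "region_names": names,
        "regions": regions,
        "voxels": voxels,
        "conv_task": conv_task,
        "conv_eeg": conv_eeg,
        "glm_task_only": task_only,
        "glm_task_eeg": task_eeg,
        "region_corr": correlation_matrix(regions, names),
        "voxel_corr": correlation_matrix(voxels),
        "ica_components": comps,
        "ica_mixing": mixing,
        "ica_converged": converged,
    }


# -- multimodal CSV -------------------------------------------------------

REQUIRED_COLUMNS = ("time_s", "p_eeg", "s_fmri", "condition")


def make_multimodal_fixture(
    samples_per_condition: int = 300,
    dt: float = 0.01,
    n: int = 10,
    seed: int = 0,
    onset_delay: float = 0.0,
) -> pd.DataFrame:
    """Synthetic paired EEG-power/BOLD table: per condition, one oscillator
    run yields ``samples_per_condition`` time-synchronized samples of the
    normalized P_EEG and S_fMRI features (balanced across the three
    conditions, 900 rows by default).  The stored EEG feature is the
    smoothed mean-field envelope power; the BOLD feature is the
    HRF-convolved order parameter — both affinely normalized."""
    from .signals import apply_onset_delay

    frames = []
    rng = np.random.default_rng(seed)
    for cond in CONDITIONS:
        traj = simulate_condition(
            _frequency_model("intrinsic"), cond, n=n, dt=dt,
            duration=samples_per_condition * dt, seed=rng,
        )
        _, eeg = synthesize_eeg(traj)
        s_fmri, _ = rescale_to_range(
            hrf_convolve(traj.R_series, canonical_hrf(dt)), *BOLD_RANGE
        )
        p_eeg = eeg.p_eeg[:samples_per_condition]
        s_fmri = s_fmri[:samples_per_condition]
        if onset_delay > 0:
            p_eeg = apply_onset_delay(p_eeg, onset_delay, dt)
            s_fmri = apply_onset_delay(s_fmri, onset_delay, dt)
        frames.append(
            pd.DataFrame(
                {
                    "time_s": np.arange(samples_per_condition) * dt,
                    "p_eeg": p_eeg,
                    "s_fmri": s_fmri,
                    "condition": cond,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_multimodal_csv(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df.to_csv(path, index=False)


def read_multimodal_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    for cond, grp in df.groupby("condition"):
        if np.any(np.diff(grp["time_s"].to_numpy()) <= 0):
            raise ValueError(f"non-monotone time_s within condition {cond!r}")
    return df
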