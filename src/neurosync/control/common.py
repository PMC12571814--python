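"""Shared training utilities: exploration schedule, episode logs, evaluation
and the learning-curve plateau criterion."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EpsilonSchedule", "EpisodeLog", "evaluate_policy", "convergence_episode"]


@dataclass(frozen=True)
class EpsilonSchedule:
    """Exponentially decaying ε-greedy exploration rate.

    ε(episode) = max(floor, start · exp(−episode/tau)); monotonically
    non-increasing.  ``tau`` defaults to one sixth of the training budget so
    exploration is essentially done by the final third of training.
    """

    start: float = 1.0
    floor: float = 0.05
    tau: float = 50.0

    def __call__(self, episode: int) -> float:
        return float(max(self.floor, self.start * np.exp(-episode / self.tau)))

    @classmethod
    def for_budget(cls, episodes: int, start: float = 1.0, floor: float = 0.05) -> "EpsilonSchedule":
        return cls(start=start, floor=floor, tau=max(1.0, episodes / 6.0))


@dataclass
class EpisodeLog:
    """Per-episode training traces."""

    cumulative_reward: list[float] = field(default_factory=list)
    mean_R: list[float] = field(default_factory=list)
    mean_E: list[float] = field(default_factory=list)
    sync_error: list[float] = field(default_factory=list)
    epsilon: list[float] = field(default_factory=list)
    condition: list[str] = field(default_factory=list)
    seed: int | None = None

    def append(self, *, cumulative_reward, mean_R, mean_E, sync_error, epsilon, condition) -> None:
        self.cumulative_reward.append(float(cumulative_reward))
        self.mean_R.append(float(mean_R))
        self.mean_E.append(float(mean_E))
        self.sync_error.append(float(sync_error))
        self.epsilon.append(float(epsilon))
        self.condition.append(str(condition))

    def __len__(self) -> int:
        return len(self.cumulative_reward)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "episode": np.arange(len(self)),
                "cumulative_reward": self.cumulative_reward,
                "mean_R": self.mean_R,
                "mean_E": self.mean_E,
                "sync_error": self.sync_error,
                "epsilon": self.epsilon,
                "condition": self.condition,
            }
        )


def run_episode(env, condition: str, policy_fn, rng: np.random.Generator, learner=None):
    """Roll one episode; ``policy_fn(obs, rng) -> action``; optional
    ``learner.observe(obs, a, r, obs2, done)`` hook.  Returns summary dict."""
    obs = env.reset(condition, rng)
    total_r = 0.0
    Rs, Es, errs = [], [], []
    for _ in range(env.config.episode_steps):
        a = policy_fn(obs, rng)
        obs2, r, info = env.step(a)
        if learner is not None:
            learner.observe(obs, a, r, obs2, info["done"])
        total_r += r
        Rs.append(info["mean_R"])
        Es.append(info["mean_E"])
        errs.append(info["sync_error"])
        obs = obs2
    return {
        "cumulative_reward": total_r,
        "mean_R": float(np.mean(Rs)),
        "mean_E": float(np.mean(Es)),
        "sync_error": float(np.mean(errs)),
    }


def evaluate_policy(policy, env, n_episodes: int = 20, seed: int = 0) -> dict:
    """Greedy (ε = 0) evaluation over fresh seeded episodes.

    Conditions cycle deterministically through the environment's condition
    list.  Returns mean sync error |R_target − R|, mean energy and mean
    cumulative reward, plus the per-episode values.
    """
    rng = np.random.default_rng(seed)
    conditions = env.config.conditions
    per_episode = []
    for ep in range(n_episodes):
        cond = conditions[ep % len(conditions)]
        summary = run_episode(env, cond, lambda obs, r: policy.act(obs), rng)
        summary["condition"] = cond
        per_episode.append(summary)
    return {
        "mean_sync_error": float(np.mean([s["sync_error"] for s in per_episode])),
        "mean_energy": float(np.mean([s["mean_E"] for s in per_episode])),
        "mean_cumulative_reward": float(np.mean([s["cumulative_reward"] for s in per_episode])),
        "episodes": per_episode,
    }


def convergence_episode(rewards, window: int = 20, tol: float = 0.05):
    """First episode whose moving-mean reward has settled, or None.

    The reference level m is the mean over the final quartile of the series.
    Episode e qualifies if every window mean over [e', e'+window), e' ≥ e,
    lies within tol·|m| of m.  Returns None when the curve never settles.
    """
    rewards = np.asarray(rewards, float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(rewards) < window:
        raise ValueError("series shorter than the window")
    m = float(np.mean(rewards[-max(1, len(rewards) // 4) :]))
    band = tol * abs(m)
    kernel = np.ones(window) / window
    moving = np.convolve(rewards, kernel, mode="valid")  # moving[i] = mean over [i, i+window)
    ok = np.abs(moving - m) <= band
    # first index from which every later window is inside the band
    settled = None
    for i in range(len(ok) - 1, -1, -1):
        if not ok[i]:
            break
        settled = i
    return settled
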