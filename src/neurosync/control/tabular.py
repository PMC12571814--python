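"""Tabular Q-learning over a discretized (R, E) state space.

The agent maintains a state-action value table updated by the classical
temporal-difference rule

    Q(s,a) ← Q(s,a) + η [r + γ max_a' Q(s',a') − Q(s,a)],

with an ε-greedy behaviour policy.  States are row-major indices over
(R-bin, E-bin); the default grid is 10 × 10 over R ∈ [0, 1] and E clipped to
[0, 20].  The task context is deliberately absent from the tabular state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .common import EpisodeLog, EpsilonSchedule, run_episode

__all__ = [
    "make_bins",
    "discretize_state",
    "q_update",
    "select_action",
    "QTableConfig",
    "TabularPolicy",
    "train_q_learning",
]


def make_bins(n_bins: int, low: float, high: float) -> np.ndarray:
    """Equal-width bin edges (n_bins + 1 values) over [low, high]."""
    return np.linspace(low, high, n_bins + 1)


def _bin_index(value: float, edges: np.ndarray) -> int:
    if not np.isfinite(value):
        raise ValueError(f"cannot discretize non-finite value {value}")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    idx = int(np.searchsorted(edges, value, side="right")) - 1
    return int(np.clip(idx, 0, len(edges) - 2))


def discretize_state(R: float, E: float, bins_R: np.ndarray, bins_E: np.ndarray) -> int:
    """Row-major (R-bin, E-bin) index; values at/above the top edge clamp to
    the top bin, values below the bottom edge to bin 0."""
    n_e = len(bins_E) - 1
    return _bin_index(R, bins_R) * n_e + _bin_index(E, bins_E)


def q_update(q: float, r: float, max_next: float, eta: float, discount: float) -> float:
    """One temporal-difference backup toward r + γ·max_a' Q(s',a')."""
    if not (0.0 <= eta <= 1.0):
        raise ValueError("eta must lie in [0, 1]")
    if not (0.0 <= discount < 1.0):
        raise ValueError("discount must lie in [0, 1)")
    return q + eta * (r + discount * max_next - q)


def select_action(q_row: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """ε-greedy choice: argmax with probability 1−ε (ties → lowest index),
    otherwise uniform random."""
    q_row = np.asarray(q_row, float)
    if q_row.size == 0:
        raise ValueError("empty action-value row")
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(q_row.size))
    return int(np.argmax(q_row))


@dataclass(frozen=True)
class QTableConfig:
    """Hyperparameters of the tabular agent."""

    bins_R: np.ndarray = field(default_factory=lambda: make_bins(10, 0.0, 1.0))
    bins_E: np.ndarray = field(default_factory=lambda: make_bins(10, 0.0, 20.0))
    eta: float = 0.1
    discount: float = 0.95
    epsilon: EpsilonSchedule | None = None  # None → derived from the budget


class TabularPolicy:
    """A trained Q-table plus its state encoder."""

    def __init__(self, table: np.ndarray, state_fn):
        self.table = table
        self.state_fn = state_fn

    def act(self, obs) -> int:
        return int(np.argmax(self.table[self.state_fn(obs)]))

    def q_row(self, obs) -> np.ndarray:
        return self.table[self.state_fn(obs)]

    def save(self, path) -> None:
        """Write the value table as CSV (one row per state)."""
        np.savetxt(path, self.table, delimiter=",")


class _TabularLearner:
    def __init__(self, table, state_fn, eta, discount):
        self.table, self.state_fn = table, state_fn
        self.eta, self.discount = eta, discount

    def observe(self, obs, a, r, obs2, done) -> None:
        s, s2 = self.state_fn(obs), self.state_fn(obs2)
        max_next = 0.0 if done else float(np.max(self.table[s2]))
        self.table[s, a] = q_update(self.table[s, a], r, max_next, self.eta, self.discount)


def train_q_learning(
    env,
    config: QTableConfig = QTableConfig(),
    episodes: int = 100,
    seed: int = 0,
    state_fn=None,
    n_states: int | None = None,
) -> tuple[TabularPolicy, EpisodeLog]:
    """Train a tabular agent on the environment for a fixed episode budget.

    Conditions cycle deterministically through ``env.config.conditions``.
    ``state_fn``/``n_states`` override the default (R, E)-bin encoder — used
    for environments whose observations are already discrete.
    """
    rng = np.random.default_rng(seed)
    if state_fn is None:
        bins_R, bins_E = config.bins_R, config.bins_E
        state_fn = lambda obs: discretize_state(obs["R"], obs["E"], bins_R, bins_E)
        n_states = (len(bins_R) - 1) * (len(bins_E) - 1)
    if n_states is None:
        raise ValueError("n_states is required with a custom state_fn")
    table = np.zeros((n_states, env.n_actions))
    schedule = config.epsilon or EpsilonSchedule.for_budget(episodes)
    learner = _TabularLearner(table, state_fn, config.eta, config.discount)
    log = EpisodeLog(seed=seed)
    conditions = env.config.conditions
    for ep in range(episodes):
        eps = schedule(ep)
        cond = conditions[ep % len(conditions)]
        policy_fn = lambda obs, r: select_action(table[state_fn(obs)], eps, r)
        summary = run_episode(env, cond, policy_fn, rng, learner=learner)
        log.append(epsilon=eps, condition=cond, **summary)
    return TabularPolicy(table, state_fn), log
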