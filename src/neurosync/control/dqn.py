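"""Deep Q-Network with a compact fully-connected value network.

The action-value function Q(s, a; θ) is a multilayer perceptron with two
hidden ReLU layers and a linear head with one output per action, trained on
minibatches drawn from an experience-replay buffer against a periodically
refreshed target network, using the Adam optimizer on the squared
temporal-difference error.  The network, its backpropagation and Adam are
implemented directly on numpy arrays, which keeps training deterministic
under a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .common import EpisodeLog, EpsilonSchedule, run_episode
from .tabular import select_action

__all__ = ["MLP", "ReplayBuffer", "DqnConfig", "DqnPolicy", "train_dqn"]


class MLP:
    """Fully-connected ReLU network with a linear output layer."""

    def __init__(self, sizes: tuple[int, ...], rng: np.random.Generator):
        self.sizes = tuple(sizes)
        self.W = [
            rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(fan_out) for fan_out in sizes[1:]]

    def forward(self, X: np.ndarray, cache: bool = False):
        acts = [np.atleast_2d(X)]
        h = acts[0]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = z if i == len(self.W) - 1 else np.maximum(z, 0.0)
            acts.append(h)
        return (h, acts) if cache else h

    def gradients(self, acts: list[np.ndarray], dout: np.ndarray):
        """Backpropagate dLoss/doutput; returns (dW, db) lists."""
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        delta = dout
        for i in range(len(self.W) - 1, -1, -1):
            dW[i] = acts[i].T @ delta
            db[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        return dW, db

    def copy_from(self, other: "MLP") -> None:
        self.W = [w.copy() for w in other.W]
        self.b = [b.copy() for b in other.b]


class _Adam:
    def __init__(self, net: MLP, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.beta1, self.beta2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.mW = [np.zeros_like(w) for w in net.W]
        self.vW = [np.zeros_like(w) for w in net.W]
        self.mb = [np.zeros_like(b) for b in net.b]
        self.vb = [np.zeros_like(b) for b in net.b]

    def step(self, dW, db) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1, corr2 = 1 - b1**self.t, 1 - b2**self.t
        for i in range(len(self.net.W)):
            for params, grads, m, v in (
                (self.net.W, dW, self.mW, self.vW),
                (self.net.b, db, self.mb, self.vb),
            ):
                m[i] = b1 * m[i] + (1 - b1) * grads[i]
                v[i] = b2 * v[i] + (1 - b2) * grads[i] ** 2
                params[i] -= self.lr * (m[i] / corr1) / (np.sqrt(v[i] / corr2) + self.eps)


class ReplayBuffer:
    """Fixed-capacity ring buffer of (s, a, r, s', done) transitions."""

    def __init__(self, capacity: int, state_dim: int):
        self.capacity = capacity
        self.s = np.zeros((capacity, state_dim))
        self.a = np.zeros(capacity, dtype=int)
        self.r = np.zeros(capacity)
        self.s2 = np.zeros((capacity, state_dim))
        self.done = np.zeros(capacity, dtype=bool)
        self.size = 0
        self._ptr = 0

    def push(self, s, a, r, s2, done) -> None:
        i = self._ptr
        self.s[i], self.a[i], self.r[i], self.s2[i], self.done[i] = s, a, r, s2, done
        self._ptr = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch: int, rng: np.random.Generator):
        idx = rng.integers(self.size, size=batch)
        return self.s[idx], self.a[idx], self.r[idx], self.s2[idx], self.done[idx]


@dataclass(frozen=True)
class DqnConfig:
    """Hyperparameters of the DQN agent."""

    hidden: tuple[int, int] = (64, 64)
    replay_capacity: int = 10_000
    batch_size: int = 64
    target_update: int = 100  # gradient steps between target-network refreshes
    lr: float = 1e-3
    discount: float = 0.95
    warmup: int = 200  # transitions collected before updates begin
    epsilon: EpsilonSchedule | None = None

    def __post_init__(self) -> None:
        if len(self.hidden) != 2:
            raise ValueError("the value network uses exactly two hidden layers")
        if self.replay_capacity < self.batch_size:
            raise ValueError("replay capacity must be >= batch size")


class DqnPolicy:
    """A trained value network plus the environment's state encoder."""

    def __init__(self, net: MLP, encode):
        self.net = net
        self.encode = encode

    def q_values(self, obs) -> np.ndarray:
        return self.net.forward(self.encode(obs))[0]

    def act(self, obs) -> int:
        return int(np.argmax(self.q_values(obs)))

    def save(self, path) -> None:
        """Write network weights to an .npz archive."""
        arrays = {f"W{i}": w for i, w in enumerate(self.net.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.net.b)})
        np.savez(path, **arrays)


class _DqnLearner:
    def __init__(self, net, target, buffer, opt, cfg: DqnConfig, encode, rng):
        self.net, self.target, self.buffer, self.opt = net, target, buffer, opt
        self.cfg, self.encode, self.rng = cfg, encode, rng
        self.steps = 0

    def observe(self, obs, a, r, obs2, done) -> None:
        self.buffer.push(self.encode(obs), a, r, self.encode(obs2), done)
        self.steps += 1
        if self.buffer.size < max(self.cfg.warmup, self.cfg.batch_size):
            return
        s, a_b, r_b, s2, done_b = self.buffer.sample(self.cfg.batch_size, self.rng)
        q_next = self.target.forward(s2).max(axis=1)
        target_q = r_b + self.cfg.discount * q_next * (~done_b)
        q, acts = self.net.forward(s, cache=True)
        if not np.all(np.isfinite(q)):
            raise FloatingPointError("DQN loss diverged: non-finite Q-values")
        dout = np.zeros_like(q)
        rows = np.arange(len(a_b))
        dout[rows, a_b] = 2.0 * (q[rows, a_b] - target_q) / len(a_b)
        self.opt.step(*self.net.gradients(acts, dout))
        if self.opt.t % self.cfg.target_update == 0:
            self.target.copy_from(self.net)


def train_dqn(
    env,
    config: DqnConfig = DqnConfig(),
    episodes: int = 300,
    seed: int = 0,
    encode=None,
    state_dim: int | None = None,
) -> tuple[DqnPolicy, EpisodeLog]:
    """Train a DQN on the environment for a fixed episode budget.

    The state encoder defaults to the environment's continuous encoding
    (R, E, condition one-hot); pass ``encode``/``state_dim`` for other
    observation types.  Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if encode is None:
        encode = env.encode_continuous
        state_dim = env.n_state_features
    if state_dim is None:
        raise ValueError("state_dim is required with a custom encoder")
    net = MLP((state_dim, *config.hidden, env.n_actions), rng)
    target = MLP((state_dim, *config.hidden, env.n_actions), rng)
    target.copy_from(net)
    buffer = ReplayBuffer(config.replay_capacity, state_dim)
    opt = _Adam(net, config.lr)
    learner = _DqnLearner(net, target, buffer, opt, config, encode, rng)
    schedule = config.epsilon or EpsilonSchedule.for_budget(episodes)
    log = EpisodeLog(seed=seed)
    conditions = env.config.conditions
    for ep in range(episodes):
        eps = schedule(ep)
        cond = conditions[ep % len(conditions)]
        policy_fn = lambda obs, r: select_action(net.forward(encode(obs))[0], eps, r)
        summary = run_episode(env, cond, policy_fn, rng, learner=learner)
        log.append(epsilon=eps, condition=cond, **summary)
    return DqnPolicy(net, encode), log
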