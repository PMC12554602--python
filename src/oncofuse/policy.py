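"""Q-learning treatment policies on tabular toy-oncology MDPs.

A patient's course of care is modeled as a finite Markov decision process
``(S, A, P, r, gamma)``: health states, treatment actions, transition
probabilities, clinical reward (positive for response, negative for
toxicity) and a discount factor.  The learner is tabular Q-learning with
experience replay, a periodically synchronized target table, epsilon-greedy
exploration and an entropy-regularized temporal-difference loss

    L = mean[(Q(s,a) - (r + gamma max_a' Q_target(s',a')))^2] - lambda_H H(pi),

where the policy ``pi(.|s) = softmax(Q(s,.)/temperature)`` is the soft
reading of the Q-table.  Synchronous value iteration provides the exact
optimal Q-table as an independent check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax as _softmax
from sklearn.base import BaseEstimator

__all__ = [
    "MDPSpec",
    "Transition",
    "discounted_return",
    "bellman_target",
    "td_loss",
    "epsilon_greedy",
    "greedy_action",
    "value_iteration",
    "QLearningPolicy",
    "train_q_learning",
    "toy_oncology_mdp",
    "chain_mdp",
]


@dataclass(frozen=True)
class MDPSpec:
    """Tabular MDP: dense transition tensor and reward table.

    ``transitions[s, a, s']`` is P(s'|s, a); ``rewards`` is (|S|, |A|) for
    r(s, a) or (|S|, |A|, |S|) for r(s, a, s').
    """

    states: tuple
    actions: tuple
    transitions: np.ndarray
    rewards: np.ndarray
    gamma: float
    terminal_states: frozenset = frozenset()
    initial_distribution: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "transitions",
                           np.asarray(self.transitions, dtype=np.float64))
        object.__setattr__(self, "rewards", np.asarray(self.rewards, dtype=np.float64))
        if self.initial_distribution is not None:
            object.__setattr__(self, "initial_distribution",
                               np.asarray(self.initial_distribution, dtype=np.float64))

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    def validate(self) -> None:
        ns, na = self.n_states, self.n_actions
        if self.transitions.shape != (ns, na, ns):
            raise ValueError(f"transition tensor must be {(ns, na, ns)}, "
                             f"got {self.transitions.shape}")
        row_sums = self.transitions.sum(axis=2)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            s, a = np.unravel_index(np.argmax(np.abs(row_sums - 1.0)), row_sums.shape)
            raise ValueError(
                f"P(.|{self.states[s]}, {self.actions[a]}) sums to {row_sums[s, a]}, not 1"
            )
        if (self.transitions < 0).any():
            raise ValueError("transition probabilities must be nonnegative")
        if self.rewards.shape not in ((ns, na), (ns, na, ns)):
            raise ValueError(f"rewards must be (S, A) or (S, A, S), got {self.rewards.shape}")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        unknown = set(self.terminal_states) - set(self.states)
        if unknown:
            raise ValueError(f"unknown terminal states {sorted(unknown)}")
        if self.initial_distribution is not None:
            if self.initial_distribution.shape != (ns,) or \
               not np.isclose(self.initial_distribution.sum(), 1.0, atol=1e-9):
                raise ValueError("initial_distribution must be a probability vector over S")

    def expected_rewards(self) -> np.ndarray:
        """r(s, a) — averaging over s' if rewards are (S, A, S)."""
        if self.rewards.ndim == 2:
            return self.rewards
        return np.einsum("sat,sat->sa", self.transitions, self.rewards)

    def terminal_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.states)
                         if s in self.terminal_states], dtype=np.int64)

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "states": list(self.states),
            "actions": list(self.actions),
            "transitions": self.transitions.tolist(),
            "rewards": self.rewards.tolist(),
            "gamma": self.gamma,
            "terminal_states": sorted(self.terminal_states),
            "initial_distribution": (None if self.initial_distribution is None
                                     else self.initial_distribution.tolist()),
        })

    @classmethod
    def from_json(cls, text: str) -> "MDPSpec":
        d = json.loads(text)
        return cls(
            states=tuple(d["states"]),
            actions=tuple(d["actions"]),
            transitions=np.array(d["transitions"]),
            rewards=np.array(d["rewards"]),
            gamma=float(d["gamma"]),
            terminal_states=frozenset(d.get("terminal_states", [])),
            initial_distribution=(None if d.get("initial_distribution") is None
                                  else np.array(d["initial_distribution"])),
        )


@dataclass(frozen=True)
class Transition:
    """One (s, a, r, s', done) record sampled from a patient trajectory."""

    state: int
    action: int
    reward: float
    next_state: int
    done: bool


def discounted_return(rewards, gamma: float) -> float:
    """``sum_t gamma^t r_t``; an empty sequence returns 0 by convention."""
    rewards = np.asarray(list(rewards), dtype=np.float64)
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    if rewards.size == 0:
        return 0.0
    return float(np.sum(gamma ** np.arange(rewards.size) * rewards))


def bellman_target(reward: float, next_state: int, done: bool,
                   q_target: np.ndarray, gamma: float) -> float:
    """``r`` for terminal transitions, else ``r + gamma max_a' Q_target(s', a')``."""
    if done:
        return float(reward)
    return float(reward + gamma * np.max(q_target[next_state]))


def _policy_entropy(q_rows: np.ndarray, temperature: float) -> np.ndarray:
    pi = _softmax(q_rows / temperature, axis=-1)
    return -np.sum(pi * np.log(np.clip(pi, 1e-300, None)), axis=-1)


def td_loss(q: np.ndarray, batch: list[Transition], q_target: np.ndarray,
            gamma: float, entropy_weight: float = 0.0,
            temperature: float = 1.0) -> float:
    """Mean squared TD error minus entropy bonus of the softmax policy."""
    if not batch:
        raise ValueError("td_loss requires a nonempty batch")
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    states = np.array([t.state for t in batch])
    targets = np.array([
        bellman_target(t.reward, t.next_state, t.done, q_target, gamma)
        for t in batch
    ])
    values = q[states, [t.action for t in batch]]
    td = float(np.mean((values - targets) ** 2))
    if entropy_weight:
        td -= entropy_weight * float(np.mean(_policy_entropy(q[states], temperature)))
    return td


def _td_gradient(q: np.ndarray, batch: list[Transition], q_target: np.ndarray,
                 gamma: float, entropy_weight: float,
                 temperature: float) -> np.ndarray:
    """Analytic gradient of :func:`td_loss` w.r.t. the Q-table (targets constant)."""
    grad = np.zeros_like(q)
    n = len(batch)
    for t in batch:
        target = bellman_target(t.reward, t.next_state, t.done, q_target, gamma)
        grad[t.state, t.action] += 2.0 * (q[t.state, t.action] - target) / n
        if entropy_weight:
            pi = _softmax(q[t.state] / temperature)
            h = -np.sum(pi * np.log(np.clip(pi, 1e-300, None)))
            # d(-H)/dq_k = (1/temp) * pi_k * (log pi_k + H)
            grad[t.state] += entropy_weight / temperature * pi * \
                (np.log(np.clip(pi, 1e-300, None)) + h) / n
    return grad


def greedy_action(q_row: np.ndarray) -> int:
    """Argmax with lowest-index tie-breaking."""
    q_row = np.asarray(q_row, dtype=np.float64)
    if q_row.size == 0:
        raise ValueError("empty action set")
    if not np.isfinite(q_row).all():
        raise ValueError("q_row must be finite")
    return int(np.argmax(q_row))


def epsilon_greedy(q_row: np.ndarray, epsilon: float,
                   rng: np.random.Generator | int) -> int:
    """Uniform random action with probability epsilon, else the greedy one."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    q_row = np.asarray(q_row, dtype=np.float64)
    if q_row.size == 0:
        raise ValueError("empty action set")
    if rng.random() < epsilon:
        return int(rng.integers(0, q_row.size))
    return greedy_action(q_row)


def value_iteration(mdp: MDPSpec, tolerance: float = 1e-10,
                    max_iterations: int = 100_000) -> np.ndarray:
    """Synchronous value iteration to the optimal action-value table Q*."""
    mdp.validate()
    r = mdp.expected_rewards()
    q = np.zeros((mdp.n_states, mdp.n_actions))
    terminal = mdp.terminal_indices()
    for _ in range(max_iterations):
        v = q.max(axis=1)
        v[terminal] = 0.0  # no value accrues beyond an absorbing terminal state
        q_new = r + mdp.gamma * mdp.transitions @ v
        if terminal.size:
            q_new[terminal] = r[terminal]
        if np.max(np.abs(q_new - q)) < tolerance:
            return q_new
        q = q_new
    raise RuntimeError(f"value iteration did not converge in {max_iterations} iterations")


class QLearningPolicy(BaseEstimator):
    """Tabular Q-learning with replay, target table and epsilon-greedy acting.

    ``fit(mdp)`` simulates episodes in the MDP and descends the
    entropy-regularized TD loss with plain SGD on the Q-table.  Fitted
    attributes: ``q_`` (learned table), ``episode_returns_``, ``log_``.
    """

    def __init__(self, episodes: int = 2000, max_steps: int = 50,
                 learning_rate: float = 0.1,
                 epsilon_start: float = 1.0, epsilon_end: float = 0.05,
                 epsilon_decay_steps: int = 5000,
                 entropy_weight: float = 0.0, temperature: float = 1.0,
                 replay_capacity: int = 4000, batch_size: int = 32,
                 target_sync_interval: int = 100, random_state: int = 0):
        self.episodes = episodes
        self.max_steps = max_steps
        self.learning_rate = learning_rate
        self.epsilon_start = epsilon_start
        self.epsilon_end = epsilon_end
        self.epsilon_decay_steps = epsilon_decay_steps
        self.entropy_weight = entropy_weight
        self.temperature = temperature
        self.replay_capacity = replay_capacity
        self.batch_size = batch_size
        self.target_sync_interval = target_sync_interval
        self.random_state = random_state

    def _epsilon(self, step: int) -> float:
        frac = min(1.0, step / max(1, self.epsilon_decay_steps))
        return self.epsilon_start + frac * (self.epsilon_end - self.epsilon_start)

    def fit(self, mdp: MDPSpec, y=None):
        mdp.validate()
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        rng = np.random.default_rng(self.random_state)
        ns, na = mdp.n_states, mdp.n_actions
        q = np.zeros((ns, na))
        q_target = q.copy()
        terminal = set(mdp.terminal_indices().tolist())
        rewards_sa = mdp.rewards
        init = (mdp.initial_distribution if mdp.initial_distribution is not None
                else np.full(ns, 1.0 / ns))

        replay: list[Transition] = []
        returns, log = [], []
        step_count = 0
        for episode in range(self.episodes):
            state = int(rng.choice(ns, p=init))
            rewards = []
            for _ in range(self.max_steps):
                if state in terminal:
                    break
                action = epsilon_greedy(q[state], self._epsilon(step_count), rng)
                next_state = int(rng.choice(ns, p=mdp.transitions[state, action]))
                reward = float(rewards_sa[state, action] if rewards_sa.ndim == 2
                               else rewards_sa[state, action, next_state])
                done = next_state in terminal
                transition = Transition(state, action, reward, next_state, done)
                if len(replay) >= self.replay_capacity:
                    replay.pop(0)
                replay.append(transition)
                rewards.append(reward)

                if len(replay) >= self.batch_size:
                    pick = rng.choice(len(replay), size=self.batch_size, replace=False)
                    batch = [replay[i] for i in pick]
                    grad = _td_gradient(q, batch, q_target, mdp.gamma,
                                        self.entropy_weight, self.temperature)
                    if not np.isfinite(grad).all():
                        raise RuntimeError(
                            f"Q-learning diverged at episode {episode}: non-finite gradient"
                        )
                    q -= self.learning_rate * grad
                step_count += 1
                if step_count % self.target_sync_interval == 0:
                    q_target = q.copy()
                state = next_state
            episode_return = discounted_return(rewards, mdp.gamma)
            returns.append(episode_return)
            if (episode + 1) % max(1, self.episodes // 20) == 0:
                log.append({"episode": episode + 1,
                            "mean_return": float(np.mean(returns[-100:])),
                            "epsilon": self._epsilon(step_count)})
        self.q_ = q
        self.episode_returns_ = np.asarray(returns)
        self.log_ = log
        self.mdp_ = mdp
        return self

    def predict(self, states) -> np.ndarray:
        """Greedy treatment recommendation per state index."""
        states = np.atleast_1d(np.asarray(states, dtype=np.int64))
        return np.array([greedy_action(self.q_[s]) for s in states])

    def policy_distribution(self) -> np.ndarray:
        """Softmax policy pi(a|s) implied by the learned Q-table."""
        return _softmax(self.q_ / self.temperature, axis=1)


def train_q_learning(mdp: MDPSpec, seed: int = 0, **params):
    """Thin wrapper: fit a :class:`QLearningPolicy`, return (Q, returns, log)."""
    agent = QLearningPolicy(random_state=seed, **params)
    agent.fit(mdp)
    return agent.q_, agent.episode_returns_, agent.log_


def chain_mdp() -> MDPSpec:
    """Deterministic 4-state / 2-action chain used as a convergence fixture.

    Action 0 ("advance") moves one state toward the absorbing end state and
    pays 1.0 on reaching it (0.2 otherwise); action 1 ("stay") loops with
    reward 0.1.  With gamma < 1 the optimal policy advances everywhere.
    """
    ns, na = 4, 2
    p = np.zeros((ns, na, ns))
    r = np.zeros((ns, na))
    for s in range(ns - 1):
        p[s, 0, s + 1] = 1.0
        r[s, 0] = 1.0 if s + 1 == ns - 1 else 0.2
        p[s, 1, s] = 1.0
        r[s, 1] = 0.1
    p[ns - 1, :, ns - 1] = 1.0  # absorbing, zero reward
    return MDPSpec(
        states=("s0", "s1", "s2", "s3"),
        actions=("advance", "stay"),
        transitions=p,
        rewards=r,
        gamma=0.9,
        terminal_states=frozenset({"s3"}),
        initial_distribution=np.array([1.0, 0.0, 0.0, 0.0]),
    )


def toy_oncology_mdp(seed: int = 0) -> MDPSpec:
    """Six-state toy disease-course MDP with three treatment intensities.

    States: remission, stable, progression-1, progression-2, toxicity, and an
    absorbing terminal state.  Actions: standard dose, intensified dose,
    supportive care.  Rewards are positive for response and negative for
    toxicity-related hospitalization.  The tables are fixed; ``seed`` is
    accepted for interface symmetry with the cohort generator and unused.
    """
    del seed
    states = ("remission", "stable", "progression1", "progression2",
              "toxicity", "terminal")
    actions = ("standard", "intensified", "supportive")
    ns, na = len(states), len(actions)
    p = np.zeros((ns, na, ns))
    r = np.zeros((ns, na))
    # remission
    p[0, 0, [0, 1]] = (0.90, 0.10); r[0, 0] = 1.0
    p[0, 1, [0, 4]] = (0.85, 0.15); r[0, 1] = 0.5
    p[0, 2, [0, 1]] = (0.70, 0.30); r[0, 2] = 0.8
    # stable
    p[1, 0, [0, 1, 2]] = (0.50, 0.40, 0.10); r[1, 0] = 0.5
    p[1, 1, [0, 1, 4]] = (0.60, 0.20, 0.20); r[1, 1] = 0.3
    p[1, 2, [1, 2]] = (0.60, 0.40); r[1, 2] = 0.0
    # progression-1
    p[2, 0, [1, 2, 3]] = (0.40, 0.40, 0.20); r[2, 0] = 0.0
    p[2, 1, [1, 2, 3, 4]] = (0.55, 0.20, 0.10, 0.15); r[2, 1] = 0.2
    p[2, 2, [2, 3]] = (0.50, 0.50); r[2, 2] = -0.2
    # progression-2
    p[3, 0, [2, 3, 5]] = (0.30, 0.50, 0.20); r[3, 0] = -0.5
    p[3, 1, [2, 3, 4, 5]] = (0.45, 0.30, 0.15, 0.10); r[3, 1] = -0.3
    p[3, 2, [3, 5]] = (0.60, 0.40); r[3, 2] = -0.8
    # toxicity: hospitalization penalty
    p[4, 0, [1, 4, 5]] = (0.50, 0.30, 0.20); r[4, 0] = -1.0
    p[4, 1, [4, 5]] = (0.60, 0.40); r[4, 1] = -1.5
    p[4, 2, [1, 4]] = (0.70, 0.30); r[4, 2] = -0.5
    # terminal: absorbing self-loop, zero reward
    p[5, :, 5] = 1.0
    return MDPSpec(
        states=states,
        actions=actions,
        transitions=p,
        rewards=r,
        gamma=0.9,
        terminal_states=frozenset({"terminal"}),
        initial_distribution=np.array([0.10, 0.30, 0.30, 0.20, 0.10, 0.0]),
    )
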