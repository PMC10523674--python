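"""Deep Q-Network agent for stimulation-parameter search.

The critic is a small fully-connected network (default 3-40-30-9: the three
state components in, one Q-value per action out, hidden layers of 40 and 30
ReLU units) trained by one-step temporal-difference learning:

* epsilon-greedy exploration with multiplicative epsilon decay per
  learning step;
* a circular (FIFO) experience-replay buffer sampled in mini-batches;
* mean-squared TD error on the sampled (state, action) outputs plus an L2
  penalty on the weights, minimised with Adam;
* a target network tracking the online network by soft updates
  ``theta_target <- tau * theta + (1 - tau) * theta_target``.

``train_dqn`` works against any object with the small episode-environment
interface (`reset`/`step`/`n_actions`/`state_dim`), which is also how the
tabular sanity checks drive it.  ``CalibrationEnv`` adapts the simulated
subject (the three fitted answer models) to that interface; one training
episode is a simulated characterization of one randomly drawn subject, and
ends either in failure (a too-strong sensation) or after the step cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ParamGrid, StimParams, state_features
from .environment import EnvModels, grid_state_table
from .mdp import (
    RewardTable,
    apply_action,
    default_reward_table,
    enumerate_actions,
    reward as state_reward,
)

__all__ = [
    "Hyperparams",
    "QNetwork",
    "ReplayBuffer",
    "DQNAgent",
    "select_action",
    "td_target",
    "update_critic",
    "soft_update",
    "train_dqn",
    "CalibrationEnv",
    "train_agent",
    "test_agent",
    "TestResult",
]


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters (defaults as used for both agents)."""

    learn_rate: float = 1e-4
    l2_factor: float = 1e-4
    target_smooth: float = 1e-3  # tau
    gamma: float = 0.99
    batch_size: int = 64
    epsilon0: float = 1.0
    epsilon_decay: float = 0.005
    epsilon_min: float = 0.25
    max_steps_per_episode: int = 60
    max_episodes: int = 2000
    avg_reward_stop: float | None = None  # stop when mean episode reward >= this
    avg_window: int = 50
    buffer_capacity: int = 5000


class QNetwork:
    """Fully connected ReLU network mapping a state vector to Q-values."""

    def __init__(self, layer_sizes=(3, 40, 30, 9), seed: int = 0):
        self.layer_sizes = tuple(layer_sizes)
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in zip(layer_sizes, layer_sizes[1:]):
            # He-normal initialisation for ReLU layers
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)))
            self.biases.append(np.zeros(n_out))

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Q-values for a batch of states, optionally with the activations
        needed for backpropagation."""
        x = np.atleast_2d(x)
        cache = [x]
        h = x
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = h @ W + b
            h = a if i == len(self.weights) - 1 else np.maximum(a, 0.0)
            if keep_cache:
                cache.append(h)
        return (h, cache) if keep_cache else h

    def copy(self) -> "QNetwork":
        other = QNetwork.__new__(QNetwork)
        other.layer_sizes = self.layer_sizes
        other.weights = [W.copy() for W in self.weights]
        other.biases = [b.copy() for b in self.biases]
        return other


class _Adam:
    def __init__(self, net: QNetwork, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.weights + net.biases]
        self.v = [np.zeros_like(p) for p in net.weights + net.biases]

    def step(self, net: QNetwork, grads: list[np.ndarray]) -> None:
        self.t += 1
        params = net.weights + net.biases
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReplayBuffer:
    """Fixed-capacity circular store of transitions (FIFO overwrite)."""

    def __init__(self, capacity: int, state_dim: int):
        self.capacity = capacity
        self.states = np.zeros((capacity, state_dim))
        self.actions = np.zeros(capacity, dtype=int)
        self.rewards = np.zeros(capacity)
        self.next_states = np.zeros((capacity, state_dim))
        self.terminals = np.zeros(capacity, dtype=bool)
        self.cursor = 0
        self.size = 0

    def push(self, s, a, r, s_next, terminal) -> None:
        i = self.cursor
        self.states[i] = s
        self.actions[i] = a
        self.rewards[i] = r
        self.next_states[i] = s_next
        self.terminals[i] = terminal
        self.cursor = (self.cursor + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator) -> dict:
        idx = rng.integers(0, self.size, size=batch_size)
        return {
            "states": self.states[idx],
            "actions": self.actions[idx],
            "rewards": self.rewards[idx],
            "next_states": self.next_states[idx],
            "terminals": self.terminals[idx],
        }

    def __len__(self) -> int:
        return self.size


def select_action(
    net: QNetwork, state: np.ndarray, epsilon: float, rng: np.random.Generator
) -> int:
    """Epsilon-greedy action index; greedy ties break to the lowest index."""
    n_actions = net.layer_sizes[-1]
    if rng.random() < epsilon:
        return int(rng.integers(0, n_actions))
    q = net.forward(state)[0]
    return int(np.argmax(q))  # argmax returns the first (lowest) maximiser


def td_target(
    reward: float,
    next_state: np.ndarray,
    terminal: bool,
    target_net: QNetwork,
    gamma: float,
) -> float:
    """One-step bootstrap target r + gamma * max_a' Q_target(s', a')."""
    if terminal:
        return float(reward)
    return float(reward + gamma * np.max(target_net.forward(next_state)[0]))


def _batch_targets(batch: dict, target_net: QNetwork, gamma: float) -> np.ndarray:
    q_next = target_net.forward(batch["next_states"]).max(axis=1)
    return batch["rewards"] + gamma * q_next * (~batch["terminals"])


def update_critic(
    net: QNetwork,
    batch: dict,
    hp: Hyperparams,
    target_net: QNetwork,
    adam: _Adam,
) -> float:
    """One Adam step on mean squared TD error + L2 weight penalty.

    Only the sampled (state, action) outputs receive error signal.  Returns
    the TD loss before the step.
    """
    y = _batch_targets(batch, target_net, hp.gamma)
    q, cache = net.forward(batch["states"], keep_cache=True)
    B = len(y)
    rows = np.arange(B)
    delta = q[rows, batch["actions"]] - y
    loss = float(np.mean(delta**2))
    dq = np.zeros_like(q)
    dq[rows, batch["actions"]] = 2.0 * delta / B
    # backpropagate through the ReLU stack
    grads_W: list[np.ndarray] = [None] * len(net.weights)
    grads_b: list[np.ndarray] = [None] * len(net.biases)
    d = dq
    for i in range(len(net.weights) - 1, -1, -1):
        h_in = cache[i]
        grads_W[i] = h_in.T @ d + hp.l2_factor * net.weights[i]
        grads_b[i] = d.sum(axis=0)
        if i > 0:
            d = (d @ net.weights[i].T) * (cache[i] > 0)
    adam.step(net, grads_W + grads_b)
    return loss


def soft_update(target_net: QNetwork, net: QNetwork, tau: float) -> None:
    """theta_target <- tau * theta + (1 - tau) * theta_target, in place."""
    if target_net.layer_sizes != net.layer_sizes:
        raise ValueError("network shapes do not match")
    for pt, p in zip(
        target_net.weights + target_net.biases, net.weights + net.biases
    ):
        pt *= 1.0 - tau
        pt += tau * p


@dataclass
class DQNAgent:
    """A trained critic plus everything needed to act greedily."""

    net: QNetwork
    target_net: QNetwork
    hp: Hyperparams
    level: str | None = None
    epsilon: float = 0.0

    def greedy(self, state: np.ndarray) -> int:
        return int(np.argmax(self.net.forward(state)[0]))


def train_dqn(env, hp: Hyperparams, seed: int = 0, layer_sizes=None):
    """Generic DQN training loop over an episode environment.

    ``env`` must provide ``state_dim``, ``n_actions``,
    ``reset(rng) -> state_vec`` and ``step(a) -> (state_vec, reward,
    terminal)``.  Returns the agent and a per-episode log (steps, total
    reward, epsilon).
    """
    ss = np.random.SeedSequence([seed, 404])
    rng_net, rng_act, rng_buf, rng_env = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    layer_sizes = layer_sizes or (env.state_dim, 40, 30, env.n_actions)
    net = QNetwork(layer_sizes, seed=int(rng_net.integers(2**31 - 1)))
    target_net = net.copy()
    adam = _Adam(net, hp.learn_rate)
    buffer = ReplayBuffer(hp.buffer_capacity, env.state_dim)
    epsilon = hp.epsilon0
    log = []
    recent: list[float] = []
    for episode in range(hp.max_episodes):
        s = env.reset(rng_env)
        total = 0.0
        steps = 0
        for _ in range(hp.max_steps_per_episode):
            a = select_action(net, s, epsilon, rng_act)
            s_next, r, terminal = env.step(a)
            buffer.push(s, a, r, s_next, terminal)
            total += r
            steps += 1
            if len(buffer) >= hp.batch_size:
                batch = buffer.sample(hp.batch_size, rng_buf)
                update_critic(net, batch, hp, target_net, adam)
                soft_update(target_net, net, hp.target_smooth)
                epsilon = max(hp.epsilon_min, epsilon * (1.0 - hp.epsilon_decay))
            s = s_next
            if terminal:
                break
        log.append(
            {"episode": episode, "steps": steps, "reward": total, "epsilon": epsilon}
        )
        recent.append(total)
        if hp.avg_reward_stop is not None and len(recent) >= hp.avg_window:
            if float(np.mean(recent[-hp.avg_window :])) >= hp.avg_reward_stop:
                break
    agent = DQNAgent(net=net, target_net=target_net, hp=hp, epsilon=epsilon)
    return agent, pd.DataFrame(log)


def _state_intensity_code(state_id: int) -> int:
    """0 = not perceived, 1 = low, 2 = high, 3 = too high."""
    return (state_id + 3) // 4


class CalibrationEnv:
    """Episode environment backed by the fitted simulated subject.

    Every episode simulates a characterization of one cohort member: the
    initial stimulus comes from ``init_fn(subject)``, each action shifts
    (PA, PW) on the grid, and the answer is looked up in a per-subject table
    of the three models' predictions over the whole grid (computed once per
    subject).  An episode fails (terminal) when the simulated answer is a
    too-strong sensation.

    ``explore_start_prob`` is the fraction of episodes initialised at a
    uniformly random grid point instead of the dataset rule (exploring
    starts).  Without it, whole regions of the state space -- notably the
    too-strong states, which terminate episodes -- are never departed from
    during training, leaving the policy unable to back out of an overshoot
    when facing a real subject.  Testing always uses the dataset rule.
    """

    state_dim = 3
    n_actions = 9

    def __init__(
        self,
        models: EnvModels,
        cohort: list,
        level: str,
        init_fn,
        grid: ParamGrid | None = None,
        reward_table: RewardTable | None = None,
        explore_start_prob: float = 0.0,
    ):
        self.models = models
        self.cohort = cohort
        self.level = level
        self.init_fn = init_fn
        self.explore_start_prob = explore_start_prob
        self.grid = grid or ParamGrid()
        self.table = reward_table or default_reward_table(level)
        self.actions = enumerate_actions()
        self._cache: dict = {}
        self._pa_index = {v: i for i, v in enumerate(self.grid.pa_values)}
        self._pw_index = {v: i for i, v in enumerate(self.grid.pw_values)}
        self.subject = None
        self.params: StimParams | None = None
        self.state_id: int | None = None

    def _table_for(self, subject) -> np.ndarray:
        key = subject.subject_id
        if key not in self._cache:
            self._cache[key] = grid_state_table(
                self.models, subject.gender, subject.weight, subject.nerve, self.grid
            )
        return self._cache[key]

    def _lookup(self, p: StimParams) -> int:
        t = self._table_for(self.subject)
        return int(t[self._pa_index[p.pa], self._pw_index[p.pw]])

    def reset(self, rng: np.random.Generator, subject=None) -> np.ndarray:
        self.subject = subject if subject is not None else self.cohort[
            int(rng.integers(0, len(self.cohort)))
        ]
        if self.explore_start_prob > 0 and rng.random() < self.explore_start_prob:
            self.params = StimParams(
                pa=self.grid.pa_values[int(rng.integers(len(self.grid.pa_values)))],
                pw=self.grid.pw_values[int(rng.integers(len(self.grid.pw_values)))],
            )
        else:
            self.params = self.init_fn(self.subject)
        self.state_id = self._lookup(self.params)
        return state_features(self.state_id)

    def step(self, action_index: int):
        self.params = apply_action(self.params, self.actions[action_index], self.grid)
        self.state_id = self._lookup(self.params)
        r = state_reward(self.state_id, self.table)
        terminal = _state_intensity_code(self.state_id) == 3
        return state_features(self.state_id), r, terminal


def train_agent(
    models: EnvModels,
    cohort: list,
    level: str,
    init_fn,
    hp: Hyperparams = Hyperparams(),
    seed: int = 0,
    grid: ParamGrid | None = None,
    reward_table: RewardTable | None = None,
    explore_start_prob: float = 0.3,
):
    """Train one agent (low or high level) against the simulated subject."""
    env = CalibrationEnv(
        models, cohort, level, init_fn, grid, reward_table,
        explore_start_prob=explore_start_prob,
    )
    agent, log = train_dqn(env, hp, seed=seed)
    agent.level = level
    return agent, log


@dataclass
class TestResult:
    accuracy: float  # fraction of episodes ending at the target intensity
    steps: list  # stimuli delivered per episode
    final_params: dict  # subject_id -> StimParams
    final_states: dict  # subject_id -> state id
    converged: dict  # subject_id -> bool


def test_agent(
    agent: DQNAgent,
    models: EnvModels,
    cohort: list,
    level: str,
    init_fn,
    convergence_window: int = 5,
    step_cap: int = 100,
    grid: ParamGrid | None = None,
) -> TestResult:
    """Greedy evaluation over every simulated subject.

    An episode converges when the chosen (PA, PW) pair is identical for
    ``convergence_window`` consecutive iterations (the agent considers that
    state the best achievable), or stops at ``step_cap``.  It counts as
    correct when the final state's perceived intensity equals the target
    level.
    """
    env = CalibrationEnv(models, cohort, level, init_fn, grid)
    target_code = {"low": 1, "high": 2}[level]
    rng = np.random.default_rng(0)  # unused: policy is greedy
    steps_all: list[int] = []
    final_params: dict = {}
    final_states: dict = {}
    converged: dict = {}
    n_correct = 0
    for subject in cohort:
        s = env.reset(rng, subject=subject)
        history = [env.params]
        while len(history) < step_cap:
            a = agent.greedy(s)
            s, _, _ = env.step(a)
            history.append(env.params)
            if len(history) >= convergence_window and all(
                p == history[-1] for p in history[-convergence_window:]
            ):
                break
        ok_converged = len(history) < step_cap or all(
            p == history[-1] for p in history[-convergence_window:]
        )
        steps_all.append(len(history))
        final_params[subject.subject_id] = env.params
        final_states[subject.subject_id] = env.state_id
        converged[subject.subject_id] = bool(ok_converged)
        if _state_intensity_code(env.state_id) == target_code:
            n_correct += 1
    return TestResult(
        accuracy=n_correct / len(cohort) if cohort else float("nan"),
        steps=steps_all,
        final_params=final_params,
        final_states=final_states,
        converged=converged,
    )
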