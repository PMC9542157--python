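"""Policy-gradient agents: PPO and A2C over the graph policy-value network,
plus a seeded uniform-random baseline.

Both algorithms follow the standard actor-critic recipe: roll the current
policy out in the environment, estimate advantages with GAE(γ, λ), then take
gradient steps on

* PPO:  L = -E[min(ρ A, clip(ρ, 1-ε, 1+ε) A)] + c_v·MSE(V, returns) - c_e·H(π)
  with probability ratio ρ = exp(log π_new - log π_old), several epochs of
  minibatched updates per rollout;
* A2C:  L = -E[log π(a|s) · A] + c_v·MSE(V, returns) - c_e·H(π), one full-batch
  step per rollout.

Actions factorize across torsions (one categorical head per rotatable
torsion); joint log-probabilities and entropies are sums over the heads.
"""

from __future__ import annotations

import dataclasses
import pickle
import time
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from . import autodiff
from .autodiff import Adam, Tensor
from .env import ConformerEnv
from .nn import BatchedGraphs, PolicyValueNet
from .observations import GraphObservation

__all__ = [
    "AgentConfig",
    "TrajectoryBatch",
    "compute_gae",
    "PPOAgent",
    "A2CAgent",
    "RandomAgent",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass
class AgentConfig:
    algorithm: str = "ppo"
    gamma: float = 0.99
    gae_lambda: float = 0.95
    ppo_clip: float = 0.2
    entropy_coef: float = 0.01
    value_coef: float = 0.5
    learning_rate: float = 3e-4
    rollout_steps: Optional[int] = None  # default: 20 episodes worth of steps
    epochs: int = 4
    minibatch_size: int = 64
    hidden: int = 64
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 <= self.gae_lambda <= 1.0:
            raise ValueError("gae_lambda must be in [0, 1]")
        if self.ppo_clip <= 0:
            raise ValueError("ppo_clip must be > 0")
        if self.algorithm not in ("ppo", "a2c"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclasses.dataclass
class TrajectoryBatch:
    """One rollout: aligned per-step records plus GAE post-processing."""

    observations: list[GraphObservation] = dataclasses.field(default_factory=list)
    actions: list[np.ndarray] = dataclasses.field(default_factory=list)
    log_probs: list[float] = dataclasses.field(default_factory=list)
    rewards: list[float] = dataclasses.field(default_factory=list)
    values: list[float] = dataclasses.field(default_factory=list)
    dones: list[bool] = dataclasses.field(default_factory=list)
    advantages: Optional[np.ndarray] = None
    returns: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.rewards)

    def finalize(self, gamma: float, lam: float, last_value: float = 0.0) -> None:
        adv, ret = compute_gae(
            np.asarray(self.rewards),
            np.asarray(self.values),
            np.asarray(self.dones, dtype=bool),
            gamma,
            lam,
            last_value,
        )
        if not np.all(np.isfinite(adv)):
            raise FloatingPointError("non-finite advantages in rollout")
        self.advantages, self.returns = adv, ret


def compute_gae(
    rewards: np.ndarray,
    values: np.ndarray,
    dones: np.ndarray,
    gamma: float,
    lam: float,
    last_value: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized advantage estimation.

    δ_t = r_t + γ·V_{t+1}·(1-done_t) - V_t
    A_t = δ_t + γλ·(1-done_t)·A_{t+1};   returns = A + V.
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    dones = np.asarray(dones, dtype=bool)
    if not (len(rewards) == len(values) == len(dones)):
        raise ValueError("rewards, values and dones must have equal length")
    T = len(rewards)
    adv = np.zeros(T)
    next_value, next_adv = float(last_value), 0.0
    for t in range(T - 1, -1, -1):
        not_done = 0.0 if dones[t] else 1.0
        delta = rewards[t] + gamma * next_value * not_done - values[t]
        next_adv = delta + gamma * lam * not_done * next_adv
        adv[t] = next_adv
        next_value = values[t]
    return adv, adv + values


# ---------------------------------------------------------------------------
# loss pieces shared by both algorithms
# ---------------------------------------------------------------------------

def _log_prob_entropy(out, actions: np.ndarray):
    """Joint log-prob per sample and summed entropy for a batched forward pass.

    ``actions`` is flat over torsion rows (aligned with ``out.logits``);
    per-sample log-probs are summed over each sample's torsion heads.
    """
    logp_all = out.logits.log_softmax(axis=1)
    rows = np.arange(len(actions))
    chosen = logp_all[rows, actions]
    n_graphs = out.value.shape[0]
    logp = autodiff.segment_sum(
        chosen.reshape(-1, 1), out.torsion_graph_ids, n_graphs
    ).reshape(-1)
    entropy = -(logp_all.exp() * logp_all).sum(axis=1).sum()
    return logp, entropy


def _flatten_actions(batch: TrajectoryBatch, idx: np.ndarray) -> np.ndarray:
    return np.concatenate([batch.actions[i] for i in idx]).astype(np.int64)


def ppo_update(
    batch: TrajectoryBatch, net: PolicyValueNet, optimizer: Adam, cfg: AgentConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Clipped-surrogate PPO update over several epochs of minibatches."""
    assert batch.advantages is not None, "finalize() the batch first"
    T = len(batch)
    old_logp = np.asarray(batch.log_probs)
    adv = batch.advantages
    adv_norm = (adv - adv.mean()) / (adv.std() + 1e-8)
    stats = {"policy_loss": 0.0, "value_loss": 0.0, "entropy": 0.0}
    n_updates = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(T)
        for start in range(0, T, cfg.minibatch_size):
            idx = order[start : start + cfg.minibatch_size]
            out = net.forward(
                BatchedGraphs.from_observations([batch.observations[i] for i in idx])
            )
            logp, entropy = _log_prob_entropy(out, _flatten_actions(batch, idx))
            ratio = (logp - Tensor(old_logp[idx])).exp()
            adv_t = Tensor(adv_norm[idx])
            surrogate = autodiff.minimum(
                ratio * adv_t,
                autodiff.clip(ratio, 1.0 - cfg.ppo_clip, 1.0 + cfg.ppo_clip) * adv_t,
            )
            policy_loss = -surrogate.mean()
            value_loss = ((out.value - Tensor(batch.returns[idx])) ** 2).mean()
            ent_mean = entropy / float(len(idx))
            loss = policy_loss + cfg.value_coef * value_loss - cfg.entropy_coef * ent_mean
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite PPO loss; aborting update")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            stats["policy_loss"] += float(policy_loss.data)
            stats["value_loss"] += float(value_loss.data)
            stats["entropy"] += float(ent_mean.data)
            n_updates += 1
    return {k: v / max(n_updates, 1) for k, v in stats.items()}


def a2c_update(
    batch: TrajectoryBatch, net: PolicyValueNet, optimizer: Adam, cfg: AgentConfig,
) -> dict[str, float]:
    """Single full-batch advantage-actor-critic update (no clipping)."""
    assert batch.advantages is not None, "finalize() the batch first"
    T = len(batch)
    idx = np.arange(T)
    adv = batch.advantages
    adv_norm = (adv - adv.mean()) / (adv.std() + 1e-8)
    out = net.forward(BatchedGraphs.from_observations(batch.observations))
    logp, entropy = _log_prob_entropy(out, _flatten_actions(batch, idx))
    policy_loss = -(logp * Tensor(adv_norm)).mean()
    value_loss = ((out.value - Tensor(batch.returns)) ** 2).mean()
    ent_mean = entropy / float(T)
    loss = policy_loss + cfg.value_coef * value_loss - cfg.entropy_coef * ent_mean
    if not np.isfinite(loss.data):
        raise FloatingPointError("non-finite A2C loss; aborting update")
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return {
        "policy_loss": float(policy_loss.data),
        "value_loss": float(value_loss.data),
        "entropy": float(ent_mean.data),
    }


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------

class _PolicyAgent:
    """Shared machinery: act / evaluate / collect / update."""

    algorithm = "ppo"

    def __init__(self, node_dim: int, edge_dim: int, n_buckets: int, cfg: AgentConfig):
        self.cfg = cfg
        self.net = PolicyValueNet(
            node_dim, edge_dim, n_buckets, hidden=cfg.hidden, seed=cfg.seed
        )
        self.optimizer = Adam(self.net.parameters(), lr=cfg.learning_rate)
        self.rng = np.random.default_rng(cfg.seed)

    @classmethod
    def for_env(cls, env: ConformerEnv, cfg: AgentConfig) -> "_PolicyAgent":
        node_dim = len(env.config.observation.alphabet) + 3
        return cls(node_dim, 6, env.config.n_buckets, cfg)

    def act(
        self, obs: GraphObservation, greedy: bool = False
    ) -> tuple[np.ndarray, float, float]:
        """Sample (or argmax) an action; returns (buckets, joint log-prob, value)."""
        out = self.net.forward_single(obs)
        logits = out.logits.data
        if logits.shape[0] == 0:
            return np.zeros(0, dtype=np.int64), 0.0, float(out.value.data[0])
        logp_all = logits - np.log(np.exp(logits - logits.max(1, keepdims=True)).sum(1, keepdims=True)) - logits.max(1, keepdims=True)
        probs = np.exp(logp_all)
        if greedy:
            action = probs.argmax(axis=1)
        else:
            action = np.array(
                [self.rng.choice(len(p), p=p / p.sum()) for p in probs], dtype=np.int64
            )
        logp = float(logp_all[np.arange(len(action)), action].sum())
        return action, logp, float(out.value.data[0])

    def collect_rollout(self, env: ConformerEnv, n_steps: int) -> tuple[TrajectoryBatch, list[float]]:
        """Run the current policy for ``n_steps`` env steps (episodes auto-reset).

        Returns the finalized batch and the total rewards of episodes that
        *completed* during the rollout.
        """
        batch = TrajectoryBatch()
        episode_totals: list[float] = []
        obs = env.reset()
        for _ in range(n_steps):
            action, logp, value = self.act(obs)
            res = env.step(action)
            batch.observations.append(obs)
            batch.actions.append(action)
            batch.log_probs.append(logp)
            batch.rewards.append(res.reward)
            batch.values.append(value)
            batch.dones.append(res.done)
            if res.done:
                episode_totals.append(env.episode_record.total_reward)
                obs = env.reset()
            else:
                obs = res.observation
        # bootstrap only when the rollout truncates an episode mid-flight
        last_value = 0.0 if batch.dones[-1] else self.value_of(obs)
        batch.finalize(self.cfg.gamma, self.cfg.gae_lambda, last_value)
        return batch, episode_totals

    def value_of(self, obs: GraphObservation) -> float:
        """State-value estimate without sampling (leaves the RNG untouched)."""
        return float(self.net.forward_single(obs).value.data[0])

    def update(self, batch: TrajectoryBatch) -> dict[str, float]:
        raise NotImplementedError

    def policy(self, greedy: bool = True) -> Callable[[GraphObservation], np.ndarray]:
        def _policy(obs: GraphObservation) -> np.ndarray:
            return self.act(obs, greedy=greedy)[0]
        return _policy


class PPOAgent(_PolicyAgent):
    algorithm = "ppo"

    def update(self, batch: TrajectoryBatch) -> dict[str, float]:
        return ppo_update(batch, self.net, self.optimizer, self.cfg, self.rng)


class A2CAgent(_PolicyAgent):
    algorithm = "a2c"

    def update(self, batch: TrajectoryBatch) -> dict[str, float]:
        return a2c_update(batch, self.net, self.optimizer, self.cfg)


class RandomAgent:
    """Uniform over the B^n discrete action space, seeded."""

    def __init__(self, n_buckets: int, seed: int = 0):
        self.n_buckets = n_buckets
        self.rng = np.random.default_rng(seed)

    def act(self, obs: GraphObservation) -> np.ndarray:
        return self.rng.integers(0, self.n_buckets, obs.n_torsions)

    def policy(self) -> Callable[[GraphObservation], np.ndarray]:
        return self.act


# ---------------------------------------------------------------------------
# training driver, checkpoints
# ---------------------------------------------------------------------------

def evaluate(agent: _PolicyAgent, env: ConformerEnv, n_episodes: int = 3,
             greedy: bool = True) -> float:
    """Mean total episode reward of the (default greedy) policy on ``env``."""
    totals = []
    for _ in range(n_episodes):
        obs = env.reset()
        done = False
        while not done:
            action, _, _ = agent.act(obs, greedy=greedy)
            res = env.step(action)
            obs, done = res.observation, res.done
        totals.append(env.episode_record.total_reward)
    return float(np.mean(totals))


def save_checkpoint(path, agent: _PolicyAgent, iteration: int, env_steps: int) -> None:
    """Serialize parameters, optimizer state, config and RNG states."""
    state = {
        "algorithm": agent.algorithm,
        "net": agent.net.state_dict(),
        "net_dims": (agent.net.node_dim, agent.net.edge_dim, agent.net.n_buckets),
        "optimizer": agent.optimizer.state_dict(),
        "config": dataclasses.asdict(agent.cfg),
        "rng_state": agent.rng.bit_generator.state,
        "iteration": iteration,
        "env_steps": env_steps,
    }
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def load_checkpoint(path) -> tuple[_PolicyAgent, int, int]:
    """Rebuild an agent (and its RNG / optimizer state) from a checkpoint."""
    with open(path, "rb") as fh:
        state = pickle.load(fh)
    cfg = AgentConfig(**state["config"])
    cls = PPOAgent if state["algorithm"] == "ppo" else A2CAgent
    agent = cls(*state["net_dims"], cfg)
    agent.net.load_state_dict(state["net"])
    agent.optimizer.load_state_dict(state["optimizer"])
    agent.rng.bit_generator.state = state["rng_state"]
    return agent, state["iteration"], state["env_steps"]


def train(
    agent: _PolicyAgent,
    env: ConformerEnv,
    total_steps: int,
    eval_env: Optional[ConformerEnv] = None,
    eval_interval: int = 5,
    logger=None,
    checkpoint_dir: Optional[str] = None,
    checkpoint_interval: int = 10,
    curriculum=None,
    stop_condition: Optional[Callable[[dict], bool]] = None,
) -> list[dict]:
    """Iterate rollout -> GAE -> update until ``total_steps`` env steps.

    Per iteration one metric row is produced (and sent to ``logger`` if given):
    iteration, env_steps, mean_episode_reward, losses, entropy, and
    eval_reward every ``eval_interval`` iterations when ``eval_env`` is given.
    ``curriculum`` (a :class:`torsionrl.curriculum.Curriculum`) is fed every
    finished episode's total and switches the env's active molecule.
    ``stop_condition`` may end training early based on the metric row.
    """
    if agent.net.n_buckets != env.config.n_buckets:
        raise ValueError(
            f"agent has {agent.net.n_buckets} action buckets but env expects "
            f"{env.config.n_buckets}"
        )
    rollout = agent.cfg.rollout_steps or 20 * env.config.max_steps
    history: list[dict] = []
    env_steps = 0
    iteration = 0
    t0 = time.time()
    while env_steps < total_steps:
        iteration += 1
        batch, episode_totals = agent.collect_rollout(env, rollout)
        env_steps += len(batch)
        losses = agent.update(batch)
        if curriculum is not None:
            for total in episode_totals:
                curriculum.record_episode(total)
            env.set_molecule_index(curriculum.molecule_index)
        row = {
            "iteration": iteration,
            "env_steps": env_steps,
            "mean_episode_reward": float(np.mean(episode_totals)) if episode_totals else float("nan"),
            **losses,
            "wall_time": time.time() - t0,
        }
        if eval_env is not None and iteration % eval_interval == 0:
            row["eval_reward"] = evaluate(agent, eval_env)
        if logger is not None:
            logger.log(row)
        if checkpoint_dir is not None and iteration % checkpoint_interval == 0:
            save_checkpoint(
                Path(checkpoint_dir) / f"checkpoint_{iteration:05d}.pkl",
                agent, iteration, env_steps,
            )
        history.append(row)
        if stop_condition is not None and stop_condition(row):
            break
    if checkpoint_dir is not None:
        save_checkpoint(Path(checkpoint_dir) / "checkpoint_final.pkl", agent, iteration, env_steps)
    return history
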