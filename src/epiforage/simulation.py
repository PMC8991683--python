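"""Episode loop, Monte-Carlo returns, and the multi-episode protocol.

An episode starts at a uniformly random non-reward state.  At each step the
agent receives the reward of its current state; the episode ends when that
state is the reward or after 250 receipts.  Otherwise the agent queries its
memory bank for the nearest stored key, softmaxes the recalled return slots
into a policy, samples an action, and moves.  On the first episode the bank
is empty and the agent random-walks.

Storage is strictly end-of-episode: discounted returns G_t are computed by
backward recursion over the episode's rewards, then every (state, action,
G_t) tuple is written to the bank in time order, so a revisited
state-action slot ends up holding the most recent return.  The terminal
state, where no action is taken, is not written.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import memory as mem
from .gridworld import (
    GridWorld,
    MAX_STEPS,
    N_ACTIONS,
    build_environment,
)
from .representations import StateEncoding, make_encoding


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one simulation run from its seed."""

    layout: str = "open_field"
    reward_state: Optional[tuple[int, int]] = None
    encoding: str = "successor"
    sigma: float = 0.05            # place-field width, grid-normalized
    gamma: float = 0.98            # discount, shared by returns and the SR
    capacity_fraction: float = 1.0
    forgetting_rule: str = "oldest"
    forget_on: str = "update"
    tie_break: str = "first"
    n_episodes: int = 5000
    max_steps: int = MAX_STEPS
    seed: int = 0
    # Snapshot cadence: every episode inside the final dense window (the
    # policy-map analyses average over it), sparsely before that.
    snapshot_dense_window: int = 400
    snapshot_sparse_every: int = 50

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")
        if not 0.0 < self.capacity_fraction <= 1.0:
            raise ValueError("capacity_fraction must lie in (0, 1]")
        if self.reward_state is not None:
            self.reward_state = tuple(self.reward_state)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a YAML or JSON mapping of config fields."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_config_encoding(env: GridWorld, config: SimulationConfig) -> StateEncoding:
    return make_encoding(
        env,
        config.encoding,
        sigma=config.sigma,
        gamma=config.gamma,
        seed=config.seed,
    )


# --------------------------------------------------------------------------
# Returns
# --------------------------------------------------------------------------


def compute_returns(rewards: np.ndarray, gamma: float) -> np.ndarray:
    """Discounted returns G_t = Σ_k γ^k r_{t+k} by backward recursion."""
    r = np.asarray(rewards, dtype=float)
    if r.size == 0:
        raise ValueError("empty reward sequence")
    if not np.all(np.isfinite(r)):
        raise ValueError("rewards must be finite")
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    G = np.empty_like(r)
    acc = 0.0
    for t in range(r.size - 1, -1, -1):
        acc = r[t] + gamma * acc
        G[t] = acc
    return G


# --------------------------------------------------------------------------
# Episodes
# --------------------------------------------------------------------------


@dataclass
class EpisodeLog:
    """Per-timestep record of one episode.

    ``states`` has one more element than ``actions``: the terminal state
    (reward reached or the 250th receipt) has no action.
    """

    states: list[int]
    actions: list[int]
    rewards: np.ndarray
    raw_score: float
    success: bool
    recall_distances: list[float] = field(default_factory=list)
    recall_exact: list[bool] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.actions)


def run_episode(
    env: GridWorld,
    bank: mem.MemoryBank,
    encoding: StateEncoding,
    rng: np.random.Generator,
    max_steps: int = MAX_STEPS,
) -> EpisodeLog:
    """One foraging episode under the current (frozen) memory bank.

    The bank is only read here; an empty bank yields uniform-random actions
    for the whole episode (the first-episode random walk).
    """
    table = encoding.table
    rewards_of = env.rewards
    nxt = env.next_state
    reward_idx = env.reward_index
    pool = env.nonreward_indices

    s = int(pool[rng.integers(pool.size)])
    states: list[int] = []
    actions: list[int] = []
    rewards: list[float] = []
    recall_d: list[float] = []
    recall_x: list[bool] = []

    use_memory = bank.n > 0
    # The bank is frozen within an episode, so recalls (and the policies
    # they induce) can be cached per state.  Skipped in access-stamping
    # mode, where every recall must touch a timestamp.
    cacheable = use_memory and bank.forget_on == "update" and bank.tie_break == "first"
    cache: dict[int, tuple[np.ndarray, float, bool]] = {}

    receipts = 0
    while True:
        receipts += 1
        states.append(s)
        rewards.append(float(rewards_of[s]))
        if s == reward_idx or receipts >= max_steps:
            break
        if use_memory:
            hit = cache.get(s) if cacheable else None
            if hit is not None:
                policy, d, x = hit
            else:
                i, d, x = mem.recall(bank, table[s], rng=rng)
                policy = mem.policy_from_values(bank._values[i])
                if cacheable:
                    cache[s] = (policy, d, x)
            recall_d.append(float(d))
            recall_x.append(bool(x))
            c = np.cumsum(policy)
            a = int(np.searchsorted(c, rng.random() * c[-1], side="right"))
            a = min(a, N_ACTIONS - 1)
        else:
            a = int(rng.integers(N_ACTIONS))
        actions.append(a)
        s = int(nxt[s, a])

    rewards_arr = np.asarray(rewards)
    return EpisodeLog(
        states=states,
        actions=actions,
        rewards=rewards_arr,
        raw_score=float(rewards_arr.sum()),
        success=bool(states[-1] == reward_idx),
        recall_distances=recall_d,
        recall_exact=recall_x,
    )


def store_episode(
    bank: mem.MemoryBank,
    episode: EpisodeLog,
    gamma: float,
    encoding: StateEncoding,
    rng: Optional[np.random.Generator] = None,
) -> mem.MemoryBank:
    """End-of-episode storage: write (s_t, a_t, G_t) for every step taken.

    Writes are applied in ascending t, so a state-action pair revisited
    within the episode keeps the most recent return.  The terminal state is
    never written (no action was taken there).
    """
    G = compute_returns(episode.rewards, gamma)
    table = encoding.table
    for t, (s, a) in enumerate(zip(episode.states, episode.actions)):
        mem.write_event(bank, table[s], a, float(G[t]), state=s, rng=rng)
    return bank


# --------------------------------------------------------------------------
# Full simulation protocol
# --------------------------------------------------------------------------


@dataclass(eq=False)
class SimulationResult:
    """Per-episode logs plus memory snapshots from one seeded run."""

    config: SimulationConfig
    scores: np.ndarray
    success: np.ndarray
    n_recalls: np.ndarray
    n_exact: np.ndarray
    nonexact_dist_sum: np.ndarray
    n_forgets: np.ndarray
    forget_tally: np.ndarray          # per-state forgetting counts
    snapshots: list[tuple[int, dict]]  # (episode index, bank snapshot)
    env: GridWorld
    encoding: StateEncoding
    bank: mem.MemoryBank


def _snapshot_due(ep: int, config: SimulationConfig) -> bool:
    if ep >= config.n_episodes - config.snapshot_dense_window:
        return True
    return ep % config.snapshot_sparse_every == 0


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Fresh environment, encoding and empty bank; n_episodes of
    run/store cycles.  Fully reproducible from ``config.seed``."""
    env = build_environment(config.layout, config.reward_state)
    encoding = build_config_encoding(env, config)
    capacity = mem.capacity_for(config.capacity_fraction, env.n_states)
    bank = mem.MemoryBank(
        capacity,
        encoding.dim,
        rule=config.forgetting_rule,
        forget_on=config.forget_on,
        tie_break=config.tie_break,
    )
    rng = np.random.default_rng(config.seed)

    n = config.n_episodes
    scores = np.empty(n)
    success = np.zeros(n, dtype=bool)
    n_recalls = np.zeros(n, dtype=np.int64)
    n_exact = np.zeros(n, dtype=np.int64)
    nonexact_dist_sum = np.zeros(n)
    n_forgets = np.zeros(n, dtype=np.int64)
    snapshots: list[tuple[int, dict]] = []

    for ep in range(n):
        log = run_episode(env, bank, encoding, rng, config.max_steps)
        scores[ep] = log.raw_score
        success[ep] = log.success
        if log.recall_distances:
            d = np.asarray(log.recall_distances)
            x = np.asarray(log.recall_exact)
            n_recalls[ep] = d.size
            n_exact[ep] = int(x.sum())
            nonexact_dist_sum[ep] = float(d[~x].sum())
        before = len(bank.forget_log)
        store_episode(bank, log, config.gamma, encoding, rng=rng)
        n_forgets[ep] = len(bank.forget_log) - before
        if _snapshot_due(ep, config):
            snapshots.append((ep, mem.snapshot(bank)))

    tally = np.zeros(env.n_states, dtype=np.int64)
    for s in bank.forget_log:
        tally[int(s)] += 1

    return SimulationResult(
        config=config,
        scores=scores,
        success=success,
        n_recalls=n_recalls,
        n_exact=n_exact,
        nonexact_dist_sum=nonexact_dist_sum,
        n_forgets=n_forgets,
        forget_tally=tally,
        snapshots=snapshots,
        env=env,
        encoding=encoding,
        bank=bank,
    )


def random_walk_baseline(env: GridWorld, n_episodes: int, seed: int) -> np.ndarray:
    """Episode scores of a memoryless uniform-random-walk agent, used as the
    chance-level reference.  Same start, reward-receipt and 250-step rules."""
    rng = np.random.default_rng(seed)
    pool = env.nonreward_indices
    nxt = env.next_state
    rewards_of = env.rewards
    reward_idx = env.reward_index
    scores = np.empty(n_episodes)
    for ep in range(n_episodes):
        s = int(pool[rng.integers(pool.size)])
        total = 0.0
        receipts = 0
        while True:
            receipts += 1
            total += rewards_of[s]
            if s == reward_idx or receipts >= env.max_steps:
                break
            s = int(nxt[s, rng.integers(N_ACTIONS)])
        scores[ep] = total
    return scores


# --------------------------------------------------------------------------
# Tabular export
# --------------------------------------------------------------------------


def episode_records(result: SimulationResult):
    """Per-episode records as a tidy DataFrame."""
    import pandas as pd

    nonexact = result.n_recalls - result.n_exact
    with np.errstate(invalid="ignore"):
        mean_dist = np.where(
            nonexact > 0, result.nonexact_dist_sum / np.maximum(nonexact, 1), np.nan
        )
    return pd.DataFrame(
        {
            "episode": np.arange(result.config.n_episodes),
            "raw_score": result.scores,
            "success": result.success,
            "n_recalls": result.n_recalls,
            "n_exact_matches": result.n_exact,
            "mean_nonexact_recall_distance": mean_dist,
            "n_forgets": result.n_forgets,
        }
    )


def save_result(result: SimulationResult, outdir: str | Path) -> None:
    """Write the CSV episode log, JSON snapshot stream and forgetting tally."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    episode_records(result).to_csv(out / "episodes.csv", index=False)
    mem.save_snapshots(result.snapshots, out / "snapshots.json")
    tally = {
        f"{x},{y}": int(c)
        for (x, y), c in zip(result.env.available_states, result.forget_tally)
    }
    (out / "forget_tally.json").write_text(json.dumps(tally))
    (out / "config.json").write_text(json.dumps(result.config.to_dict()))
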