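"""Derived statistics: performance normalization, policy maps, preferred
directions, policy entropy, recall-match statistics, trajectory sampling,
forgetting incidence, and Welch/Bonferroni testing.

Normalized performance rescales raw episode scores so that the all-fail
score (-2.5) maps to 0% and the optimal average score R* = 10 - 0.01 λ maps
to 100%, making runs comparable across environments.  Policy maps query a
frozen memory bank with every available state's encoding; from them come
preferred-direction fields (the policy-weighted average cardinal
displacement) and per-state Shannon entropy (natural log, so the uniform
policy over four actions scores ln 4 ≈ 1.386 nats).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from . import memory as mem
from .gridworld import ACTION_VECTORS, GridWorld, MAX_STEPS, N_ACTIONS, optimal_average_reward
from .representations import StateEncoding
from .simulation import SimulationResult

#: Cardinal-direction matrix, rows Down, Up, Left, Right.
DIRECTION_MATRIX = ACTION_VECTORS.astype(float)


# --------------------------------------------------------------------------
# Performance
# --------------------------------------------------------------------------

MIN_SCORE = -2.5  # 250 step penalties of -0.01: the all-fail episode score


def normalize_performance(raw_scores: Sequence[float], env: GridWorld) -> float:
    """Mean episode score as a percentage of the optimal average score.

    100 × (mean(raw) + 2.5) / (R* + 2.5); 0% is every episode failing,
    100% is the optimal agent's average.
    """
    scores = np.asarray(raw_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score sequence")
    r_star = optimal_average_reward(env)
    return float(100.0 * (scores.mean() - MIN_SCORE) / (r_star - MIN_SCORE))


# --------------------------------------------------------------------------
# Policies: direction and entropy fields
# --------------------------------------------------------------------------


def preferred_direction(policy: np.ndarray) -> np.ndarray:
    """Policy-weighted average cardinal displacement z_s = π_s · D.

    A uniform policy gives (0, 0); a deterministic one gives the unit
    vector of its action.  ‖z_s‖ ≤ 1 always.
    """
    p = np.asarray(policy, dtype=float)
    return p @ DIRECTION_MATRIX


def policy_entropy(policy: np.ndarray) -> float:
    """Shannon entropy in nats with the 0·log 0 := 0 convention."""
    p = np.asarray(policy, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def policy_map(bank: mem.MemoryBank, env: GridWorld, encoding: StateEncoding) -> np.ndarray:
    """(n_states, 4) array of policies from querying the bank at every
    available state, using the same nearest-key recall as behaviour."""
    if bank.n == 0:
        raise LookupError("cannot build a policy map from an empty bank")
    table = encoding.table
    out = np.empty((env.n_states, N_ACTIONS))
    for s in range(env.n_states):
        i, _, _ = mem.recall(bank, table[s])
        out[s] = mem.policy_from_values(bank.values[i])
    return out


@dataclass
class PolicyFields:
    """Per-state mean preferred direction and mean entropy over a window."""

    directions: np.ndarray  # (n_states, 2)
    entropy: np.ndarray     # (n_states,)


def average_policy_fields(
    snapshots: Sequence[tuple[int, dict]],
    env: GridWorld,
    encoding: StateEncoding,
    window: int,
) -> PolicyFields:
    """Average direction/entropy fields over the last ``window`` snapshots.

    Each snapshot is rebuilt into a frozen bank, queried at every state,
    and the per-state direction vectors and entropies averaged.
    """
    if len(snapshots) < window:
        raise ValueError(f"need >= {window} snapshots, have {len(snapshots)}")
    z = np.zeros((env.n_states, 2))
    h = np.zeros(env.n_states)
    for _, snap in snapshots[-window:]:
        bank = mem.bank_from_snapshot(snap, encoding.table)
        pmap = policy_map(bank, env, encoding)
        z += pmap @ DIRECTION_MATRIX
        p = np.where(pmap > 0, pmap, 1.0)
        h += -(pmap * np.log(p)).sum(axis=1)
    return PolicyFields(directions=z / window, entropy=h / window)


def neighbourhood_coherence(directions: np.ndarray, env: GridWorld) -> float:
    """Mean cosine similarity of preferred directions across graph-adjacent
    state pairs — the policy-coherence summary of a direction field."""
    sims = []
    norms = np.linalg.norm(directions, axis=1)
    for s in range(env.n_states):
        for a in range(N_ACTIONS):
            t = int(env.next_state[s, a])
            if t <= s:  # each undirected edge once, skip self-loops
                continue
            denom = norms[s] * norms[t]
            if denom > 1e-12:
                sims.append(float(directions[s] @ directions[t] / denom))
    return float(np.mean(sims))


# --------------------------------------------------------------------------
# Recall-match statistics
# --------------------------------------------------------------------------


class MatchStats(NamedTuple):
    exact_pct: float            # % of recall events with an exact key match
    mean_nonexact_distance: float  # mean Chebyshev distance of the rest

    @staticmethod
    def undefined() -> "MatchStats":
        return MatchStats(float("nan"), float("nan"))


def match_statistics(result: SimulationResult) -> dict[str, MatchStats]:
    """Exact-match percentage and mean non-match recall distance, split by
    episode outcome.  Groups with no recall events report NaN markers."""
    out: dict[str, MatchStats] = {}
    for label, mask in (("success", result.success), ("failure", ~result.success)):
        n_rec = int(result.n_recalls[mask].sum())
        if n_rec == 0:
            out[label] = MatchStats.undefined()
            continue
        n_ex = int(result.n_exact[mask].sum())
        n_non = n_rec - n_ex
        mean_d = float(result.nonexact_dist_sum[mask].sum() / n_non) if n_non else float("nan")
        out[label] = MatchStats(100.0 * n_ex / n_rec, mean_d)
    return out


# --------------------------------------------------------------------------
# Trajectory sampling from frozen banks
# --------------------------------------------------------------------------


def sample_trajectories(
    snapshots: Sequence[tuple[int, dict]],
    env: GridWorld,
    encoding: StateEncoding,
    per_snapshot: int,
    rng: np.random.Generator,
    max_steps: int = MAX_STEPS,
) -> np.ndarray:
    """Step counts of read-only episodes drawn from reconstructed banks.

    For each snapshot the bank is rebuilt, ``per_snapshot`` episodes are
    run from uniform random non-reward starts without any writes, and the
    number of steps taken (capped at ``max_steps``) recorded.
    """
    if not snapshots:
        raise ValueError("no snapshots to sample from")
    table = encoding.table
    pool = env.nonreward_indices
    nxt = env.next_state
    reward_idx = env.reward_index
    lengths = []
    for _, snap in snapshots:
        bank = mem.bank_from_snapshot(snap, table)
        cache: dict[int, np.ndarray] = {}
        for _ in range(per_snapshot):
            s = int(pool[rng.integers(pool.size)])
            steps = 0
            while s != reward_idx and steps < max_steps:
                policy = cache.get(s)
                if policy is None:
                    i, _, _ = mem.recall(bank, table[s])
                    policy = mem.policy_from_values(bank.values[i])
                    cache[s] = policy
                c = np.cumsum(policy)
                a = min(int(np.searchsorted(c, rng.random() * c[-1], side="right")), N_ACTIONS - 1)
                s = int(nxt[s, a])
                steps += 1
            lengths.append(max(steps, 1))
    return np.asarray(lengths, dtype=np.int64)


# --------------------------------------------------------------------------
# Forgetting incidence
# --------------------------------------------------------------------------


def forgetting_frequencies(tallies: Sequence[np.ndarray]) -> np.ndarray:
    """Per-run forgetting frequencies: each run's per-state counts divided
    by its total forgetting events.  Shape (n_runs, n_states)."""
    rows = []
    for t in tallies:
        t = np.asarray(t, dtype=float)
        total = t.sum()
        if total == 0:
            raise ValueError("run has zero forgetting events (unlimited capacity?)")
        rows.append(t / total)
    return np.vstack(rows)


def forgetting_incidence(tallies: Sequence[np.ndarray]) -> np.ndarray:
    """Mean per-state forgetting frequency across runs of one condition."""
    return forgetting_frequencies(tallies).mean(axis=0)


def incidence_difference(oldest_mean: np.ndarray, random_mean: np.ndarray) -> np.ndarray:
    """Oldest-rule minus random-rule mean incidence.  Negative entries mark
    states the oldest rule preserves relative to random forgetting; the
    field sums to ≈ 0 because both terms sum to 1."""
    return np.asarray(oldest_mean, dtype=float) - np.asarray(random_mean, dtype=float)


# --------------------------------------------------------------------------
# Welch's t-test with Bonferroni correction
# --------------------------------------------------------------------------


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    p_bonferroni: float


def welch_test(
    x: Sequence[float],
    y: Sequence[float],
    tails: str = "two",
    m_comparisons: int = 1,
) -> WelchResult:
    """Unpaired unequal-variance t-test with Welch–Satterthwaite df.

    ``tails``: 'two', or one-tailed 'greater'/'less' (mean(x) vs mean(y)).
    ``p_bonferroni`` = min(1, m·p).  Two identical zero-variance samples
    give t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if tails not in ("two", "greater", "less"):
        raise ValueError("tails must be 'two', 'greater' or 'less'")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    delta = x.mean() - y.mean()
    if se2 == 0.0:
        if delta == 0.0:
            # undefined t with equal means: no evidence either way
            return WelchResult(0.0, float(nx + ny - 2), 1.0, 1.0)
        t_stat = math.inf if delta > 0 else -math.inf
        df = float(nx + ny - 2)
    else:
        t_stat = delta / math.sqrt(se2)
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    if tails == "two":
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    elif tails == "greater":
        p = float(stats.t.sf(t_stat, df))
    else:
        p = float(stats.t.cdf(t_stat, df))
    p = min(p, 1.0)
    return WelchResult(float(t_stat), float(df), p, min(1.0, m_comparisons * p))


# --------------------------------------------------------------------------
# Optional rendering
# --------------------------------------------------------------------------


def render_field(
    values: np.ndarray,
    env: GridWorld,
    path: str,
    title: Optional[str] = None,
) -> None:
    """Save a per-state scalar field as a PNG heatmap (obstacles blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.full((env.height, env.width), np.nan)
    for (x, y), v in zip(env.available_states, values):
        grid[y, x] = v
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, origin="lower")
    fig.colorbar(im, ax=ax)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
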