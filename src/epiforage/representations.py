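"""State encodings used as episodic-memory keys.

Each encoding assigns every available state a unique activity vector.  Two
are *unstructured* (onehot, uniform random): distances between their rows
carry no information about where states sit in the maze.  Two are
*structured*:

* place-cell codes — one Gaussian-tuned unit per available state, activity
  falling off with Euclidean distance from the unit's preferred location in
  grid-normalized coordinates.  Place fields ignore walls entirely.
* successor representations (SR) — row ``s`` of ``M = (I - γT)^{-1}``, the
  expected discounted future occupancy of every state starting from ``s``
  under a uniform random walk.  Because T is built from the obstacle-pruned
  state graph the SR is sensitive to walls.

Retrieval compares keys with the Chebyshev (L∞) distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .gridworld import GridWorld, N_ACTIONS

ENCODING_KINDS = ("onehot", "random", "place_cell", "successor")


@dataclass(eq=False)
class StateEncoding:
    """Per-state activity table: row i is the key vector of available state i."""

    kind: str
    table: np.ndarray  # shape (n_states, dim)
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.table.shape[1]


@dataclass(eq=False)
class TransitionModel:
    """Row-stochastic random-walk transition matrix on available states."""

    matrix: np.ndarray


def onehot_encoding(env: GridWorld) -> StateEncoding:
    """Unit basis vectors: state i's key has a 1 at index i, zeros elsewhere."""
    return StateEncoding("onehot", np.eye(env.n_states))


def random_encoding(env: GridWorld, seed: int) -> StateEncoding:
    """I.i.d. uniform [0, 1) keys, one row per state, reproducible from seed.

    The dimensionality is set to the number of available states so that all
    four encodings share key dimension.
    """
    rng = np.random.default_rng(seed)
    table = rng.random((env.n_states, env.n_states))
    return StateEncoding("random", table, {"seed": seed})


def place_cell_encoding(env: GridWorld, sigma: float = 0.05) -> StateEncoding:
    """Gaussian place-cell population code.

    One unit per available state, centred on that state in grid-normalized
    coordinates (grid coordinates divided by the grid width, so the default
    σ = 0.05 equals one cell).  Unit i's activity at agent position (x, y):

        f_i(x, y) = (1 / 2πσ²) · exp(−[(x−x_i)² + (y−y_i)²] / 2σ²)

    Activities depend only on Euclidean distance — walls are invisible to
    this code.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    coords = np.asarray(env.available_states, dtype=float) / env.width
    diff = coords[:, None, :] - coords[None, :, :]
    sq = (diff ** 2).sum(axis=2)
    table = np.exp(-sq / (2.0 * sigma ** 2)) / (2.0 * np.pi * sigma ** 2)
    return StateEncoding("place_cell", table, {"sigma": sigma})


def random_walk_transitions(env: GridWorld) -> TransitionModel:
    """T(s, s') under the uniform random walk: each of the four actions with
    probability 1/4, blocked actions contributing to the self-loop."""
    n = env.n_states
    T = np.zeros((n, n))
    for s in range(n):
        for a in range(N_ACTIONS):
            T[s, env.next_state[s, a]] += 1.0 / N_ACTIONS
    return TransitionModel(T)


def successor_encoding(env: GridWorld, gamma: float = 0.98) -> StateEncoding:
    """Successor-representation keys, M = (I − γT)^{-1} solved as a linear
    system.  Rows are nonnegative and each sums to 1/(1−γ)."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    T = random_walk_transitions(env).matrix
    n = env.n_states
    M = np.linalg.solve(np.eye(n) - gamma * T, np.eye(n))
    return StateEncoding("successor", M, {"gamma": gamma})


def make_encoding(
    env: GridWorld,
    kind: str,
    *,
    sigma: float = 0.05,
    gamma: float = 0.98,
    seed: int = 0,
) -> StateEncoding:
    """Dispatch on encoding kind with the standard defaults."""
    if kind == "onehot":
        return onehot_encoding(env)
    if kind == "random":
        return random_encoding(env, seed)
    if kind == "place_cell":
        return place_cell_encoding(env, sigma)
    if kind == "successor":
        return successor_encoding(env, gamma)
    raise ValueError(f"unknown encoding kind {kind!r}; choose from {ENCODING_KINDS}")


def chebyshev_distance(p: np.ndarray, q: np.ndarray) -> float:
    """L∞ distance: maximum absolute coordinate difference."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {q.shape}")
    return float(np.max(np.abs(p - q))) if p.size else 0.0


def encoding_to_frame(encoding: StateEncoding, env: GridWorld):
    """Export an encoding table as a DataFrame indexed by state coordinate."""
    import pandas as pd

    index = [f"{x},{y}" for x, y in env.available_states]
    return pd.DataFrame(encoding.table, index=index)
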