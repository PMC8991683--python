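"""Gridworld foraging environments.

Four 20x20 lattice mazes (open field, separated field, four rooms, tunnel)
in which an agent forages for a single rewarded state.  States are grid
coordinates ``(x, y)`` with ``y`` increasing upward; the four actions are
Down, Up, Left, Right in that order.  Obstacle cells are removed from the
state graph entirely (no edges into or out of them), and an action that
would move the agent into an obstacle or off the grid leaves it in place.

Every non-reward state carries a small step penalty (-0.01); the reward
state pays +10 and ends the episode.  Episodes are capped at 250 reward
receipts, so a completely failed episode scores exactly -2.5 and an optimal
path of geodesic length ``d`` scores ``10 - 0.01 d``.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# --------------------------------------------------------------------------
# Constants and action semantics
# --------------------------------------------------------------------------

GRID_SIZE = 20
STEP_PENALTY = -0.01
REWARD_VALUE = 10.0
MAX_STEPS = 250

DOWN, UP, LEFT, RIGHT = 0, 1, 2, 3
N_ACTIONS = 4
ACTION_NAMES = ("down", "up", "left", "right")
#: Cardinal displacement of each action, row order Down, Up, Left, Right.
ACTION_VECTORS = np.array([(0, -1), (0, 1), (-1, 0), (1, 0)], dtype=np.int64)

Coord = tuple[int, int]

# --------------------------------------------------------------------------
# Layout data
#
# The obstacle sets below are the layout definitions; revise these coordinate
# lists to change a maze, nothing else depends on how they are produced.
# four_rooms is pinned by its published 365-available-state count (full cross
# walls minus four doorways = 35 obstacles); separated_field and tunnel are
# reconstructions of the pictured mazes.
# --------------------------------------------------------------------------


def _four_rooms() -> frozenset[Coord]:
    walls = {(x, 10) for x in range(GRID_SIZE)} | {(10, y) for y in range(GRID_SIZE)}
    doorways = {(5, 10), (15, 10), (10, 5), (10, 15)}
    return frozenset(walls - doorways)


def _separated_field() -> frozenset[Coord]:
    # Vertical wall at x=10 spanning y=0..13; single gap along the top.
    return frozenset((10, y) for y in range(14))


def _tunnel() -> frozenset[Coord]:
    # Horizontal wall segments above and below a one-row corridor at y=10,
    # open at both ends.
    return frozenset({(x, 9) for x in range(2, 18)} | {(x, 11) for x in range(2, 18)})


LAYOUTS: dict[str, frozenset[Coord]] = {
    "open_field": frozenset(),
    "separated_field": _separated_field(),
    "four_rooms": _four_rooms(),
    "tunnel": _tunnel(),
}

#: Default reward location per layout: off-centre, never on an obstacle.
DEFAULT_REWARD_STATE: dict[str, Coord] = {
    "open_field": (14, 14),
    "separated_field": (14, 14),
    "four_rooms": (14, 14),
    "tunnel": (14, 14),
}


# --------------------------------------------------------------------------
# Environment container
# --------------------------------------------------------------------------


@dataclass(eq=False)
class GridWorld:
    """A foraging maze: lattice states, obstacles, reward and step dynamics.

    ``available_states`` fixes the canonical state ordering used everywhere
    (encoding rows, memory keys, tallies).  ``next_state[s, a]`` gives the
    state index reached from state ``s`` under action ``a`` with blocked
    moves mapping back to ``s``.
    """

    layout: str
    width: int
    height: int
    obstacles: frozenset[Coord]
    available_states: tuple[Coord, ...]
    reward_state: Coord
    step_penalty: float = STEP_PENALTY
    reward_value: float = REWARD_VALUE
    max_steps: int = MAX_STEPS
    state_index: dict[Coord, int] = field(repr=False, default_factory=dict)
    next_state: np.ndarray = field(repr=False, default=None)
    rewards: np.ndarray = field(repr=False, default=None)

    @property
    def n_states(self) -> int:
        return len(self.available_states)

    @property
    def reward_index(self) -> int:
        return self.state_index[self.reward_state]

    @property
    def nonreward_indices(self) -> np.ndarray:
        """Indices of every available state except the reward (start pool)."""
        idx = np.arange(self.n_states)
        return idx[idx != self.reward_index]


def build_environment(layout: str, reward_state: Coord | None = None) -> GridWorld:
    """Construct one of the four canonical mazes.

    Parameters
    ----------
    layout
        One of ``open_field``, ``separated_field``, ``four_rooms``, ``tunnel``.
    reward_state
        Optional ``(x, y)`` reward location; defaults to the layout's
        documented position.  Must not be an obstacle.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {sorted(LAYOUTS)}")
    obstacles = LAYOUTS[layout]
    if reward_state is None:
        reward_state = DEFAULT_REWARD_STATE[layout]
    return _assemble(layout, GRID_SIZE, GRID_SIZE, obstacles, tuple(reward_state))


def _assemble(
    layout: str,
    width: int,
    height: int,
    obstacles: frozenset[Coord],
    reward_state: Coord,
) -> GridWorld:
    for ox, oy in obstacles:
        if not (0 <= ox < width and 0 <= oy < height):
            raise ValueError(f"obstacle {(ox, oy)} lies outside the {width}x{height} grid")
    if reward_state in obstacles:
        raise ValueError(f"reward state {reward_state} is an obstacle")
    if not (0 <= reward_state[0] < width and 0 <= reward_state[1] < height):
        raise ValueError(f"reward state {reward_state} lies outside the grid")

    available = tuple(
        (x, y) for x in range(width) for y in range(height) if (x, y) not in obstacles
    )
    state_index = {s: i for i, s in enumerate(available)}
    n = len(available)

    nxt = np.empty((n, N_ACTIONS), dtype=np.int64)
    for i, (x, y) in enumerate(available):
        for a in range(N_ACTIONS):
            dx, dy = ACTION_VECTORS[a]
            tx, ty = x + int(dx), y + int(dy)
            if 0 <= tx < width and 0 <= ty < height and (tx, ty) not in obstacles:
                nxt[i, a] = state_index[(tx, ty)]
            else:
                nxt[i, a] = i  # blocked: stay in place

    rewards = np.full(n, STEP_PENALTY)
    rewards[state_index[reward_state]] = REWARD_VALUE

    env = GridWorld(
        layout=layout,
        width=width,
        height=height,
        obstacles=obstacles,
        available_states=available,
        reward_state=reward_state,
        state_index=state_index,
        next_state=nxt,
        rewards=rewards,
    )
    if np.any(distances_from(env, reward_state) < 0):
        raise ValueError(f"layout {layout!r} is disconnected: some state cannot reach the reward")
    return env


# --------------------------------------------------------------------------
# Dynamics and geometry
# --------------------------------------------------------------------------


def step(env: GridWorld, state: Coord, action: int) -> Coord:
    """One transition: the neighbour in the action's direction, or ``state``
    unchanged if that cell is an obstacle or off-grid."""
    if state not in env.state_index:
        raise ValueError(f"{state} is not an available state")
    if not 0 <= action < N_ACTIONS:
        raise ValueError(f"invalid action {action}")
    return env.available_states[env.next_state[env.state_index[state], action]]


def distances_from(env: GridWorld, source: Coord) -> np.ndarray:
    """Geodesic (BFS) distance from ``source`` to every available state.

    Returns an integer array indexed like ``available_states``; unreachable
    states get -1 (only possible for a malformed custom layout).
    """
    if source not in env.state_index:
        raise ValueError(f"{source} is not an available state")
    n = env.n_states
    dist = np.full(n, -1, dtype=np.int64)
    s0 = env.state_index[source]
    dist[s0] = 0
    queue = deque([s0])
    while queue:
        s = queue.popleft()
        for a in range(N_ACTIONS):
            t = env.next_state[s, a]
            if dist[t] < 0:
                dist[t] = dist[s] + 1
                queue.append(t)
    return dist


def geodesic_distance(env: GridWorld, source: Coord, target: Coord) -> int:
    """Shortest path length between two available states on the obstacle-
    respecting state graph."""
    if target not in env.state_index:
        raise ValueError(f"{target} is not an available state")
    d = int(distances_from(env, source)[env.state_index[target]])
    if d < 0:
        raise ValueError(f"{target} is unreachable from {source}")
    return d


def mean_distance_to_reward(env: GridWorld, include_reward_state: bool = False) -> float:
    """λ: mean geodesic distance of available states to the reward state.

    The reward state itself (distance 0) is excluded by default because a
    start there never occurs in the task; including it shifts λ by well
    under 1% on these grids.
    """
    d = distances_from(env, env.reward_state).astype(float)
    if include_reward_state:
        return float(d.mean())
    return float(d[np.arange(env.n_states) != env.reward_index].mean())


def optimal_average_reward(env: GridWorld, include_reward_state: bool = False) -> float:
    """Best achievable average episode score, R* = 10 - 0.01 λ.

    An optimal agent starting at geodesic distance d accrues d step
    penalties before the +10 receipt, so averaging over uniform starts
    gives 10 - 0.01 λ.  Degenerate single-state environments give 10.
    """
    if env.n_states == 1:
        return env.reward_value
    lam = mean_distance_to_reward(env, include_reward_state=include_reward_state)
    return env.reward_value + env.step_penalty * lam


# --------------------------------------------------------------------------
# Layout file I/O: a one-line JSON header followed by "x,y" obstacle lines
# --------------------------------------------------------------------------


def save_layout(env: GridWorld, path: str | Path) -> None:
    header = {
        "layout": env.layout,
        "width": env.width,
        "height": env.height,
        "reward_state": list(env.reward_state),
    }
    lines = [json.dumps(header)]
    lines += [f"{x},{y}" for x, y in sorted(env.obstacles)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_layout(path: str | Path) -> GridWorld:
    """Build an environment from a layout file written by :func:`save_layout`."""
    text = Path(path).read_text().strip().splitlines()
    header = json.loads(text[0])
    obstacles: set[Coord] = set()
    for line in text[1:]:
        line = line.strip()
        if not line:
            continue
        x, y = (int(v) for v in line.split(","))
        obstacles.add((x, y))
    return _assemble(
        header.get("layout", "custom"),
        int(header["width"]),
        int(header["height"]),
        frozenset(obstacles),
        tuple(header["reward_state"]),
    )
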