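"""Capacity-limited episodic memory bank.

The bank is a dictionary of at most N entries.  Each entry pairs a key
(the activity vector of a visited state) with a 4-slot value array holding
the most recent Monte-Carlo return observed for each action taken there,
plus a timestamp recording when the entry was last written.

Retrieval finds the stored key nearest the query under the Chebyshev (L∞)
distance and turns its value array into a softmax policy.  When a novel
state must be stored in a full bank an old entry is overwritten — the
forgetting event.  Two victim-selection rules are provided:

* ``oldest`` — the least recently *updated* entry (write-time stamping;
  an ``forget_on='access'`` switch additionally refreshes timestamps on
  recall, for comparison).
* ``random`` — uniform over stored entries.

Unvisited action slots default to a return of 0.0 so the softmax always
has four finite inputs; a single large observed return then dominates the
policy, which is what produces confident policies near the reward.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np

from .gridworld import N_ACTIONS

FORGETTING_RULES = ("oldest", "random")


def capacity_for(fraction: float, n_available: int) -> int:
    """Dictionary capacity for a memory-restriction condition.

    ``floor(fraction * n_available)``: 75% of the open field's 400 states
    gives N = 300; 75% of the four rooms' 365 gives N = 273.  A fraction of
    1 means every state fits and nothing is ever overwritten.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("capacity fraction must lie in (0, 1]")
    if n_available <= 0:
        raise ValueError("n_available must be positive")
    # Guard against binary round-off pulling an exact product below its
    # integer value (e.g. 0.29 * 100 -> 28.999...96).
    return int(math.floor(fraction * n_available + 1e-9))


@dataclass
class MemoryEntry:
    """Read-only view of one stored event record."""

    key: np.ndarray
    values: np.ndarray          # 4 return slots; unvisited slots hold 0.0
    filled: np.ndarray          # which slots were actually observed
    last_update: int
    state: Optional[Any] = None  # provenance label (state index), if supplied


class MemoryBank:
    """Fixed-capacity key-value store with forgetting.

    Keys live in a preallocated ``(capacity, dim)`` array for fast
    vectorized nearest-key search; an exact-match hash table keyed on the
    key bytes gives O(1) update-in-place.
    """

    def __init__(
        self,
        capacity: int,
        key_dim: int,
        rule: str = "oldest",
        forget_on: str = "update",
        tie_break: str = "first",
    ):
        if capacity < 1:
            raise ValueError("capacity must be a positive integer")
        if rule not in FORGETTING_RULES:
            raise ValueError(f"unknown forgetting rule {rule!r}")
        if forget_on not in ("update", "access"):
            raise ValueError("forget_on must be 'update' or 'access'")
        if tie_break not in ("first", "random"):
            raise ValueError("tie_break must be 'first' or 'random'")
        self.capacity = capacity
        self.key_dim = key_dim
        self.rule = rule
        self.forget_on = forget_on
        self.tie_break = tie_break
        self.n = 0
        self.event_counter = 0
        self._keys = np.empty((capacity, key_dim))
        self._values = np.zeros((capacity, N_ACTIONS))
        self._filled = np.zeros((capacity, N_ACTIONS), dtype=bool)
        self._last_update = np.zeros(capacity, dtype=np.int64)
        self._state: list[Any] = [None] * capacity
        self._keybytes: list[bytes] = [b""] * capacity
        self._lookup: dict[bytes, int] = {}
        #: state labels (or row indices when unlabelled) of overwritten entries
        self.forget_log: list[Any] = []

    def __len__(self) -> int:
        return self.n

    @property
    def keys(self) -> np.ndarray:
        return self._keys[: self.n]

    @property
    def values(self) -> np.ndarray:
        return self._values[: self.n]

    @property
    def states(self) -> list[Any]:
        return self._state[: self.n]

    def entry(self, i: int) -> MemoryEntry:
        if not 0 <= i < self.n:
            raise IndexError(f"no entry {i} in a bank of {self.n}")
        return MemoryEntry(
            key=self._keys[i].copy(),
            values=self._values[i].copy(),
            filled=self._filled[i].copy(),
            last_update=int(self._last_update[i]),
            state=self._state[i],
        )


def recall(
    bank: MemoryBank,
    query: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> tuple[int, float, bool]:
    """Nearest stored entry to ``query`` under Chebyshev distance.

    Returns ``(index, distance, exact)`` where ``exact`` means distance is
    exactly zero (safe because queries and keys come from the same
    precomputed table).  Ties go to the lowest storage index unless the
    bank was built with ``tie_break='random'``.  Retrieval does not touch
    timestamps unless ``forget_on='access'``.
    """
    if bank.n == 0:
        raise LookupError("recall from an empty memory bank")
    q = np.asarray(query, dtype=float)
    if q.shape != (bank.key_dim,):
        raise ValueError(f"query dimension {q.shape} != key dimension ({bank.key_dim},)")
    d = np.abs(bank._keys[: bank.n] - q).max(axis=1)
    if bank.tie_break == "random":
        if rng is None:
            raise ValueError("tie_break='random' requires an rng")
        lo = d.min()
        i = int(rng.choice(np.flatnonzero(d == lo)))
    else:
        i = int(np.argmin(d))
    if bank.forget_on == "access":
        bank.event_counter += 1
        bank._last_update[i] = bank.event_counter
    return i, float(d[i]), bool(d[i] == 0.0)


def policy_from_values(values: np.ndarray) -> np.ndarray:
    """Unit-temperature softmax over the four return slots.

    Computed with max-subtraction; softmax shift invariance makes this
    exact.  Empty slots must already hold the 0.0 default.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (N_ACTIONS,):
        raise ValueError(f"expected {N_ACTIONS} return slots, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("return values must be finite")
    e = np.exp(v - v.max())
    return e / e.sum()


def select_forget_index(
    bank: MemoryBank,
    rule: str | None = None,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Pick the entry to overwrite when the bank is full.

    ``oldest``: minimal last-update timestamp, ties to the lowest storage
    index.  ``random``: uniform over entries (requires an rng).
    """
    rule = bank.rule if rule is None else rule
    if bank.n < bank.capacity:
        raise RuntimeError("bank below capacity: no forgetting needed")
    if rule == "oldest":
        return int(np.argmin(bank._last_update[: bank.n]))
    if rule == "random":
        if rng is None:
            raise ValueError("random forgetting requires an rng")
        return int(rng.integers(bank.n))
    raise ValueError(f"unknown forgetting rule {rule!r}")


def write_event(
    bank: MemoryBank,
    key: np.ndarray,
    action: int,
    return_value: float,
    state: Any = None,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Store one (state, action, return) event; returns the row written.

    Exact key match: that entry's action slot is overwritten with the most
    recent return and the timestamp refreshed.  Novel key below capacity:
    appended.  Novel key at capacity: a victim chosen by the bank's
    forgetting rule is replaced wholesale — the forgetting event, logged in
    ``bank.forget_log`` under the victim's state label.
    """
    k = np.ascontiguousarray(key, dtype=float)
    if k.shape != (bank.key_dim,):
        raise ValueError(f"key dimension {k.shape} != bank dimension ({bank.key_dim},)")
    if not np.isfinite(return_value):
        raise ValueError("return value must be finite")
    if not 0 <= action < N_ACTIONS:
        raise ValueError(f"invalid action {action}")

    bank.event_counter += 1
    h = k.tobytes()
    row = bank._lookup.get(h)
    if row is None:
        if bank.n < bank.capacity:
            row = bank.n
            bank.n += 1
        else:
            row = select_forget_index(bank, rng=rng)
            victim = bank._state[row]
            bank.forget_log.append(victim if victim is not None else row)
            del bank._lookup[bank._keybytes[row]]
        bank._keys[row] = k
        bank._keybytes[row] = h
        bank._lookup[h] = row
        bank._values[row] = 0.0
        bank._filled[row] = False
        bank._state[row] = state
    bank._values[row, action] = return_value
    bank._filled[row, action] = True
    bank._last_update[row] = bank.event_counter
    return row


# --------------------------------------------------------------------------
# Snapshots: JSON-friendly dumps keyed by state label; keys are rebuilt from
# the encoding table on load, so snapshots stay small and text-only.
# --------------------------------------------------------------------------


def snapshot(bank: MemoryBank) -> dict:
    entries = []
    for i in range(bank.n):
        vals = [
            float(bank._values[i, a]) if bank._filled[i, a] else None
            for a in range(N_ACTIONS)
        ]
        entries.append(
            {
                "state": bank._state[i],
                "values": vals,
                "last_update": int(bank._last_update[i]),
            }
        )
    return {"capacity": bank.capacity, "rule": bank.rule, "entries": entries}


def bank_from_snapshot(
    snap: dict,
    encoding_table: np.ndarray,
    rule: str | None = None,
) -> MemoryBank:
    """Reconstruct a bank from a snapshot, pulling keys from the encoding
    table by the stored state labels (which must be state indices)."""
    entries = snap["entries"]
    capacity = int(snap.get("capacity") or max(len(entries), 1))
    bank = MemoryBank(capacity, encoding_table.shape[1], rule=rule or snap.get("rule", "oldest"))
    for e in entries:
        s = e["state"]
        if s is None:
            raise ValueError("snapshot entry lacks a state label; cannot rebuild its key")
        for a, v in enumerate(e["values"]):
            if v is not None:
                write_event(bank, encoding_table[s], a, float(v), state=s)
        bank._last_update[bank.n - 1] = int(e["last_update"])
    bank.event_counter = int(max((e["last_update"] for e in entries), default=0))
    return bank


def save_snapshots(snapshots: list[tuple[int, dict]], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([{"episode": ep, **snap} for ep, snap in snapshots])
    )


def load_snapshots(path: str | Path) -> list[tuple[int, dict]]:
    raw = json.loads(Path(path).read_text())
    return [(int(d["episode"]), {k: d[k] for k in ("capacity", "rule", "entries")}) for d in raw]
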