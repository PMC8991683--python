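"""Shared fixtures.

The two session-scoped simulation batches back both the acceptance tests
and the simulation/analysis property tests; they are the expensive part of
the suite (a few minutes each) and run at the reduced scale the checks are
defined at: 1000 episodes per seed.
"""

from __future__ import annotations

import numpy as np
import pytest

import epiforage as ef

LADDER_SEEDS = (0, 1, 2, 3, 4)
LADDER_FRACTIONS = (1.0, 0.75, 0.25)
REDUCED_EPISODES = 1000

FORGET_SEEDS = (0, 1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def open_field():
    return ef.build_environment("open_field")


@pytest.fixture(scope="session")
def four_rooms():
    return ef.build_environment("four_rooms")


@pytest.fixture(scope="session")
def separated_field():
    return ef.build_environment("separated_field")


@pytest.fixture(scope="session")
def ladder_runs():
    """Open-field capacity ladder: onehot vs successor at 100/75/25%
    capacity, 5 matched seeds each, with dense final-window snapshots."""
    runs = {}
    for enc in ("onehot", "successor"):
        for frac in LADDER_FRACTIONS:
            for seed in LADDER_SEEDS:
                cfg = ef.SimulationConfig(
                    layout="open_field",
                    encoding=enc,
                    capacity_fraction=frac,
                    seed=seed,
                    n_episodes=REDUCED_EPISODES,
                    snapshot_dense_window=25,
                    snapshot_sparse_every=500,
                )
                runs[(enc, frac, seed)] = ef.run_simulation(cfg)
    return runs


@pytest.fixture(scope="session")
def ladder_perf(ladder_runs):
    """Per-condition list of per-seed normalized performances."""
    perf = {}
    for (enc, frac, seed), r in ladder_runs.items():
        perf.setdefault((enc, frac), []).append(
            ef.normalize_performance(r.scores, r.env)
        )
    return perf


@pytest.fixture(scope="session")
def baseline_perf(open_field):
    """Chance level: per-seed normalized performance of random-walk agents."""
    return [
        ef.normalize_performance(
            ef.random_walk_baseline(open_field, REDUCED_EPISODES, seed), open_field
        )
        for seed in LADDER_SEEDS
    ]


@pytest.fixture(scope="session")
def forgetting_runs():
    """Four-rooms oldest vs random forgetting at 75% capacity, 6 seeds."""
    runs = {"oldest": [], "random": []}
    for rule in runs:
        for seed in FORGET_SEEDS:
            cfg = ef.SimulationConfig(
                layout="four_rooms",
                encoding="successor",
                capacity_fraction=0.75,
                forgetting_rule=rule,
                seed=seed,
                n_episodes=REDUCED_EPISODES,
                snapshot_dense_window=1,
                snapshot_sparse_every=2000,
            )
            runs[rule].append(ef.run_simulation(cfg))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
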