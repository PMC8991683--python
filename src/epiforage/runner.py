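"""Condition-grid orchestration.

Expands an experiment grid (environments × encodings × capacity fractions ×
forgetting rules × seeds) into simulation configs, runs them sequentially,
and summarises mean/SD normalized performance per condition with Welch
tests (Bonferroni-corrected) between each restricted-capacity condition and
the unrestricted one.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import normalize_performance, welch_test
from .simulation import SimulationConfig, SimulationResult, run_simulation, save_result

log = logging.getLogger("epiforage")

#: Capacity ladder of the main performance comparison.
DEFAULT_FRACTIONS = (1.0, 0.9, 0.75, 0.6, 0.5, 0.25)


@dataclass
class ExperimentGrid:
    environments: Sequence[str] = ("open_field",)
    encodings: Sequence[str] = ("onehot", "successor")
    fractions: Sequence[float] = DEFAULT_FRACTIONS
    rules: Sequence[str] = ("oldest",)
    seeds: Sequence[int] = (0, 1, 2, 3, 4, 5)
    n_episodes: int = 5000
    gamma: float = 0.98
    sigma: float = 0.05
    outdir: Optional[str] = None
    extra: dict = field(default_factory=dict)


def _dedupe(name: str, values: Sequence) -> list:
    seen: list = []
    for v in values:
        if v in seen:
            warnings.warn(f"duplicate {name} value {v!r} in grid; deduplicated")
        else:
            seen.append(v)
    return seen


def expand_grid(grid: ExperimentGrid) -> list[SimulationConfig]:
    """Cartesian product of the grid axes, one config per cell × seed, in a
    stable, deterministic order."""
    axes = {
        "environments": _dedupe("environment", grid.environments),
        "encodings": _dedupe("encoding", grid.encodings),
        "fractions": _dedupe("fraction", grid.fractions),
        "rules": _dedupe("rule", grid.rules),
        "seeds": _dedupe("seed", grid.seeds),
    }
    for name, vals in axes.items():
        if not vals:
            raise ValueError(f"empty grid axis: {name}")
    configs = []
    for env, enc, frac, rule, seed in itertools.product(
        axes["environments"], axes["encodings"], axes["fractions"], axes["rules"], axes["seeds"]
    ):
        configs.append(
            SimulationConfig(
                layout=env,
                encoding=enc,
                capacity_fraction=frac,
                forgetting_rule=rule,
                seed=seed,
                n_episodes=grid.n_episodes,
                gamma=grid.gamma,
                sigma=grid.sigma,
                **grid.extra,
            )
        )
    return configs


def _condition_key(c: SimulationConfig) -> tuple:
    return (c.layout, c.encoding, c.capacity_fraction, c.forgetting_rule)


def run_experiment(
    grid: ExperimentGrid,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every grid cell and summarise.

    Returns ``(summary, tests)``: per-condition mean/SD of per-seed
    normalized performance (the mean of simulation-average values over
    seeds), and Welch comparisons of each restricted condition against the
    full-capacity condition of the same environment/encoding/rule,
    Bonferroni-corrected within that family.
    """
    configs = expand_grid(grid)
    outdir = Path(grid.outdir) if grid.outdir else None
    perf: dict[tuple, list[float]] = {}
    forgets: dict[tuple, list[int]] = {}
    for i, cfg in enumerate(configs):
        log.info("run %d/%d: %s", i + 1, len(configs), _condition_key(cfg) + (cfg.seed,))
        result = run_simulation(cfg)
        key = _condition_key(cfg)
        perf.setdefault(key, []).append(normalize_performance(result.scores, result.env))
        forgets.setdefault(key, []).append(int(result.forget_tally.sum()))
        if outdir is not None:
            rundir = outdir / (
                f"{cfg.layout}_{cfg.encoding}_f{cfg.capacity_fraction:g}"
                f"_{cfg.forgetting_rule}_s{cfg.seed}"
            )
            save_result(result, rundir)

    rows = []
    for key, vals in perf.items():
        env, enc, frac, rule = key
        rows.append(
            {
                "environment": env,
                "encoding": enc,
                "capacity_fraction": frac,
                "forgetting_rule": rule,
                "n_seeds": len(vals),
                "mean_normalized_performance": float(np.mean(vals)),
                "sd_normalized_performance": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "mean_forgetting_events": float(np.mean(forgets[key])),
            }
        )
    summary = pd.DataFrame(rows)

    test_rows = []
    families: dict[tuple, list[tuple]] = {}
    for key in perf:
        env, enc, frac, rule = key
        families.setdefault((env, enc, rule), []).append(key)
    for fam, keys in families.items():
        full = next((k for k in keys if k[2] == 1.0), None)
        restricted = [k for k in keys if k is not full]
        m = len(restricted)
        if full is None or m == 0 or len(perf[full]) < 2:
            continue
        for k in restricted:
            if len(perf[k]) < 2:
                continue
            res = welch_test(perf[k], perf[full], tails="two", m_comparisons=m)
            test_rows.append(
                {
                    "environment": fam[0],
                    "encoding": fam[1],
                    "forgetting_rule": fam[2],
                    "capacity_fraction": k[2],
                    "vs_fraction": 1.0,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "p_bonferroni": res.p_bonferroni,
                }
            )
    tests = pd.DataFrame(test_rows)

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "summary.csv", index=False)
        if not tests.empty:
            tests.to_csv(outdir / "welch_tests.csv", index=False)
    return summary, tests
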