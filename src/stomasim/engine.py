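"""Seeded random-order asynchronous ensemble simulation.

Each time step draws a fresh uniform permutation of the internal nodes
(signals, clamped nodes and the output are excluded) and updates them in
that sequence against the *current*, partially updated state; the output
node is always updated last.  Signals are refreshed from their schedule
at the start of each step and are never updated by rules.  A node with
``delay_steps = d`` evaluates its rule against the recorded system state
``d`` steps earlier (states before step 0 equal the initial state).

Replicates are statistically independent: each draws its random stream
from a child of the master seed via ``numpy`` seed-sequence spawning, so
results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import rules as R
from .model import ModelSpec

__all__ = [
    "ExperimentConfig", "EnsembleResult", "SummaryStats",
    "run_replicate", "run_ensemble", "summarize", "run_pulse_protocol",
    "synchronous_step",
]


@dataclass
class ExperimentConfig:
    """One simulated experimental condition.

    ``signal_levels`` holds constant signal settings;
    ``signal_schedule`` maps a signal name to ``{step: level}`` change
    points (the latest change point at or before the current step is in
    force, before the first change point the constant/initial level
    applies).  ``clamps`` fix nodes at a level for the whole run —
    knockouts, constitutive activation, pharmacological treatments.
    ``rule_overrides`` swap in alternative update rules by rule text.
    """

    n_steps: int = 18
    n_replicates: int = 2000
    seed: int = 0
    signal_levels: dict[str, float] = field(default_factory=dict)
    signal_schedule: dict[str, dict[int, float]] = field(default_factory=dict)
    clamps: dict[str, float] = field(default_factory=dict)
    rule_overrides: dict[str, str] = field(default_factory=dict)

    def validate_against(self, model: ModelSpec) -> None:
        errors = []
        signal_names = {s.name for s in model.signals}
        declared = set(model.node_names)
        for name in list(self.signal_levels) + list(self.signal_schedule):
            if name not in signal_names:
                errors.append(f"{name!r} is not a signal node")
        for name, levels in (
                [(k, [v]) for k, v in self.signal_levels.items()]
                + [(k, list(v.values())) for k, v in self.signal_schedule.items()]):
            if name in signal_names:
                node = model.node(name)
                for lv in levels:
                    if not (node.min_level <= lv <= node.max_level):
                        errors.append(f"signal {name}={lv} outside "
                                      f"[{node.min_level}, {node.max_level}]")
        for name, lv in self.clamps.items():
            if name not in declared:
                errors.append(f"clamped node {name!r} is not declared")
            else:
                node = model.node(name)
                if not (node.min_level <= lv <= node.max_level):
                    errors.append(f"clamp {name}={lv} outside "
                                  f"[{node.min_level}, {node.max_level}]")
        if self.n_steps < 0 or self.n_replicates < 1:
            errors.append("n_steps must be >= 0 and n_replicates >= 1")
        if errors:
            raise ValueError("invalid experiment config:\n  - " + "\n  - ".join(errors))


@dataclass
class EnsembleResult:
    """Per-replicate trajectories plus ensemble mean and standard error.

    ``levels`` has shape ``(n_replicates, n_steps + 1, n_nodes)``; step 0
    is the initial condition.
    """

    levels: np.ndarray
    node_names: list[str]
    config: ExperimentConfig
    model_name: str = ""

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.node_names)}

    @property
    def n_replicates(self) -> int:
        return self.levels.shape[0]

    @property
    def n_steps(self) -> int:
        return self.levels.shape[1] - 1

    @property
    def mean_trajectory(self) -> np.ndarray:
        """(n_steps+1, n_nodes) arithmetic mean over replicates."""
        return self.levels.mean(axis=0)

    @property
    def sem_trajectory(self) -> np.ndarray:
        n = self.n_replicates
        if n < 2:
            return np.zeros_like(self.mean_trajectory)
        return self.levels.std(axis=0, ddof=1) / np.sqrt(n)

    def node_levels(self, node: str) -> np.ndarray:
        """(n_replicates, n_steps+1) trajectory slice for one node."""
        return self.levels[:, :, self._index[node]]

    def node_mean(self, node: str) -> np.ndarray:
        return self.node_levels(node).mean(axis=0)

    def to_frame(self):
        """Tidy (replicate, step, node, level) DataFrame."""
        import pandas as pd
        reps, steps, nodes = self.levels.shape
        rep_idx = np.repeat(np.arange(reps), steps * nodes)
        step_idx = np.tile(np.repeat(np.arange(steps), nodes), reps)
        node_idx = np.tile(np.arange(nodes), reps * steps)
        return pd.DataFrame({
            "replicate": rep_idx,
            "step": step_idx,
            "node": np.asarray(self.node_names, dtype=object)[node_idx],
            "level": self.levels.reshape(-1),
        })


@dataclass(frozen=True)
class SummaryStats:
    """Sigmoidal-trajectory summary for one node.

    ``max_level`` is the maximum over steps of the ensemble mean (the
    steady-state plateau for sigmoidal time courses).  ``t50`` (``t95``)
    is the first step at which at least 50% (95%) of replicates attain at
    least 50% (95%) of ``max_level``.  All three are 0 when the node
    never rises.
    """

    max_level: float
    t50: int
    t95: int


# ---------------------------------------------------------------------------
# Compiled simulation plan
# ---------------------------------------------------------------------------

class _SimPlan:
    """Model + config compiled to positional arrays and rule closures."""

    def __init__(self, model: ModelSpec, config: ExperimentConfig):
        config.validate_against(model)
        self.model = model
        self.config = config
        names = model.node_names
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        nodes = model.nodes

        rules = dict(model.rules)
        for name, text in config.rule_overrides.items():
            rules[name] = R.parse_rule(text, names)

        self.initial = [float(n.initial_level) for n in nodes]
        for sig, lv in config.signal_levels.items():
            self.initial[self.index[sig]] = float(lv)
        clamped = set(config.clamps)
        for name, lv in config.clamps.items():
            self.initial[self.index[name]] = float(lv)

        # schedule change points resolved to per-step signal values
        self.signal_steps: list[tuple[int, float]] = []  # (node_idx, level) per step
        self.schedule: list[list[tuple[int, float]]] = []
        for t in range(config.n_steps + 1):
            updates = []
            for sig, points in config.signal_schedule.items():
                eligible = [s for s in points if s <= t]
                if eligible:
                    updates.append((self.index[sig], float(points[max(eligible)])))
            self.schedule.append(updates)
        for i, lv in self.schedule[0]:
            self.initial[i] = lv

        output = model.output.name
        self.output_idx = self.index[output] if output not in clamped else None
        self.update_order_pool = [
            self.index[n.name] for n in nodes
            if n.role == "internal" and n.name not in clamped
        ]
        self.fns: list = [None] * len(names)
        self.delays = [0] * len(names)
        for name, expr in rules.items():
            i = self.index[name]
            node = model.node(name)
            if name in clamped or node.role == "signal":
                continue
            self.fns[i] = R.compile_rule(expr, self.index,
                                         float(node.min_level), float(node.max_level))
            self.delays[i] = int(node.delay_steps)


def _run_one(plan: _SimPlan, rng: np.random.Generator) -> np.ndarray:
    n_steps = plan.config.n_steps
    n_nodes = len(plan.names)
    traj = np.empty((n_steps + 1, n_nodes))
    state = list(plan.initial)
    traj[0] = state
    history = [list(state)]  # completed states, history[t] = state after step t
    fns = plan.fns
    delays = plan.delays
    pool = plan.update_order_pool
    out = plan.output_idx
    for t in range(1, n_steps + 1):
        for i, lv in plan.schedule[t] if t < len(plan.schedule) else []:
            state[i] = lv
        order = rng.permutation(len(pool))
        for k in order:
            i = pool[k]
            d = delays[i]
            if d:
                # regulators as recorded d steps before the current one
                state[i] = fns[i](history[max(0, t - d)])
            else:
                state[i] = fns[i](state)
        if out is not None:
            state[out] = fns[out](state)
        traj[t] = state
        history.append(list(state))
    return traj


def run_replicate(model: ModelSpec, config: ExperimentConfig,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Simulate a single replicate; returns (n_steps+1, n_nodes) levels."""
    plan = _SimPlan(model, config)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    return _run_one(plan, rng)


def run_ensemble(model: ModelSpec, config: ExperimentConfig) -> EnsembleResult:
    """Simulate ``config.n_replicates`` independent replicates.

    Replicate ``k`` uses the ``k``-th spawned child of
    ``SeedSequence(config.seed)``, so the ensemble is reproducible and
    independent of evaluation order.
    """
    plan = _SimPlan(model, config)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_replicates)
    levels = np.empty((config.n_replicates, config.n_steps + 1, len(plan.names)))
    for k, child in enumerate(children):
        levels[k] = _run_one(plan, np.random.default_rng(child))
    return EnsembleResult(levels=levels, node_names=list(plan.names),
                          config=config, model_name=model.name)


def summarize(ensemble: EnsembleResult, node: str) -> SummaryStats:
    """Maximum steady-state mean level and attainment times for a node."""
    if node not in ensemble._index:
        raise KeyError(f"unknown node {node!r}")
    levels = ensemble.node_levels(node)
    mean = levels.mean(axis=0)
    max_level = float(mean.max())
    if max_level == 0:
        return SummaryStats(0.0, 0, 0)

    def first_step(level_frac: float, rep_frac: float) -> int:
        threshold = level_frac * max_level
        attained = (levels >= threshold).mean(axis=0) >= rep_frac
        hits = np.nonzero(attained)[0]
        return int(hits[0]) if hits.size else 0

    return SummaryStats(max_level, first_step(0.5, 0.5), first_step(0.95, 0.95))


def run_pulse_protocol(model: ModelSpec, schedule: Mapping[str, Mapping[int, float]],
                       n_steps: int = 30, n_replicates: int = 2000,
                       seed: int = 0) -> EnsembleResult:
    """Ensemble under a stepwise signal schedule (light-pulse protocols)."""
    config = ExperimentConfig(
        n_steps=n_steps, n_replicates=n_replicates, seed=seed,
        signal_schedule={k: dict(v) for k, v in schedule.items()})
    return run_ensemble(model, config)


# ---------------------------------------------------------------------------
# Synchronous update (test oracle only; not a production mode)
# ---------------------------------------------------------------------------

def synchronous_step(model: ModelSpec, state: Mapping[str, float]) -> dict[str, float]:
    """One parallel-update step: every rule reads the same pre-state."""
    out = dict(state)
    for name, expr in model.rules.items():
        node = model.node(name)
        out[name] = R.evaluate(expr, state, node.min_level, node.max_level)
    return out
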