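"""Canonical and synthetic test models.

``guard_cell_model()`` loads the packaged synthetic guard-cell network
(see ``data/guard_cell_synthetic.yaml``).  ``build_model`` assembles a
valid :class:`ModelSpec` from rule strings, deriving the edge list from
the rules so rule/edge consistency holds by construction — handy for toy
models and randomized property tests.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from . import rules as R
from .model import EdgeSpec, ModelSpec, NodeSpec, load_model

__all__ = ["guard_cell_model", "build_model", "toy_models", "random_model"]

_DATA_FILE = "guard_cell_synthetic.yaml"


def guard_cell_model() -> ModelSpec:
    """The packaged synthetic guard-cell stomatal-opening model."""
    with resources.as_file(resources.files("stomasim.data") / _DATA_FILE) as p:
        return load_model(p)


def build_model(nodes: Sequence[NodeSpec], rules: Mapping[str, str],
                name: str = "model",
                edge_signs: Mapping[tuple[str, str], str] | None = None) -> ModelSpec:
    """Assemble a model, deriving edges from the rules' referenced nodes.

    A reference that appears (anywhere) under a ``Not`` gets a negative
    edge unless overridden via ``edge_signs``.
    """
    names = [n.name for n in nodes]
    parsed = {k: R.parse_rule(v, names) for k, v in rules.items()}
    edges: list[EdgeSpec] = []
    for target, expr in parsed.items():
        negated = _negated_refs(expr)
        for src in sorted(R.referenced_nodes(expr)):
            sign = (edge_signs or {}).get((src, target))
            if sign is None:
                sign = "-" if src in negated else "+"
            edges.append(EdgeSpec(src, target, sign))
    model = ModelSpec(nodes=list(nodes), edges=edges, rules=parsed, name=name)
    model.validate()
    return model


def _negated_refs(expr: R.RuleExpr, under_not: bool = False) -> frozenset[str]:
    if isinstance(expr, R.Ref):
        return frozenset({expr.name}) if under_not else frozenset()
    if isinstance(expr, R.Cmp):
        return frozenset({expr.ref.name}) if under_not else frozenset()
    if isinstance(expr, R.NotOp):
        return _negated_refs(expr.operand, not under_not)
    if isinstance(expr, (R.AndOp, R.OrOp)):
        out: frozenset[str] = frozenset()
        for p in expr.operands:
            out |= _negated_refs(p, under_not)
        return out
    if isinstance(expr, R.BinOp):
        return _negated_refs(expr.left, under_not) | _negated_refs(expr.right, under_not)
    return frozenset()


def _n(name: str, max_level: float = 1, initial: float = 0,
       role: str = "internal", delay: int = 0, min_level: float = 0) -> NodeSpec:
    return NodeSpec(name=name, min_level=min_level, max_level=max_level,
                    initial_level=initial, role=role, delay_steps=delay)


def toy_models() -> dict[str, ModelSpec]:
    """Small models with analytically known behavior.

    - ``chain``: S -> A -> B -> C(out); with the source on, every node
      reaches 1 within three steps under any update order.
    - ``cycle3``: a 3-node positive feedback loop (one SCC of size 3).
      Synchronous update rotates the activity pattern forever; random
      order asynchronous update absorbs into the all-ON or all-OFF
      fixed point.
    - ``oscillator``: two nodes inhibiting each other with both ON
      initially; random order resolves the conflict to one of the two
      fixed points (A on / B on) with equal probability by symmetry.
    - ``multilevel``: a counter node driven up/down through comparison
      clauses by a binary switch, exercising arithmetic + logic mixing.
    """
    chain = build_model(
        [_n("S", role="signal"), _n("A"), _n("B"), _n("C", role="output")],
        {"A": "S", "B": "A", "C": "B"}, name="chain")
    cycle3 = build_model(
        [_n("A", initial=1), _n("B"), _n("C", role="output")],
        {"A": "C", "B": "A", "C": "B"}, name="cycle3")
    oscillator = build_model(
        [_n("A", initial=1), _n("B", initial=1), _n("O", role="output")],
        {"A": "Not B", "B": "Not A", "O": "A And Not B"}, name="oscillator")
    multilevel = build_model(
        [_n("S", role="signal"), _n("X", max_level=3),
         _n("hi"), _n("O", role="output")],
        {"X": "X + S - (Not S)", "hi": "X >= 2", "O": "hi And (X = 3)"},
        name="multilevel")
    return {"chain": chain, "cycle3": cycle3,
            "oscillator": oscillator, "multilevel": multilevel}


def random_model(n_nodes: int, edge_density: float = 0.3, max_level: int = 2,
                 seed: int = 0) -> ModelSpec:
    """Random valid model for property-based tests.

    Node 0 is a signal, the last node the output; each other node gets
    1..k random regulators (k set by ``edge_density``) combined by a
    randomly chosen rule template.  The same seed yields the same model.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    max_regs = max(1, min(n_nodes - 1, int(round(edge_density * n_nodes))))
    names = [f"n{i}" for i in range(n_nodes)]
    nodes = []
    for i, name in enumerate(names):
        role = "signal" if i == 0 else ("output" if i == n_nodes - 1 else "internal")
        lv = int(rng.integers(1, max_level + 1))
        init = int(rng.integers(0, lv + 1)) if role != "signal" else 0
        nodes.append(NodeSpec(name=name, min_level=0, max_level=lv,
                              initial_level=init, role=role))
    rules: dict[str, str] = {}
    for i, name in enumerate(names):
        if i == 0:
            continue
        k = int(rng.integers(1, max_regs + 1))
        regs = list(rng.choice(names[:-1], size=min(k, n_nodes - 1), replace=False))
        rules[name] = _random_rule(regs, nodes, rng)
    return build_model(nodes, rules, name=f"random_{n_nodes}_{seed}")


def _random_rule(regs: list[str], nodes: list[NodeSpec],
                 rng: np.random.Generator) -> str:
    levels = {n.name: int(n.max_level) for n in nodes}

    def clause(reg: str) -> str:
        choice = rng.integers(0, 4)
        if choice == 0:
            return reg
        if choice == 1:
            return f"Not {reg}"
        if choice == 2:
            return f"({reg} >= {int(rng.integers(1, levels[reg] + 1))})"
        return f"({reg} = {int(rng.integers(0, levels[reg] + 1))})"

    template = rng.integers(0, 3)
    parts = [clause(r) for r in regs]
    if template == 0:
        return " And ".join(parts)
    if template == 1:
        return " Or ".join(parts)
    return " + ".join(parts)
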