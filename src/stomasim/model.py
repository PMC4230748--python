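"""Domain types and model file I/O.

A :class:`ModelSpec` is a complete declarative description of a
multi-level discrete dynamic model: nodes with level ranges and initial
states, signed directed edges (including edge-on-edge regulations), one
update rule per internal/output node, and per-node update delays.

Models are stored as YAML with three sections (``nodes``, ``edges``,
``rules``); rules are kept as plain strings in the modeling notation so a
stored model can be audited line by line.  An edge whose target is itself
an edge (a regulation of a transport or conversion process, e.g. an
anion channel gating malate export) is recorded faithfully; for graph
work it is projected onto a single edge from the modulator to the
modulated edge's target node, flagged with a ``modulates_edge``
attribute.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import yaml

from . import rules as R

__all__ = [
    "NodeSpec", "EdgeRef", "EdgeSpec", "ModelSpec", "ModelValidationError",
    "load_model", "save_model", "export_graph",
]

ROLES = ("signal", "internal", "output")
KINDS = ("integer", "numeric")


class ModelValidationError(ValueError):
    """Raised on load/validation; lists every failure at once."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        lines = "\n  - ".join(self.failures)
        super().__init__(f"model validation failed:\n  - {lines}")


@dataclass(frozen=True)
class NodeSpec:
    """One component of the model.

    ``kind='integer'`` nodes hold integer levels within
    ``[min_level, max_level]``; ``kind='numeric'`` nodes (such as a
    weighted output readout) take whatever values their rule arithmetic
    produces within the range.  ``delay_steps`` makes the node's rule
    read its regulators' levels from that many steps earlier.
    """

    name: str
    min_level: float = 0
    max_level: float = 1
    kind: str = "integer"
    initial_level: float = 0
    role: str = "internal"
    delay_steps: int = 0
    display: str | None = None


@dataclass(frozen=True)
class EdgeRef:
    """Identifies an edge by its endpoints (for edge-on-edge regulation)."""

    source: str
    target: str


@dataclass(frozen=True)
class EdgeSpec:
    """Signed directed interaction.

    ``target`` is a node name, or an :class:`EdgeRef` when the
    interaction modulates another edge rather than a node.
    """

    source: str
    target: str | EdgeRef
    sign: str  # '+' or '-'

    @property
    def modulates_edge(self) -> bool:
        return isinstance(self.target, EdgeRef)

    @property
    def effective_target(self) -> str:
        """Node the edge acts on after projection."""
        return self.target.target if isinstance(self.target, EdgeRef) else self.target


@dataclass
class ModelSpec:
    """Nodes + edges + rules; the single source of truth for a model."""

    nodes: list[NodeSpec]
    edges: list[EdgeSpec]
    rules: dict[str, R.RuleExpr]
    name: str = "model"
    description: str = ""
    metadata: dict = field(default_factory=dict)

    # -- basic accessors ---------------------------------------------------

    def node(self, name: str) -> NodeSpec:
        return self._by_name[name]

    @property
    def _by_name(self) -> dict[str, NodeSpec]:
        return {n.name: n for n in self.nodes}

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def signals(self) -> list[NodeSpec]:
        return [n for n in self.nodes if n.role == "signal"]

    @property
    def internals(self) -> list[NodeSpec]:
        return [n for n in self.nodes if n.role == "internal"]

    @property
    def output(self) -> NodeSpec:
        outs = [n for n in self.nodes if n.role == "output"]
        if len(outs) != 1:
            raise ModelValidationError([f"expected exactly 1 output node, found {len(outs)}"])
        return outs[0]

    def initial_state(self) -> dict[str, float]:
        return {n.name: n.initial_level for n in self.nodes}

    def rule_text(self, name: str) -> str:
        return R.unparse(self.rules[name])

    # -- graph projection --------------------------------------------------

    def graph(self, multigraph: bool = False) -> nx.DiGraph:
        """Directed graph with edge-on-edge regulations projected.

        A modulator edge ``A -> (B -> C)`` becomes ``A -> C`` carrying
        ``modulates_edge=True``.  With ``multigraph=True`` parallel edges
        are preserved (used for degree counts).
        """
        g: nx.DiGraph = nx.MultiDiGraph() if multigraph else nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.name, role=n.role, min_level=n.min_level,
                       max_level=n.max_level, kind=n.kind)
        for e in self.edges:
            g.add_edge(e.source, e.effective_target, sign=e.sign,
                       modulates_edge=e.modulates_edge)
        return g

    def in_neighbors(self, name: str) -> frozenset[str]:
        return frozenset(e.source for e in self.edges if e.effective_target == name)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise listing all failures."""
        fail: list[str] = []
        names = [n.name for n in self.nodes]
        declared = set(names)
        if len(names) != len(declared):
            dupes = sorted({n for n in names if names.count(n) > 1})
            fail.append(f"duplicate node names: {dupes}")
        outputs = [n for n in self.nodes if n.role == "output"]
        if len(outputs) != 1:
            fail.append(f"expected exactly 1 output node, found {len(outputs)}")
        for n in self.nodes:
            if n.role not in ROLES:
                fail.append(f"{n.name}: unknown role {n.role!r}")
            if n.kind not in KINDS:
                fail.append(f"{n.name}: unknown kind {n.kind!r}")
            if not (n.min_level <= n.initial_level <= n.max_level):
                fail.append(f"{n.name}: initial level {n.initial_level} outside "
                            f"[{n.min_level}, {n.max_level}]")
            if n.delay_steps < 0:
                fail.append(f"{n.name}: negative delay")
            if n.kind == "integer" and float(n.initial_level) != int(n.initial_level):
                fail.append(f"{n.name}: integer node with non-integer initial level")
        for e in self.edges:
            if e.source not in declared:
                fail.append(f"edge source {e.source!r} is not a declared node")
            if isinstance(e.target, EdgeRef):
                pair = (e.target.source, e.target.target)
                if not any(x.source == pair[0] and x.target == pair[1]
                           for x in self.edges if not x.modulates_edge):
                    fail.append(f"edge-on-edge target {pair[0]}->{pair[1]} does not "
                                f"resolve to a declared edge")
            elif e.target not in declared:
                fail.append(f"edge target {e.target!r} is not a declared node")
            if e.sign not in ("+", "-"):
                fail.append(f"edge {e.source}->{e.effective_target}: bad sign {e.sign!r}")
        for n in self.nodes:
            if n.role == "signal" and n.name in self.rules:
                fail.append(f"signal node {n.name} must not have an update rule")
            if n.role in ("internal", "output") and n.name not in self.rules:
                fail.append(f"{n.role} node {n.name} lacks an update rule")
        for target, expr in self.rules.items():
            if target not in declared:
                fail.append(f"rule given for undeclared node {target!r}")
                continue
            refs = R.referenced_nodes(expr)
            undeclared = refs - declared
            for u in sorted(undeclared):
                fail.append(f"rule for {target}: undeclared node {u!r}")
            inn = self.in_neighbors(target)
            missing_edges = (refs & declared) - inn
            for m in sorted(missing_edges):
                fail.append(f"rule for {target} references {m} but no edge "
                            f"{m}->{target} is declared")
            unused = inn - refs
            for m in sorted(unused):
                fail.append(f"edge {m}->{target} has no corresponding reference "
                            f"in the rule for {target}")
        if fail:
            raise ModelValidationError(fail)

    # -- misc ---------------------------------------------------------------

    def with_rule(self, node: str, rule_text: str,
                  extra_edges: list[EdgeSpec] | None = None) -> "ModelSpec":
        """Copy of the model with one rule replaced (and edges added)."""
        new_rules = dict(self.rules)
        new_rules[node] = R.parse_rule(rule_text, self.node_names)
        out = ModelSpec(nodes=list(self.nodes),
                        edges=list(self.edges) + list(extra_edges or []),
                        rules=new_rules, name=self.name,
                        description=self.description,
                        metadata=dict(self.metadata))
        out.validate()
        return out

    def with_initial(self, node: str, level: float) -> "ModelSpec":
        nodes = [replace(n, initial_level=level) if n.name == node else n
                 for n in self.nodes]
        return ModelSpec(nodes=nodes, edges=list(self.edges),
                         rules=dict(self.rules), name=self.name,
                         description=self.description, metadata=dict(self.metadata))

    def content_hash(self) -> str:
        """Stable digest of the model definition (used in run manifests)."""
        return hashlib.sha256(
            yaml.safe_dump(_to_dict(self), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

def _num(v: float) -> float | int:
    return int(v) if float(v).is_integer() else float(v)


def _to_dict(model: ModelSpec) -> dict:
    nodes = []
    for n in model.nodes:
        d: dict = {"name": n.name, "role": n.role,
                   "levels": {"min": _num(n.min_level), "max": _num(n.max_level)},
                   "kind": n.kind, "initial": _num(n.initial_level)}
        if n.delay_steps:
            d["delay"] = n.delay_steps
        if n.display:
            d["display"] = n.display
        nodes.append(d)
    edges = []
    for e in model.edges:
        d = {"source": e.source, "sign": e.sign}
        if isinstance(e.target, EdgeRef):
            d["target_edge"] = {"source": e.target.source, "target": e.target.target}
        else:
            d["target"] = e.target
        edges.append(d)
    out = {"name": model.name, "description": model.description,
           "nodes": nodes, "edges": edges,
           "rules": {k: R.unparse(v) for k, v in sorted(model.rules.items())}}
    if model.metadata:
        out["metadata"] = model.metadata
    return out


def _from_dict(data: dict) -> ModelSpec:
    nodes = []
    for d in data.get("nodes", []):
        levels = d.get("levels", {})
        nodes.append(NodeSpec(
            name=d["name"],
            min_level=levels.get("min", 0),
            max_level=levels.get("max", 1),
            kind=d.get("kind", "integer"),
            initial_level=d.get("initial", 0),
            role=d.get("role", "internal"),
            delay_steps=d.get("delay", 0),
            display=d.get("display"),
        ))
    edges = []
    for d in data.get("edges", []):
        if "target_edge" in d:
            target: str | EdgeRef = EdgeRef(d["target_edge"]["source"],
                                            d["target_edge"]["target"])
        else:
            target = d["target"]
        edges.append(EdgeSpec(source=d["source"], target=target, sign=d["sign"]))
    declared = [n.name for n in nodes]
    parsed: dict[str, R.RuleExpr] = {}
    failures: list[str] = []
    for name, text in (data.get("rules") or {}).items():
        try:
            parsed[name] = R.parse_rule(str(text), declared)
        except (R.RuleSyntaxError, R.UndeclaredNodeError) as exc:
            failures.append(f"rule for {name}: {exc}")
    if failures:
        raise ModelValidationError(failures)
    return ModelSpec(nodes=nodes, edges=edges, rules=parsed,
                     name=data.get("name", "model"),
                     description=data.get("description", ""),
                     metadata=data.get("metadata", {}) or {})


def save_model(model: ModelSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(model), sort_keys=False,
                                         allow_unicode=True, width=100))


def load_model(path: str | Path, validate: bool = True) -> ModelSpec:
    """Load a model definition file; all invariants are checked on load."""
    data = yaml.safe_load(Path(path).read_text())
    model = _from_dict(data)
    if validate:
        model.validate()
    return model


def loads_model(text: str, validate: bool = True) -> ModelSpec:
    model = _from_dict(yaml.safe_load(text))
    if validate:
        model.validate()
    return model


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

def export_graph(model: ModelSpec, path: str | Path, format: str = "graphml") -> None:
    """Write the projected network as GraphML or SIF.

    SIF lines read ``source <relation> target`` with relation
    ``positive``/``negative``, suffixed ``-edge-mod`` for projected
    edge-on-edge regulations.
    """
    fmt = format.lower()
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(model.graph(), path)
    elif fmt == "sif":
        lines = []
        for e in model.edges:
            rel = "positive" if e.sign == "+" else "negative"
            if e.modulates_edge:
                rel += "-edge-mod"
            lines.append(f"{e.source}\t{rel}\t{e.effective_target}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unsupported graph format {format!r} (use graphml or sif)")
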