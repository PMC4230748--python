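"""Structural analysis of the signed directed network.

Degrees, strongly connected components (SCCs), the impact of single-edge
removal on SCC integrity, and exact simple-path enumeration between the
signal nodes and the output.  All operations work on the projected
directed graph of a :class:`~stomasim.model.ModelSpec` (edge-on-edge
regulations counted as one edge from the modulator to the modulated
edge's target node; parallel edges counted separately for degrees).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import networkx as nx
import pandas as pd

from .model import ModelSpec

__all__ = [
    "DegreeRecord", "SCCReport", "degree_table", "top_decile",
    "strongly_connected_components", "edge_removal_impact",
    "count_simple_paths", "bypass_paths", "PathCountOverflow",
]


@dataclass(frozen=True)
class DegreeRecord:
    node: str
    in_degree: int
    out_degree: int

    @property
    def total_degree(self) -> int:
        return self.in_degree + self.out_degree


@dataclass
class SCCReport:
    """Non-trivial SCCs plus the up/down-stream structure of the largest.

    ``components`` holds node sets of size >= 2, sorted by size
    descending.  ``upstream`` are nodes outside SCC1 that reach it,
    ``downstream`` nodes reachable from it, ``isolated`` nodes connected
    to SCC1 by no directed path in either direction.
    """

    components: list[frozenset[str]]
    upstream: frozenset[str]
    downstream: frozenset[str]
    isolated: frozenset[str]

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


def _graph(model_or_graph) -> nx.DiGraph:
    if isinstance(model_or_graph, ModelSpec):
        return model_or_graph.graph()
    return model_or_graph


def degree_table(model: ModelSpec) -> pd.DataFrame:
    """In/out/total degree of every node, sorted by total degree.

    Computed on the multigraph projection so parallel edges count
    separately.
    """
    g = model.graph(multigraph=True)
    records = [DegreeRecord(n, g.in_degree(n), g.out_degree(n)) for n in g.nodes]
    df = pd.DataFrame(
        {"node": [r.node for r in records],
         "in_degree": [r.in_degree for r in records],
         "out_degree": [r.out_degree for r in records],
         "total_degree": [r.total_degree for r in records]})
    return df.sort_values(["total_degree", "node"],
                          ascending=[False, True]).reset_index(drop=True)


def top_decile(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Top 10% of nodes by a degree metric, ties at the cutoff included."""
    k = max(1, round(len(table) / 10))
    ranked = table.sort_values([metric, "node"], ascending=[False, True])
    cutoff = ranked[metric].iloc[k - 1]
    return ranked[ranked[metric] >= cutoff].reset_index(drop=True)


def strongly_connected_components(model_or_graph) -> SCCReport:
    """Tarjan-based SCC decomposition; singletons excluded from the report."""
    g = _graph(model_or_graph)
    comps = sorted((frozenset(c) for c in nx.strongly_connected_components(g)
                    if len(c) >= 2), key=len, reverse=True)
    if not comps:
        return SCCReport([], frozenset(), frozenset(), frozenset())
    scc1 = comps[0]
    anchor = next(iter(scc1))
    reachable_from = set(nx.descendants(g, anchor)) | scc1
    reaching = set(nx.ancestors(g, anchor)) | scc1
    upstream = frozenset(reaching - scc1)
    downstream = frozenset(reachable_from - scc1)
    isolated = frozenset(set(g.nodes) - scc1 - upstream - downstream)
    return SCCReport(comps, upstream, downstream, isolated)


def edge_removal_impact(model_or_graph, scc: Iterable[str]) -> pd.DataFrame:
    """Node loss from an SCC caused by each of its internal edges.

    For every edge with both endpoints in ``scc``, the loss is the SCC
    size minus the size of the largest strongly connected component that
    the SCC's nodes form once the edge is removed.  Sorted descending.
    """
    g = _graph(model_or_graph)
    scc = frozenset(scc)
    sub = g.subgraph(scc).copy()
    rows = []
    for u, v in list(sub.edges):
        sub.remove_edge(u, v)
        largest = max((len(c) for c in nx.strongly_connected_components(sub)),
                      default=0)
        rows.append({"source": u, "target": v, "node_loss": len(scc) - largest})
        sub.add_edge(u, v)
    return (pd.DataFrame(rows, columns=["source", "target", "node_loss"])
            .sort_values(["node_loss", "source", "target"],
                         ascending=[False, True, True])
            .reset_index(drop=True))


class PathCountOverflow(RuntimeError):
    """Raised when simple-path enumeration exceeds the configured cap."""


def count_simple_paths(model_or_graph, sources: Iterable[str], target: str,
                       cap: int = 50_000_000) -> int:
    """Exact number of directed simple paths from any source to the target.

    Exhaustive depth-first backtracking that counts without storing
    paths, summed over sources.  ``cap`` bounds the count as a guard
    against pathological inputs.
    """
    g = _graph(model_or_graph)
    succ = {n: sorted(g.successors(n)) for n in g.nodes}
    on_path: set[str] = set()
    count = 0

    def dfs(node: str) -> None:
        nonlocal count
        if node == target:
            count += 1
            if count > cap:
                raise PathCountOverflow(f"more than {cap} simple paths")
            return
        on_path.add(node)
        for nxt in succ[node]:
            if nxt not in on_path:
                dfs(nxt)
        on_path.discard(node)

    for src in sources:
        if src in succ:
            dfs(src)
    return count


def bypass_paths(model_or_graph, sources: Iterable[str], target: str,
                 avoid: Iterable[str] = ()) -> list[list[str]]:
    """All simple source->target paths avoiding every node in ``avoid``."""
    g = _graph(model_or_graph).copy()
    g.remove_nodes_from(set(avoid) - {target} - set(sources))
    paths: list[list[str]] = []
    for src in sources:
        if src in g and target in g:
            paths.extend(nx.all_simple_paths(g, src, target))
    return sorted(paths)


def simple_paths_iter(model_or_graph, sources: Iterable[str],
                      target: str) -> Iterator[list[str]]:
    g = _graph(model_or_graph)
    for src in sources:
        if src in g:
            yield from nx.all_simple_paths(g, src, target)
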