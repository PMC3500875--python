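"""Local-independence graphs and the delta-separation criterion.

A local-independence graph is a directed graph over named stochastic
processes: an arrow l -> k means process k is conditionally locally
dependent on process l, i.e. k's local characteristic (drift or intensity
given the full past) genuinely involves l's history.  Unlike causal DAGs
these graphs may contain cycles — mutual (feedback) dependence between two
processes is perfectly meaningful — but never self-loops, since dependence
of a process on its own past is taken for granted rather than drawn.

Whether "A does not influence B given C" can be read off such a graph is
decided by delta-separation:

1. restrict to the ancestral subgraph generated by A, B and C
   (reachability-based, so the step is well defined with cycles);
2. delete every directed edge starting in B;
3. moralize (join co-parents, drop directions);
4. ask whether C separates A from B in the resulting undirected graph.

The criterion is deliberately asymmetric in (A, B): influence flows with
time, and deleting B's outgoing edges encodes that we are asking about
influence *into* B.

An exhaustive simple-path enumerator (:func:`separation_oracle`) is kept as
an independent reference for the separation step on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import NodeLookupError, SizeGuardError, ValidationError

__all__ = [
    "LocalIndependenceGraph",
    "UndirectedGraph",
    "ancestral_subgraph",
    "moralize",
    "delta_separated",
    "separation_oracle",
]


@dataclass(frozen=True)
class LocalIndependenceGraph:
    """Directed graph over named processes; cycles allowed, no self-loops.

    Parameters
    ----------
    nodes:
        Unique process names, order preserved for deterministic output.
    edges:
        ``(from, to)`` pairs meaning *to* is locally dependent on *from*.
        Duplicates are collapsed; self-loops are rejected.
    roles:
        Optional documentation-only mapping node -> role
        (treatment / mediator / outcome / censoring / unobserved).
        Roles never alter any algorithm.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    roles: Mapping[str, str] = field(default_factory=dict)

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
        roles: Mapping[str, str] | None = None,
    ) -> None:
        nodes = tuple(str(n) for n in nodes)
        if len(set(nodes)) != len(nodes):
            raise ValidationError("node names must be unique")
        node_set = set(nodes)
        seen: set[tuple[str, str]] = set()
        clean: list[tuple[str, str]] = []
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValidationError(f"self-loop on node {u!r} is not allowed")
            if u not in node_set or v not in node_set:
                raise ValidationError(f"edge ({u!r}, {v!r}) references unknown node")
            if (u, v) not in seen:
                seen.add((u, v))
                clean.append((u, v))
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", tuple(clean))
        object.__setattr__(self, "roles", dict(roles or {}))

    # -- accessors ---------------------------------------------------------

    def parents(self, node: str) -> set[str]:
        self._require(node)
        return {u for u, v in self.edges if v == node}

    def children(self, node: str) -> set[str]:
        self._require(node)
        return {v for u, v in self.edges if u == node}

    def _require(self, node: str) -> None:
        if node not in self.nodes:
            raise NodeLookupError(f"unknown node {node!r}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    # -- JSON schema shared with sdeflow -----------------------------------

    def to_json_dict(self) -> dict:
        return {
            "schema": "dynpath-graph/1",
            "nodes": [
                {"name": n, **({"role": self.roles[n]} if n in self.roles else {})}
                for n in self.nodes
            ],
            "edges": [{"from": u, "to": v} for u, v in self.edges],
        }

    @classmethod
    def from_json_dict(cls, obj: Mapping) -> "LocalIndependenceGraph":
        try:
            raw_nodes = obj["nodes"]
            raw_edges = obj.get("edges", [])
        except (TypeError, KeyError) as exc:
            raise ValidationError(f"malformed graph JSON: {exc}") from exc
        names, roles = [], {}
        for n in raw_nodes:
            if isinstance(n, str):
                names.append(n)
            else:
                names.append(n["name"])
                if "role" in n:
                    roles[n["name"]] = n["role"]
        edges = [(e["from"], e["to"]) for e in raw_edges]
        return cls(names, edges, roles)


@dataclass(frozen=True)
class UndirectedGraph:
    """Simple undirected graph (symmetric adjacency, no self-loops)."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        nodes = tuple(str(n) for n in nodes)
        if len(set(nodes)) != len(nodes):
            raise ValidationError("node names must be unique")
        node_set = set(nodes)
        clean = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValidationError(f"self-loop on node {u!r} is not allowed")
            if u not in node_set or v not in node_set:
                raise ValidationError(f"edge ({u!r}, {v!r}) references unknown node")
            clean.add(frozenset((u, v)))
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", frozenset(clean))

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges

    def edge_list(self) -> list[tuple[str, str]]:
        """Deterministically ordered edge list (sorted endpoints)."""
        return sorted(tuple(sorted(e)) for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _as_node_set(g: LocalIndependenceGraph, nodes: Iterable[str], what: str) -> set[str]:
    out = {str(n) for n in nodes}
    unknown = out - set(g.nodes)
    if unknown:
        raise NodeLookupError(f"unknown node(s) in {what}: {sorted(unknown)}")
    return out


def ancestral_subgraph(
    g: LocalIndependenceGraph, keep: Iterable[str]
) -> LocalIndependenceGraph:
    """Induced subgraph on ``keep`` plus all its ancestors.

    An ancestor is any node with a directed path into ``keep``; in cyclic
    graphs this is plain reachability, so every node on a cycle feeding
    ``keep`` is retained.
    """
    keep = _as_node_set(g, keep, "keep")
    dg = g.to_networkx()
    closure = set(keep)
    for n in keep:
        closure |= nx.ancestors(dg, n)
    nodes = tuple(n for n in g.nodes if n in closure)
    edges = tuple((u, v) for u, v in g.edges if u in closure and v in closure)
    roles = {n: r for n, r in g.roles.items() if n in closure}
    return LocalIndependenceGraph(nodes, edges, roles)


def moralize(g: LocalIndependenceGraph) -> UndirectedGraph:
    """Moral graph: undirected skeleton plus marriages of co-parents.

    Every pair of distinct parents sharing a child is joined, then all
    directions are dropped.
    """
    edges: set[tuple[str, str]] = {(u, v) for u, v in g.edges}
    for child in g.nodes:
        parents = sorted(g.parents(child))
        for i, p in enumerate(parents):
            for q in parents[i + 1 :]:
                edges.add((p, q))
    return UndirectedGraph(g.nodes, edges)


def _validate_abc(
    g: LocalIndependenceGraph,
    a: Iterable[str],
    b: Iterable[str],
    c: Iterable[str],
) -> tuple[set[str], set[str], set[str]]:
    sa = _as_node_set(g, a, "A")
    sb = _as_node_set(g, b, "B")
    sc = _as_node_set(g, c, "C")
    if not sa or not sb:
        raise ValidationError("A and B must be nonempty")
    if sa & sb or sa & sc or sb & sc:
        raise ValidationError("A, B and C must be pairwise disjoint")
    return sa, sb, sc


def _undirected_separated(
    ug: UndirectedGraph, a: set[str], b: set[str], c: set[str]
) -> bool:
    """Does every path from ``a`` to ``b`` intersect ``c``? (BFS from a.)"""
    adj: dict[str, set[str]] = {n: set() for n in ug.nodes}
    for e in ug.edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    frontier = list(a - c)
    seen = set(frontier)
    while frontier:
        u = frontier.pop()
        if u in b:
            return False
        for v in adj[u]:
            if v not in seen and v not in c:
                seen.add(v)
                frontier.append(v)
    return True


def delta_separated(
    g: LocalIndependenceGraph,
    a: Iterable[str],
    b: Iterable[str],
    c: Iterable[str] = (),
) -> bool:
    """Test whether C delta-separates A from B in a local-independence graph.

    Pipeline: ancestral restriction to A∪B∪C, deletion of directed edges out
    of B, moralization, then undirected separation of A from B by C.  The
    verdict is asymmetric in (A, B): it asks whether influence *from* A
    *into* B is blocked.
    """
    sa, sb, sc = _validate_abc(g, a, b, c)
    anc = ancestral_subgraph(g, sa | sb | sc)
    pruned_edges = tuple((u, v) for u, v in anc.edges if u not in sb)
    pruned = LocalIndependenceGraph(anc.nodes, pruned_edges, anc.roles)
    moral = moralize(pruned)
    return _undirected_separated(moral, sa, sb, sc)


def separation_oracle(
    ug: UndirectedGraph,
    a: Iterable[str],
    b: Iterable[str],
    c: Iterable[str] = (),
    max_nodes: int = 10,
) -> bool:
    """Exhaustive reference check of undirected separation on small graphs.

    Enumerates every simple path between A and B and reports whether each
    one intersects C.  Exponential; guarded at ``max_nodes`` nodes.
    """
    if len(ug.nodes) > max_nodes:
        raise SizeGuardError(
            f"separation_oracle is exhaustive; refusing {len(ug.nodes)} > "
            f"{max_nodes} nodes"
        )
    sa = {str(n) for n in a}
    sb = {str(n) for n in b}
    sc = {str(n) for n in c}
    unknown = (sa | sb | sc) - set(ug.nodes)
    if unknown:
        raise NodeLookupError(f"unknown node(s): {sorted(unknown)}")
    if not sa or not sb:
        raise ValidationError("A and B must be nonempty")
    if sa & sb or sa & sc or sb & sc:
        raise ValidationError("A, B and C must be pairwise disjoint")
    g = ug.to_networkx()
    for s in sa:
        for t in sb:
            for path in nx.all_simple_paths(g, s, t):
                if not (set(path) & sc):
                    return False
    return True
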