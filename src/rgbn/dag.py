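"""Directed acyclic graphs over the study variables, with arc constraints.

A thin, deterministic wrapper around an edge set.  networkx supplies cycle
detection and topological sorting; everything else (constraint checking,
serialization order) is explicit so learner output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

Edge = tuple[str, str]


class CycleError(ValueError):
    """Raised when an operation would create or encounter a directed cycle."""


@dataclass
class Dag:
    """Directed acyclic graph: named nodes, (parent, child) edges.

    Child adjacency is maintained incrementally so cycle queries are a
    plain DFS — the score-based learners call them in their inner loop.
    """

    nodes: tuple[str, ...]
    edges: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self.edges = set(self.edges)
        node_set = set(self.nodes)
        self._children: dict[str, set[str]] = {n: set() for n in self.nodes}
        self._parents: dict[str, set[str]] = {n: set() for n in self.nodes}
        for p, c in self.edges:
            if p == c:
                raise ValueError(f"self-loop {p}->{c}")
            if p not in node_set or c not in node_set:
                raise ValueError(f"edge {p}->{c} references unknown node")
            self._children[p].add(c)
            self._parents[c].add(p)
        if not self.is_acyclic():
            raise CycleError("graph contains a directed cycle")

    # -- queries ----------------------------------------------------------
    def parents(self, node: str) -> list[str]:
        return sorted(self._parents[node])

    def children(self, node: str) -> list[str]:
        return sorted(self._children[node])

    def has_edge(self, parent: str, child: str) -> bool:
        return (parent, child) in self.edges

    def adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges

    def neighbours(self, node: str) -> set[str]:
        return self._children[node] | self._parents[node]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def _reaches(self, src: str, dst: str, skip: Edge | None = None) -> bool:
        stack, seen = [src], set()
        while stack:
            v = stack.pop()
            if v == dst:
                return True
            if v in seen:
                continue
            seen.add(v)
            for c in self._children[v]:
                if skip is not None and (v, c) == skip:
                    continue
                stack.append(c)
        return False

    def is_acyclic(self) -> bool:
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        queue = [n for n in self.nodes if indeg[n] == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for c in self._children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return seen == len(self.nodes)

    def creates_cycle(self, parent: str, child: str) -> bool:
        """Would adding parent->child close a directed cycle?"""
        if (parent, child) in self.edges:
            return False
        return self._reaches(child, parent)

    def reversal_creates_cycle(self, parent: str, child: str) -> bool:
        """Would reversing parent->child to child->parent close a cycle?"""
        return self._reaches(parent, child, skip=(parent, child))

    def topological_order(self) -> list[str]:
        """Deterministic topological sort (lexicographic tie-break)."""
        try:
            return list(nx.lexicographical_topological_sort(self.to_networkx()))
        except nx.NetworkXUnfeasible as exc:  # pragma: no cover - guarded
            raise CycleError("graph contains a directed cycle") from exc

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    # -- mutation ---------------------------------------------------------
    def copy(self) -> "Dag":
        return Dag(self.nodes, set(self.edges))

    def add_edge(self, parent: str, child: str) -> None:
        if parent == child:
            raise ValueError(f"self-loop {parent}->{child}")
        if self.creates_cycle(parent, child):
            raise CycleError(f"adding {parent}->{child} creates a cycle")
        self.edges.add((parent, child))
        self._children[parent].add(child)
        self._parents[child].add(parent)

    def remove_edge(self, parent: str, child: str) -> None:
        if (parent, child) in self.edges:
            self.edges.discard((parent, child))
            self._children[parent].discard(child)
            self._parents[child].discard(parent)

    def signature(self) -> frozenset[Edge]:
        """Hashable identity of the structure (used by tabu memory)."""
        return frozenset(self.edges)

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.sorted_edges())


@dataclass(frozen=True)
class ArcConstraints:
    """Prior-knowledge blacklist/whitelist over directed arcs."""

    forbidden: frozenset[Edge] = frozenset()
    required: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.forbidden & self.required
        if overlap:
            raise ValueError(f"arcs both required and forbidden: {sorted(overlap)}")
        nodes = {n for e in self.required for n in e}
        probe = Dag(tuple(sorted(nodes)))
        for p, c in sorted(self.required):
            probe.add_edge(p, c)  # raises CycleError if whitelist is cyclic

    def allows(self, parent: str, child: str) -> bool:
        return (parent, child) not in self.forbidden

    def requires(self, parent: str, child: str) -> bool:
        return (parent, child) in self.required

    @staticmethod
    def make(
        forbidden: Iterable[Edge] = (), required: Iterable[Edge] = ()
    ) -> "ArcConstraints":
        return ArcConstraints(frozenset(forbidden), frozenset(required))


def default_constraints(
    covariates: Iterable[str], responses: Iterable[str]
) -> ArcConstraints:
    """Prior-knowledge constraints for the body-composition networks.

    Anthropometry can drive body composition but not the reverse, and
    nothing causes age: all response->covariate arcs and all arcs into Age
    are forbidden.  Covariate-to-covariate arcs stay legal during learning
    (they are ignored when models are extracted).
    """
    cov = list(covariates)
    resp = list(responses)
    forbidden: set[Edge] = set()
    for r in resp:
        for c in cov:
            forbidden.add((r, c))
    for v in cov + resp:
        if v != "Age":
            forbidden.add((v, "Age"))
    return ArcConstraints.make(forbidden=forbidden)


def empty_constrained_dag(nodes: Iterable[str], constraints: ArcConstraints) -> Dag:
    """Empty graph plus all whitelisted arcs."""
    dag = Dag(tuple(nodes))
    for p, c in sorted(constraints.required):
        dag.add_edge(p, c)
    return dag


# -- serialization ---------------------------------------------------------

def edges_to_tsv(dag: Dag) -> str:
    """Two-column TSV edge list, lexicographic order, header included."""
    lines = ["parent\tchild"]
    lines.extend(f"{p}\t{c}" for p, c in dag.sorted_edges())
    return "\n".join(lines) + "\n"

def edges_from_tsv(text: str, nodes: Iterable[str]) -> Dag:
    lines = [ln for ln in text.strip().splitlines() if ln]
    if not lines or lines[0].split("\t") != ["parent", "child"]:
        raise ValueError("edge TSV must start with 'parent\\tchild' header")
    edges = set()
    for ln in lines[1:]:
        p, c = ln.split("\t")
        edges.add((p, c))
    return Dag(tuple(nodes), edges)


def to_dot(dag: Dag, edge_labels: dict[Edge, str] | None = None) -> str:
    """GraphViz DOT rendering with deterministic ordering."""
    out = ["digraph rgbn {"]
    for n in dag.nodes:
        out.append(f'  "{n}";')
    for p, c in dag.sorted_edges():
        label = (edge_labels or {}).get((p, c))
        attr = f' [label="{label}"]' if label is not None else ""
        out.append(f'  "{p}" -> "{c}"{attr};')
    out.append("}")
    return "\n".join(out) + "\n"
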