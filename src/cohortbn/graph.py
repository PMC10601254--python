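"""Directed graphs for Bayesian networks.

A :class:`DirectedGraph` carries a node list, a set of directed edges
and — only for the output of constraint-based structure learning — a set
of undirected edges.  Classifier graphs are always fully directed and
acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx


@dataclass
class DirectedGraph:
    """Node set plus directed (and optionally undirected) edges.

    Parameters
    ----------
    nodes:
        Variable names.  Order is preserved and used for deterministic
        tie-breaking.
    directed_edges:
        ``(parent, child)`` pairs.
    undirected_edges:
        Unordered pairs, used only by partially directed structure
        learning output; always empty for classifier graphs.
    """

    nodes: list[str]
    directed_edges: list[tuple[str, str]] = field(default_factory=list)
    undirected_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        seen: set[tuple[str, str]] = set()
        for u, v in self.directed_edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add((u, v))
        useen: set[frozenset[str]] = set()
        for u, v in self.undirected_edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            key = frozenset((u, v))
            if key in useen:
                raise ValueError(f"duplicate undirected edge ({u!r}, {v!r})")
            useen.add(key)

    # -- queries -----------------------------------------------------

    def parents(self, node: str) -> list[str]:
        self._check_node(node)
        return [u for u, v in self.directed_edges if v == node]

    def children(self, node: str) -> list[str]:
        self._check_node(node)
        return [v for u, v in self.directed_edges if u == node]

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self._nx())

    def topological_order(self) -> list[str]:
        """Deterministic topological order (ties broken by node-list order)."""
        if not self.is_acyclic():
            raise ValueError("graph has a directed cycle")
        rank = {n: i for i, n in enumerate(self.nodes)}
        return list(
            nx.lexicographical_topological_sort(self._nx(), key=lambda n: rank[n])
        )

    def markov_blanket(self, node: str) -> set[str]:
        """Parents, children and the children's other parents."""
        self._check_node(node)
        blanket: set[str] = set(self.parents(node)) | set(self.children(node))
        for child in self.children(node):
            blanket.update(self.parents(child))
        blanket.discard(node)
        return blanket

    def ancestors(self, node: str) -> set[str]:
        self._check_node(node)
        return set(nx.ancestors(self._nx(), node))

    def _check_node(self, node: str) -> None:
        if node not in self.nodes:
            raise ValueError(f"unknown node {node!r}")

    def _nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        return g

    # -- export ------------------------------------------------------

    def to_dot(self, name: str = "G") -> str:
        """Render as a DOT document (undirected edges drawn without arrowheads)."""
        lines = [f"digraph {name} {{"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in self.directed_edges:
            lines.append(f'  "{u}" -> "{v}";')
        for u, v in self.undirected_edges:
            lines.append(f'  "{u}" -> "{v}" [dir=none];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def markov_blanket(dag: DirectedGraph, node: str) -> set[str]:
    """Functional alias for :meth:`DirectedGraph.markov_blanket`."""
    return dag.markov_blanket(node)


def star_graph(center: str, leaves: Iterable[str]) -> DirectedGraph:
    """A graph with arcs from ``center`` to every leaf (the NB shape)."""
    leaves = list(leaves)
    return DirectedGraph([center, *leaves], [(center, leaf) for leaf in leaves])
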