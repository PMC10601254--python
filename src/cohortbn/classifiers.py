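"""Bayesian-network classifiers: NB, TAN and KDB.

All three variants share the same prediction rule — the class state
maximizing P(c) * prod_j P(a_j | parents(a_j)) — and differ only in the
attribute-attribute arcs:

* Naive Bayes (NB): none; the class is every attribute's only parent.
* Tree-Augmented NB (TAN): a maximum-weight spanning tree over the
  attributes, weighted by class-conditional mutual information, so each
  attribute gains at most one attribute parent.
* k-Dependence Bayesian classifier (KDB): attributes sorted by mutual
  information with the class; the attribute at position i receives the
  min(i-1, k) earlier attributes with the highest class-conditional
  mutual information as parents.

NB is exactly KDB(0) and TAN has the same parent-count budget as
KDB(1) built on a global tree instead of a greedy per-node choice.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import (
    ConditionalProbabilityTable,
    class_posterior,
    conditional_mutual_information,
    fit_cpt,
    mutual_information,
)
from .graph import DirectedGraph

__all__ = [
    "FittedClassifier",
    "Prediction",
    "train_nb",
    "train_tan",
    "train_kdb",
    "predict",
    "count_dependencies",
    "maximum_weight_spanning_tree",
    "log_likelihood",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class FittedClassifier:
    """A fitted NB / TAN / KDB model.

    ``dag`` spans the class variable and all attributes; the class is a
    parent of every attribute in every variant.  ``cpts`` maps each node
    to its conditional probability table (the class CPT is the prior).
    """

    variant: str  # "nb" | "tan" | "kdb"
    k: int
    class_var: str
    attributes: tuple[str, ...]
    dag: DirectedGraph
    cpts: dict[str, ConditionalProbabilityTable]
    smoothing: float

    @property
    def class_states(self) -> tuple[str, ...]:
        return self.cpts[self.class_var].child_states

    @property
    def class_prior(self) -> dict[str, float]:
        cpt = self.cpts[self.class_var]
        return {s: float(p) for s, p in zip(cpt.child_states, cpt.probs[0])}

    def attribute_edges(self) -> list[tuple[str, str]]:
        """Attribute-attribute arcs (excludes class→attribute arcs)."""
        return [
            (u, v) for u, v in self.dag.directed_edges if u != self.class_var
        ]


@dataclass(frozen=True)
class Prediction:
    predicted_class: str
    posterior: dict[str, float]


def _check_training_args(
    table: pd.DataFrame, class_var: str, attributes: Sequence[str]
) -> tuple[str, ...]:
    attributes = tuple(attributes)
    if class_var in attributes:
        raise ValueError(f"class variable {class_var!r} cannot be an attribute")
    if len(set(attributes)) != len(attributes):
        raise ValueError("duplicate attribute names")
    for col in (class_var, *attributes):
        if col not in table.columns:
            raise ValueError(f"unknown column {col!r}")
    if len(attributes) < 1:
        raise ValueError("at least one attribute is required")
    return attributes


def _fit_model(
    table: pd.DataFrame,
    variant: str,
    k: int,
    class_var: str,
    attributes: tuple[str, ...],
    attr_parents: Mapping[str, tuple[str, ...]],
    smoothing: float,
    states: Mapping[str, Sequence[str]] | None,
) -> FittedClassifier:
    edges = [(class_var, a) for a in attributes]
    for a in attributes:
        for p in attr_parents[a]:
            edges.append((p, a))
    dag = DirectedGraph([class_var, *attributes], edges)
    if not dag.is_acyclic():
        raise ValueError("classifier graph has a cycle")  # pragma: no cover
    cpts = {class_var: fit_cpt(table, class_var, (), smoothing, states)}
    for a in attributes:
        cpts[a] = fit_cpt(
            table, a, (class_var, *attr_parents[a]), smoothing, states
        )
    return FittedClassifier(
        variant=variant,
        k=k,
        class_var=class_var,
        attributes=attributes,
        dag=dag,
        cpts=cpts,
        smoothing=smoothing,
    )


def train_nb(
    table: pd.DataFrame,
    class_var: str,
    attributes: Sequence[str],
    smoothing: float = 1.0,
    states: Mapping[str, Sequence[str]] | None = None,
) -> FittedClassifier:
    """Fit a Naive Bayes model: star DAG class→attribute, smoothed CPTs."""
    attributes = _check_training_args(table, class_var, attributes)
    return _fit_model(
        table, "nb", 0, class_var, attributes,
        {a: () for a in attributes}, smoothing, states,
    )


def maximum_weight_spanning_tree(
    nodes: Sequence[str], weights: Mapping[frozenset[str], float]
) -> list[tuple[str, str]]:
    """Kruskal-style maximum-weight spanning tree with cycle rejection.

    Edges are sorted by decreasing weight, then lexicographically by the
    sorted node pair (the deterministic tie-break); each edge is accepted
    unless it would close a cycle.  Returns n-1 undirected edges as
    sorted pairs.
    """
    nodes = list(nodes)
    candidates = sorted(
        (tuple(sorted(pair)) for pair in itertools.combinations(nodes, 2)),
        key=lambda uv: (-weights.get(frozenset(uv), 0.0), uv),
    )
    parent = {n: n for n in nodes}

    def find(n: str) -> str:
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    tree: list[tuple[str, str]] = []
    for u, v in candidates:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v))
            if len(tree) == len(nodes) - 1:
                break
    return tree


def _orient_from_root(
    nodes: Sequence[str], tree: Sequence[tuple[str, str]], root: str
) -> dict[str, tuple[str, ...]]:
    """Direct tree edges away from the root; returns per-node parent tuple."""
    adjacency: dict[str, list[str]] = {n: [] for n in nodes}
    for u, v in tree:
        adjacency[u].append(v)
        adjacency[v].append(u)
    parents: dict[str, tuple[str, ...]] = {n: () for n in nodes}
    visited = {root}
    frontier = [root]
    while frontier:
        node = frontier.pop()
        for nb in sorted(adjacency[node]):
            if nb not in visited:
                visited.add(nb)
                parents[nb] = (node,)
                frontier.append(nb)
    return parents


def train_tan(
    table: pd.DataFrame,
    class_var: str,
    attributes: Sequence[str],
    smoothing: float = 1.0,
    root: str | None = None,
    states: Mapping[str, Sequence[str]] | None = None,
) -> FittedClassifier:
    """Fit a Tree-Augmented Naive Bayes model.

    Steps: (1) class-conditional mutual information for every attribute
    pair; (2) maximum-weight spanning tree by greedy sorted edge
    selection with cycle rejection; (3) edges oriented away from the
    root (default: the attribute with the highest mutual information
    with the class); (4) class added as parent of every attribute and
    CPTs fitted.
    """
    attributes = _check_training_args(table, class_var, attributes)
    if len(attributes) < 2:
        raise ValueError("TAN requires at least 2 attributes (no tree exists)")
    weights = {
        frozenset((a, b)): conditional_mutual_information(table, a, b, class_var)
        for a, b in itertools.combinations(attributes, 2)
    }
    tree = maximum_weight_spanning_tree(attributes, weights)
    if root is None:
        # deterministic: highest MI with the class, ties broken by name
        mi = {a: mutual_information(table, a, class_var) for a in attributes}
        root = sorted(attributes, key=lambda a: (-mi[a], a))[0]
    elif root not in attributes:
        raise ValueError(f"root {root!r} is not an attribute")
    attr_parents = _orient_from_root(attributes, tree, root)
    return _fit_model(
        table, "tan", 1, class_var, attributes, attr_parents, smoothing, states
    )


def train_kdb(
    table: pd.DataFrame,
    class_var: str,
    attributes: Sequence[str],
    k: int = 2,
    smoothing: float = 1.0,
    states: Mapping[str, Sequence[str]] | None = None,
) -> FittedClassifier:
    """Fit a k-dependence Bayesian classifier.

    Attributes are sorted by decreasing mutual information with the
    class (ties broken lexicographically); the attribute at position i
    (1-based) receives as parents the min(i-1, k) already-placed
    attributes with the highest class-conditional mutual information,
    plus the class.  KDB(0) is structurally identical to NB.
    """
    attributes = _check_training_args(table, class_var, attributes)
    if not 0 <= k <= len(attributes) - 1:
        raise ValueError(
            f"k must be in [0, {len(attributes) - 1}] for "
            f"{len(attributes)} attributes; got {k}"
        )
    mi = {a: mutual_information(table, a, class_var) for a in attributes}
    order = sorted(attributes, key=lambda a: (-mi[a], a))
    attr_parents: dict[str, tuple[str, ...]] = {}
    for i, a in enumerate(order):  # i earlier attributes precede position i+1
        candidates = order[:i]
        n_parents = min(i, k)
        if n_parents == 0:
            attr_parents[a] = ()
            continue
        cmi = {
            b: conditional_mutual_information(table, a, b, class_var)
            for b in candidates
        }
        chosen = sorted(candidates, key=lambda b: (-cmi[b], b))[:n_parents]
        attr_parents[a] = tuple(chosen)
    return _fit_model(
        table, "kdb", k, class_var, attributes, attr_parents, smoothing, states
    )


def predict(model: FittedClassifier, instance: Mapping[str, str]) -> Prediction:
    """Most probable class for one instance (full attribute evidence).

    Ties are broken by class-state order.
    """
    posterior = class_posterior(model, instance)
    best = max(
        model.class_states,
        key=lambda c: (posterior[c], -model.class_states.index(c)),
    )
    return Prediction(predicted_class=best, posterior=posterior)


def count_dependencies(n_attributes: int, k: int) -> int:
    """Number of attribute-attribute arcs in a KDB structure.

    Sum over i = 1..n of min(i-1, k): 0 for NB (k=0), n-1 for a tree
    budget (k=1), and e.g. 31 for n=17, k=2.
    """
    if n_attributes < 1:
        raise ValueError("n_attributes must be >= 1")
    if not 0 <= k <= n_attributes - 1:
        raise ValueError(f"k must be in [0, {n_attributes - 1}]; got {k}")
    return sum(min(i - 1, k) for i in range(1, n_attributes + 1))


def log_likelihood(model: FittedClassifier, table: pd.DataFrame) -> float:
    """Training-set joint log-likelihood (natural log) under the model."""
    total = 0.0
    for _, row in table.iterrows():
        assignment = {col: str(row[col]) for col in model.dag.nodes}
        lp = 0.0
        for node in model.dag.nodes:
            p = model.cpts[node].prob(assignment[node], assignment)
            if p <= 0.0:
                return -math.inf
            lp += math.log(p)
        total += lp
    return total


# -- serialization ---------------------------------------------------


def model_to_json(model: FittedClassifier) -> str:
    doc = {
        "type": model.variant,
        "k": model.k,
        "class_var": model.class_var,
        "attributes": list(model.attributes),
        "nodes": list(model.dag.nodes),
        "edges": [list(e) for e in model.dag.directed_edges],
        "smoothing": model.smoothing,
        "cpts": {
            node: {
                "parents": list(cpt.parents),
                "child_states": list(cpt.child_states),
                "parent_states": [list(s) for s in cpt.parent_states],
                "probs": cpt.probs.tolist(),
            }
            for node, cpt in model.cpts.items()
        },
    }
    return json.dumps(doc, indent=2)


def model_from_json(text: str) -> FittedClassifier:
    doc = json.loads(text)
    dag = DirectedGraph(doc["nodes"], [tuple(e) for e in doc["edges"]])
    cpts = {
        node: ConditionalProbabilityTable(
            child=node,
            parents=tuple(spec["parents"]),
            child_states=tuple(spec["child_states"]),
            parent_states=tuple(tuple(s) for s in spec["parent_states"]),
            probs=np.asarray(spec["probs"], dtype=float),
        )
        for node, spec in doc["cpts"].items()
    }
    return FittedClassifier(
        variant=doc["type"],
        k=int(doc["k"]),
        class_var=doc["class_var"],
        attributes=tuple(doc["attributes"]),
        dag=dag,
        cpts=cpts,
        smoothing=float(doc["smoothing"]),
    )
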