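"""Core Bayesian-network machinery.

Conditional probability tables (CPTs) with Laplace smoothing, the joint
factorization P(x1..xn) = prod_i P(xi | parents(xi)), empirical mutual
information and class-conditional mutual information in bits, exact
class-posterior inference in log space, and CPT row queries.

A cohort table is an ordinary :class:`pandas.DataFrame` whose cells are
state labels (strings); no missing values are allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError
from .graph import DirectedGraph

__all__ = [
    "ConditionalProbabilityTable",
    "fit_cpt",
    "joint_probability",
    "mutual_information",
    "conditional_mutual_information",
    "class_posterior",
    "query_cpt",
]


@dataclass(frozen=True)
class ConditionalProbabilityTable:
    """Distribution of one child node per combination of parent states.

    ``probs`` has one row per parent-state combination (mixed-radix
    order: the first parent varies slowest) and one column per child
    state.  A parentless node has a single row — its marginal.
    """

    child: str
    parents: tuple[str, ...]
    child_states: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        n_configs = int(np.prod([len(s) for s in self.parent_states], initial=1))
        if self.probs.shape != (n_configs, len(self.child_states)):
            raise ValueError(
                f"CPT for {self.child!r}: probs shape {self.probs.shape} "
                f"!= ({n_configs}, {len(self.child_states)})"
            )
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"CPT rows for {self.child!r} do not sum to 1")

    def config_index(self, assignment: Mapping[str, str]) -> int:
        """Row index for a full assignment of the parents."""
        idx = 0
        for parent, states in zip(self.parents, self.parent_states):
            if parent not in assignment:
                raise ValueError(f"missing assignment for parent {parent!r}")
            value = assignment[parent]
            if value not in states:
                raise ValueError(
                    f"{value!r} is not a state of {parent!r} (states: {states})"
                )
            idx = idx * len(states) + states.index(value)
        return idx

    def row(self, assignment: Mapping[str, str]) -> np.ndarray:
        """The conditional distribution of the child given parent states."""
        return self.probs[self.config_index(assignment)]

    def prob(self, child_state: str, assignment: Mapping[str, str]) -> float:
        if child_state not in self.child_states:
            raise ValueError(
                f"{child_state!r} is not a state of {self.child!r} "
                f"(states: {self.child_states})"
            )
        return float(self.row(assignment)[self.child_states.index(child_state)])


def _column_states(
    table: pd.DataFrame, column: str, states: Mapping[str, Sequence[str]] | None
) -> tuple[str, ...]:
    if states is not None and column in states:
        return tuple(states[column])
    return tuple(sorted(table[column].astype(str).unique()))


def fit_cpt(
    table: pd.DataFrame,
    child: str,
    parents: Sequence[str],
    smoothing: float = 1.0,
    states: Mapping[str, Sequence[str]] | None = None,
) -> ConditionalProbabilityTable:
    """Estimate P(child | parents) by smoothed empirical frequencies.

    P(child=s | parents=g) = (count(s, g) + smoothing)
                           / (count(g) + smoothing * |states(child)|).

    A parent combination never observed yields the uniform distribution
    when ``smoothing`` is 0 (and under pure smoothing otherwise).
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    parents = tuple(parents)
    child_states = _column_states(table, child, states)
    parent_states = tuple(_column_states(table, p, states) for p in parents)
    cards = [len(s) for s in parent_states]
    n_configs = int(np.prod(cards, initial=1))
    counts = np.zeros((n_configs, len(child_states)), dtype=float)

    if len(table) > 0:
        child_codes = (
            table[child].astype(str).map({s: i for i, s in enumerate(child_states)})
        )
        if child_codes.isna().any():
            bad = table[child][child_codes.isna()].iloc[0]
            raise ValueError(f"{bad!r} is not a declared state of {child!r}")
        config = np.zeros(len(table), dtype=np.int64)
        for p, p_states in zip(parents, parent_states):
            codes = table[p].astype(str).map({s: i for i, s in enumerate(p_states)})
            if codes.isna().any():
                bad = table[p][codes.isna()].iloc[0]
                raise ValueError(f"{bad!r} is not a declared state of {p!r}")
            config = config * len(p_states) + codes.to_numpy(dtype=np.int64)
        np.add.at(counts, (config, child_codes.to_numpy(dtype=np.int64)), 1.0)

    numer = counts + smoothing
    denom = counts.sum(axis=1, keepdims=True) + smoothing * len(child_states)
    probs = np.where(denom > 0, numer / np.where(denom == 0, 1.0, denom), 0.0)
    # unseen configuration with smoothing 0: fall back to uniform
    empty = denom[:, 0] == 0
    if empty.any():
        probs[empty] = 1.0 / len(child_states)
    return ConditionalProbabilityTable(
        child=child,
        parents=parents,
        child_states=child_states,
        parent_states=parent_states,
        probs=probs,
    )


def joint_probability(
    dag: DirectedGraph,
    cpts: Mapping[str, ConditionalProbabilityTable] | Sequence[ConditionalProbabilityTable],
    assignment: Mapping[str, str],
) -> float:
    """P(assignment) = prod over nodes of P(x_i | parents(x_i))."""
    if not isinstance(cpts, Mapping):
        cpts = {cpt.child: cpt for cpt in cpts}
    prob = 1.0
    for node in dag.nodes:
        if node not in assignment:
            raise ValueError(f"assignment is missing node {node!r}")
        cpt = cpts[node]
        prob *= cpt.prob(assignment[node], assignment)
    return prob


def _joint_counts(table: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Contingency array over the given columns (observed states, sorted)."""
    if len(table) == 0:
        raise DataError("empty table")
    for col in columns:
        if col not in table.columns:
            raise ValueError(f"unknown column {col!r}")
    codes, cards = [], []
    for col in columns:
        values = table[col].astype(str)
        states = sorted(values.unique())
        codes.append(values.map({s: i for i, s in enumerate(states)}).to_numpy())
        cards.append(len(states))
    flat = np.ravel_multi_index(codes, cards)
    counts = np.bincount(flat, minlength=int(np.prod(cards)))
    return counts.reshape(cards).astype(float)


def _mi_from_counts(counts: np.ndarray) -> float:
    """MI in bits from a 2-D contingency array (0·log 0 = 0 convention)."""
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def mutual_information(table: pd.DataFrame, x: str, y: str) -> float:
    """Empirical mutual information I(X; Y) in bits."""
    return max(0.0, _mi_from_counts(_joint_counts(table, [x, y])))


def conditional_mutual_information(
    table: pd.DataFrame, xi: str, xj: str, c: str
) -> float:
    """Class-conditional mutual information I(Xi; Xj | C) in bits.

    Sum over (xi, xj, c) of p(xi, xj, c) * log2[p(xi, xj | c) /
    (p(xi | c) p(xj | c))]; zero exactly when Xi and Xj are independent
    within every class.
    """
    counts = _joint_counts(table, [xi, xj, c])  # axes: xi, xj, c
    n = counts.sum()
    cmi = 0.0
    for k in range(counts.shape[2]):
        slab = counts[:, :, k]
        n_c = slab.sum()
        if n_c == 0:
            continue
        cmi += (n_c / n) * _mi_from_counts(slab)
    return max(0.0, cmi)


def class_posterior(model, evidence: Mapping[str, str]) -> dict[str, float]:
    """Exact posterior over class states given full attribute evidence.

    Computes log P(c) + sum_j log P(a_j | parents(a_j)) for every class
    state and normalizes; log-space keeps 16-attribute products stable.
    """
    for attr in model.attributes:
        if attr not in evidence:
            raise ValueError(f"evidence is missing attribute {attr!r}")
    log_post = []
    for c_state in model.class_states:
        assignment = dict(evidence)
        assignment[model.class_var] = c_state
        lp = math.log(model.cpts[model.class_var].prob(c_state, assignment))
        for attr in model.attributes:
            p = model.cpts[attr].prob(evidence[attr], assignment)
            if p <= 0.0:
                lp = -math.inf
                break
            lp += math.log(p)
        log_post.append(lp)
    m = max(log_post)
    if m == -math.inf:
        raise ValueError("all class states have zero posterior probability")
    weights = [math.exp(lp - m) for lp in log_post]
    total = sum(weights)
    return {c: w / total for c, w in zip(model.class_states, weights)}


def query_cpt(
    model, child: str, parent_assignment: Mapping[str, str]
) -> dict[str, float]:
    """Read one conditional-distribution row of a fitted model's CPT.

    ``parent_assignment`` must cover exactly the child's parents in the
    model DAG — this is the mechanism behind reading off, e.g., the
    probability of neonatal jaundice given pneumonia status and amniotic
    fluid cleanliness from a fitted network.
    """
    if child not in model.cpts:
        raise ValueError(f"unknown node {child!r}")
    cpt = model.cpts[child]
    expected = set(cpt.parents)
    given = set(parent_assignment)
    if given != expected:
        raise ValueError(
            f"parent assignment for {child!r} must cover exactly "
            f"{sorted(expected)}; got {sorted(given)}"
        )
    row = cpt.row(parent_assignment)
    return {s: float(p) for s, p in zip(cpt.child_states, row)}
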