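"""Constraint-based structure discovery and bootstrap model averaging.

The learner is Grow-Shrink (GS): each variable's Markov blanket is
found by a greedy grow phase (add any variable dependent on the target
given the current blanket) followed by a shrink phase (drop any blanket
member independent of the target given the rest), using the G²
likelihood-ratio test of conditional independence on stratified
contingency tables.  Blankets are resolved to a skeleton, colliders are
oriented where a common neighbour is absent from the separating set,
and all remaining edges are reported undirected.

Stability is assessed by nonparametric bootstrap: resample the table
with replacement B times, learn a network on each replicate, and report
per-edge *strength* (the fraction of replicates containing the edge in
either orientation) and *direction confidence* (the fraction of those
replicates orienting it from→to, with undirected occurrences counted
half for each direction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .graph import DirectedGraph

__all__ = [
    "CITestResult",
    "ci_test",
    "grow_shrink",
    "AveragedNetwork",
    "Arc",
    "ArcSummary",
    "bootstrap_average",
    "summarize_arcs",
]


@dataclass(frozen=True)
class CITestResult:
    """G² conditional-independence test result."""

    statistic: float
    df: int
    p_value: float


def _encode(table: pd.DataFrame) -> tuple[np.ndarray, dict[str, int], list[int]]:
    """Integer-code every column; returns (matrix, column index, cards)."""
    if len(table) == 0:
        raise DataError("empty table")
    mat = np.empty((len(table), table.shape[1]), dtype=np.int64)
    cards = []
    index = {}
    for j, col in enumerate(table.columns):
        values = table[col].astype(str)
        states = sorted(values.unique())
        mat[:, j] = values.map({s: i for i, s in enumerate(states)}).to_numpy()
        cards.append(len(states))
        index[col] = j
    return mat, index, cards


def _g2_from_codes(
    x: np.ndarray, y: np.ndarray, zs: Sequence[np.ndarray],
    cx: int, cy: int, czs: Sequence[int],
) -> CITestResult:
    """G² = 2 Σ n_xyz ln(n_xyz n_z / (n_xz n_yz)), summed over strata.

    Strata with a zero margin contribute 0.  Degrees of freedom are
    (|x|-1)(|y|-1)·Π|z| regardless of empty strata.
    """
    cz = int(np.prod(czs, initial=1))
    z = np.zeros(len(x), dtype=np.int64)
    for zcol, card in zip(zs, czs):
        z = z * card + zcol
    flat = (z * cx + x) * cy + y
    counts = np.bincount(flat, minlength=cz * cx * cy).reshape(cz, cx, cy)
    n_z = counts.sum(axis=(1, 2), keepdims=True)
    n_xz = counts.sum(axis=2, keepdims=True)
    n_yz = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = counts * n_z / (n_xz * n_yz)
        terms = counts * np.log(ratio)
    g2 = 2.0 * float(np.nansum(terms))
    g2 = max(g2, 0.0)
    df = (cx - 1) * (cy - 1) * cz
    p = float(stats.chi2.sf(g2, df)) if df > 0 else 1.0
    return CITestResult(statistic=g2, df=df, p_value=p)


def ci_test(
    table: pd.DataFrame, x: str, y: str, conditioning: Sequence[str] = ()
) -> CITestResult:
    """G² likelihood-ratio test of X ⊥ Y | conditioning set."""
    conditioning = list(conditioning)
    if x in conditioning or y in conditioning:
        raise ValueError("conditioning set must exclude x and y")
    for col in (x, y, *conditioning):
        if col not in table.columns:
            raise ValueError(f"unknown column {col!r}")
    mat, index, cards = _encode(table)
    return _g2_from_codes(
        mat[:, index[x]], mat[:, index[y]],
        [mat[:, index[z]] for z in conditioning],
        cards[index[x]], cards[index[y]],
        [cards[index[z]] for z in conditioning],
    )


class _CIOracle:
    """Cached G² tests over an encoded table."""

    def __init__(self, mat: np.ndarray, cards: Sequence[int]):
        self.mat = mat
        self.cards = list(cards)
        self._cache: dict[tuple[int, int, tuple[int, ...]], float] = {}

    def p_value(self, i: int, j: int, cond: Sequence[int]) -> float:
        a, b = (i, j) if i < j else (j, i)
        key = (a, b, tuple(sorted(cond)))
        if key not in self._cache:
            result = _g2_from_codes(
                self.mat[:, a], self.mat[:, b],
                [self.mat[:, z] for z in key[2]],
                self.cards[a], self.cards[b],
                [self.cards[z] for z in key[2]],
            )
            self._cache[key] = result.p_value
        return self._cache[key]


def _grow_shrink_blanket(
    oracle: _CIOracle, target: int, order: Sequence[int], alpha: float
) -> list[int]:
    blanket: list[int] = []
    changed = True
    while changed:  # grow: add variables dependent given the current blanket
        changed = False
        for x in order:
            if x == target or x in blanket:
                continue
            if oracle.p_value(target, x, blanket) < alpha:
                blanket.append(x)
                changed = True
    for x in list(blanket):  # shrink: drop members independent given the rest
        rest = [b for b in blanket if b != x]
        if oracle.p_value(target, x, rest) >= alpha:
            blanket.remove(x)
    return blanket


def _subsets(items: Sequence[int], max_size: int | None = None):
    limit = len(items) if max_size is None else min(len(items), max_size)
    for r in range(limit + 1):
        yield from itertools.combinations(items, r)


def grow_shrink(
    table: pd.DataFrame, alpha: float = 0.05
) -> DirectedGraph:
    """Grow-Shrink structure learning; returns a partially directed graph.

    Variables are processed in column order (GS output can depend on
    this ordering, so it is fixed and documented).  Edges that take part
    in a discovered collider are directed; everything else is reported
    as an undirected edge.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    mat, index, cards = _encode(table)
    columns = list(table.columns)
    n_vars = len(columns)
    oracle = _CIOracle(mat, cards)
    order = list(range(n_vars))

    blankets = {
        t: set(_grow_shrink_blanket(oracle, t, order, alpha)) for t in order
    }
    # enforce blanket symmetry (AND rule) for robustness
    for t in order:
        blankets[t] = {x for x in blankets[t] if t in blankets[x]}

    # neighbour resolution: X—Y direct unless some subset of the smaller
    # blanket (minus the other endpoint) separates them
    adjacency: dict[int, set[int]] = {t: set() for t in order}
    sepsets: dict[tuple[int, int], tuple[int, ...]] = {}
    for x in order:
        for y in sorted(blankets[x]):
            if y <= x:
                continue
            bx = sorted(blankets[x] - {y})
            by = sorted(blankets[y] - {x})
            base = bx if len(bx) <= len(by) else by
            separated = False
            for s in _subsets(base):
                if oracle.p_value(x, y, s) >= alpha:
                    sepsets[(x, y)] = s
                    separated = True
                    break
            if not separated:
                adjacency[x].add(y)
                adjacency[y].add(x)

    # collider orientation: X—C—Y with X,Y non-adjacent and C outside
    # the separating set of (X, Y)
    directed: set[tuple[int, int]] = set()
    for x, y in itertools.combinations(order, 2):
        if y in adjacency[x]:
            continue
        common = adjacency[x] & adjacency[y]
        if not common:
            continue
        if (x, y) in sepsets:
            sep = sepsets[(x, y)]
        else:
            bx = sorted(blankets[x] - {y})
            by = sorted(blankets[y] - {x})
            base = bx if len(bx) <= len(by) else by
            sep = next(
                (s for s in _subsets(base) if oracle.p_value(x, y, s) >= alpha),
                None,
            )
            if sep is None:
                continue
        for c in sorted(common):
            if c not in sep:
                directed.add((x, c))
                directed.add((y, c))

    # an edge oriented both ways by conflicting colliders stays undirected
    clean_directed = [
        (columns[u], columns[v])
        for u, v in sorted(directed)
        if (v, u) not in directed
    ]
    directed_pairs = {frozenset((u, v)) for u, v in directed}
    undirected = [
        (columns[x], columns[y])
        for x in order
        for y in sorted(adjacency[x])
        if x < y and frozenset((x, y)) not in directed_pairs
    ]
    conflicted = [
        (columns[u], columns[v])
        for u, v in sorted(directed)
        if (v, u) in directed and u < v
    ]
    return DirectedGraph(columns, clean_directed, undirected + conflicted)


@dataclass(frozen=True)
class Arc:
    """One skeleton edge of an averaged network.

    ``strength`` is the fraction of bootstrap replicates containing the
    edge in either orientation; ``direction_confidence`` the fraction of
    those oriented ``source → target`` (undirected counted 0.5).  The
    reported orientation is the majority one.
    """

    source: str
    target: str
    strength: float
    direction_confidence: float


@dataclass(frozen=True)
class AveragedNetwork:
    nodes: tuple[str, ...]
    arcs: tuple[Arc, ...]
    threshold: float
    n_replicates: int

    @property
    def retained(self) -> tuple[Arc, ...]:
        return tuple(a for a in self.arcs if a.strength >= self.threshold)


@dataclass(frozen=True)
class ArcSummary:
    n_directed: int
    n_undirected: int


def bootstrap_average(
    table: pd.DataFrame,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    threshold: float = 0.5,
) -> AveragedNetwork:
    """Bootstrap model averaging of Grow-Shrink networks.

    Draws ``B`` resamples of the table with replacement (same n), learns
    a network on each, and averages arc occurrence into strengths; with
    B replicates every strength is a multiple of 1/B.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1; got {B}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1]; got {threshold}")
    rng = np.random.default_rng(seed)
    n = len(table)
    present: dict[frozenset[str], int] = {}
    toward: dict[tuple[str, str], float] = {}
    for _ in range(B):
        idx = rng.integers(0, n, n)
        replicate = table.iloc[idx].reset_index(drop=True)
        graph = grow_shrink(replicate, alpha)
        for u, v in graph.directed_edges:
            key = frozenset((u, v))
            present[key] = present.get(key, 0) + 1
            toward[(u, v)] = toward.get((u, v), 0.0) + 1.0
        for u, v in graph.undirected_edges:
            key = frozenset((u, v))
            present[key] = present.get(key, 0) + 1
            toward[(u, v)] = toward.get((u, v), 0.0) + 0.5
            toward[(v, u)] = toward.get((v, u), 0.0) + 0.5

    arcs = []
    for key, count in present.items():
        u, v = sorted(key)
        fwd = toward.get((u, v), 0.0)
        rev = toward.get((v, u), 0.0)
        if rev > fwd:
            u, v = v, u
            fwd, rev = rev, fwd
        arcs.append(
            Arc(
                source=u,
                target=v,
                strength=count / B,
                direction_confidence=fwd / count,
            )
        )
    arcs.sort(key=lambda a: (-a.strength, a.source, a.target))
    return AveragedNetwork(
        nodes=tuple(table.columns),
        arcs=tuple(arcs),
        threshold=threshold,
        n_replicates=B,
    )


def summarize_arcs(net: AveragedNetwork, direction_cutoff: float = 0.9) -> ArcSummary:
    """Count retained arcs as directed vs undirected.

    An arc whose majority orientation reaches ``direction_cutoff`` of
    the replicates containing it is counted directed; arcs that flip
    orientation across replicates (confidence below the cutoff, e.g.
    51%/49%) are counted undirected.
    """
    if not 0.5 < direction_cutoff <= 1.0:
        raise ValueError(
            f"direction_cutoff must be in (0.5, 1]; got {direction_cutoff}"
        )
    n_directed = sum(
        1 for a in net.retained if a.direction_confidence >= direction_cutoff
    )
    return ArcSummary(
        n_directed=n_directed,
        n_undirected=len(net.retained) - n_directed,
    )
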