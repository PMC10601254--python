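"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — plain enumeration over joint
states, pairwise counting, Prüfer-sequence tree enumeration — and never
shares code with the package internals it validates.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from typing import Mapping, Sequence

import numpy as np


def enumeration_posterior(model, evidence: Mapping[str, str]) -> dict[str, float]:
    """Class posterior from the full joint table built by enumeration.

    Builds P(class, attributes) cell by cell as a product of CPT
    entries, then conditions on the evidence by direct summation.
    """
    states = {model.class_var: model.cpts[model.class_var].child_states}
    for a in model.attributes:
        states[a] = model.cpts[a].child_states
    nodes = [model.class_var, *model.attributes]
    joint: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(*(states[n] for n in nodes)):
        assignment = dict(zip(nodes, combo))
        prob = 1.0
        for node in nodes:
            cpt = model.cpts[node]
            row_index = 0
            for parent, p_states in zip(cpt.parents, cpt.parent_states):
                row_index = row_index * len(p_states) + p_states.index(
                    assignment[parent]
                )
            prob *= cpt.probs[row_index][
                cpt.child_states.index(assignment[node])
            ]
        joint[combo] = prob
    weights = {}
    for c_state in states[model.class_var]:
        combo = tuple(
            c_state if n == model.class_var else evidence[n] for n in nodes
        )
        weights[c_state] = joint[combo]
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


def network_joint(network) -> dict[tuple[str, ...], float]:
    """Exact joint of a ground-truth network by enumeration (node order)."""
    order = network.dag.topological_order()
    joint: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(*(network.spec(n).states for n in order)):
        assignment = dict(zip(order, combo))
        prob = 1.0
        for node in order:
            cpt = network.cpts[node]
            row_index = 0
            for parent, p_states in zip(cpt.parents, cpt.parent_states):
                row_index = row_index * len(p_states) + p_states.index(
                    assignment[parent]
                )
            prob *= cpt.probs[row_index][
                cpt.child_states.index(assignment[node])
            ]
        key = tuple(assignment[n] for n in network.names)
        joint[key] = joint.get(key, 0.0) + prob
    return joint


def exact_variable_marginal(network, variable: str) -> dict[str, float]:
    """Marginal of one variable summed out of the enumerated joint."""
    idx = network.names.index(variable)
    marginal: dict[str, float] = {}
    for combo, prob in network_joint(network).items():
        marginal[combo[idx]] = marginal.get(combo[idx], 0.0) + prob
    return marginal


def pearson_chi2(counts: Sequence[Sequence[int]]) -> float:
    """Pearson X² from an r x c count table, cell by cell."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = counts[i].sum() * counts[:, j].sum() / n
            stat += (counts[i, j] - expected) ** 2 / expected
    return stat


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U of group x by exhaustive pair comparison (0.5 credit for ties)."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mutual_information_bits(pairs: Sequence[tuple[str, str]]) -> float:
    """MI of paired observations by direct formula evaluation."""
    n = len(pairs)
    joint = Counter(pairs)
    px = Counter(a for a, _ in pairs)
    py = Counter(b for _, b in pairs)
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab / ((px[a] / n) * (py[b] / n)))
    return mi


def conditional_mutual_information_bits(
    triples: Sequence[tuple[str, str, str]]
) -> float:
    """CMI(Xi; Xj | C) by direct triple summation of the defining formula."""
    n = len(triples)
    joint = Counter(triples)
    p_c = Counter(c for _, _, c in triples)
    p_ic = Counter((a, c) for a, _, c in triples)
    p_jc = Counter((b, c) for _, b, c in triples)
    cmi = 0.0
    for (a, b, c), count in joint.items():
        p_abc = count / n
        cond_joint = count / p_c[c]
        cond_i = p_ic[(a, c)] / p_c[c]
        cond_j = p_jc[(b, c)] / p_c[c]
        cmi += p_abc * math.log2(cond_joint / (cond_i * cond_j))
    return cmi


def all_spanning_trees(nodes: Sequence[str]):
    """All labeled spanning trees via Prüfer sequences (n^(n-2) trees)."""
    nodes = list(nodes)
    n = len(nodes)
    if n == 2:
        yield [tuple(sorted(nodes))]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        edges = []
        seq_list = list(seq)
        leaves = sorted(i for i in range(n) if degree[i] == 1)
        for v in seq_list:
            leaf = leaves.pop(0)
            edges.append(tuple(sorted((nodes[leaf], nodes[v]))))
            degree[v] -= 1
            if degree[v] == 1:
                # insert keeping the leaf list sorted
                lo = 0
                while lo < len(leaves) and leaves[lo] < v:
                    lo += 1
                leaves.insert(lo, v)
        u, v = leaves
        edges.append(tuple(sorted((nodes[u], nodes[v]))))
        yield edges


def max_weight_tree_weight(
    nodes: Sequence[str], weights: Mapping[frozenset, float]
) -> float:
    """Maximum total weight over every labeled spanning tree."""
    best = -math.inf
    for tree in all_spanning_trees(nodes):
        w = sum(weights.get(frozenset(e), 0.0) for e in tree)
        best = max(best, w)
    return best


def concordance_auc(
    scores: Sequence[float], labels: Sequence[str], positive: str
) -> float:
    """AUC by exhaustive positive/negative pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
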