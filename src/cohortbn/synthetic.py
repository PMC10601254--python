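"""Synthetic maternal–neonatal cohort generator.

The clinical cohort this package is designed around (≈2000 deliveries
in women with diabetes in pregnancy, ≈15% neonatal-pneumonia
prevalence, 16 discretized maternal and neonatal predictors) is not
publicly available.  This module provides a fixed, versioned
ground-truth Bayesian network over the same 17 variables so that every
downstream stage — screening, classifier training, structure learning,
evaluation — can be exercised and tested against a known data-generating
process.

Variables (all categorical):

====== ======= ==========================================
name   states  meaning
====== ======= ==========================================
age    1/2/3   maternal age band
pbg    1/2/3   two-hour postprandial blood glucose band
p      0/1     parity (multiparous)
hdop   0/1     gestational hypertension
ptb    0/1     preterm birth
prom   0/1     premature rupture of membranes
ms     0/1     macrosomia
nrds   0/1     neonatal respiratory distress syndrome
nnj    0/1     neonatal jaundice
pph    0/1     postpartum haemorrhage
na     0/1     neonatal asphyxia
ngr    0/1     neonatal growth restriction
g      1/2/3   number of pregnancies (gravidity band)
afv    1/2/3   amniotic fluid volume grade
afc    1/2/3   amniotic fluid cleanliness grade
crp    1/2/3   C-reactive protein band
np     0/1     neonatal pneumonia (outcome)
====== ======= ==========================================

The dependency structure encodes clinically motivated pathways:
glucose control drives hypertension, macrosomia and membrane rupture
(pbg→hdop, pbg→ms, pbg→prom→ptb), gravidity drives parity and amniotic
fluid volume (g→p, g→afv→afc→crp), and pneumonia both depends on
upstream risk factors (pbg, ptb, afc, p → np) and drives neonatal
sequelae (np→nrds, np→nnj←afc, np→na, np→ngr, np→pph).  The CPT
constants are fixed; they were chosen so the marginal outcome
prevalence is ≈0.152 and every predictor carries a screening-detectable
association with the outcome at n ≈ 2000.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import ConditionalProbabilityTable
from .graph import DirectedGraph

__all__ = [
    "VariableSpec",
    "GroundTruthNetwork",
    "default_ground_truth",
    "sample_cohort",
    "exact_marginal",
    "network_to_json",
]

OUTCOME = "np"

BINARY = ("0", "1")
ORDINAL3 = ("1", "2", "3")


@dataclass(frozen=True)
class VariableSpec:
    """A named categorical variable with an ordered state list."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(f"{self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"{self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A DAG plus one CPT per variable: the data-generating process."""

    variables: tuple[VariableSpec, ...]
    dag: DirectedGraph
    cpts: dict[str, ConditionalProbabilityTable]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if set(names) != set(self.dag.nodes):
            raise ValueError("variables and DAG nodes differ")
        if not self.dag.is_acyclic():
            raise ValueError("ground-truth DAG must be acyclic")
        for var in self.variables:
            if var.name not in self.cpts:
                raise ValueError(f"missing CPT for {var.name!r}")
            cpt = self.cpts[var.name]
            if tuple(sorted(cpt.parents)) != tuple(sorted(self.dag.parents(var.name))):
                raise ValueError(
                    f"CPT parents for {var.name!r} do not match DAG parents"
                )
            if cpt.child_states != var.states:
                raise ValueError(f"CPT states for {var.name!r} do not match spec")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise ValueError(f"unknown variable {name!r}")


def _cpt(
    child: str,
    child_states: Sequence[str],
    parents: Sequence[tuple[str, Sequence[str]]],
    rows: Sequence[Sequence[float]],
) -> ConditionalProbabilityTable:
    return ConditionalProbabilityTable(
        child=child,
        parents=tuple(name for name, _ in parents),
        child_states=tuple(child_states),
        parent_states=tuple(tuple(states) for _, states in parents),
        probs=np.asarray(rows, dtype=float),
    )


def _binary_rows(p_one: Sequence[float]) -> list[list[float]]:
    return [[1.0 - p, p] for p in p_one]


# Intercept of the logistic outcome model, fixed so that the exact
# marginal P(np=1) of the default network is 0.152 (see exact_marginal).
_NP_INTERCEPT = -3.7537229
_NP_SLOPES = {"pbg": 0.85, "ptb": 1.10, "afc": 0.80, "p": 0.50}


def _np_rows() -> list[list[float]]:
    rows = []
    for pbg, ptb, afc, p in itertools.product(range(3), range(2), range(3), range(2)):
        logit = (
            _NP_INTERCEPT
            + _NP_SLOPES["pbg"] * pbg
            + _NP_SLOPES["ptb"] * ptb
            + _NP_SLOPES["afc"] * afc
            + _NP_SLOPES["p"] * p
        )
        prob = 1.0 / (1.0 + math.exp(-logit))
        rows.append([1.0 - prob, prob])
    return rows


def default_ground_truth() -> GroundTruthNetwork:
    """The fixed 17-variable ground-truth network (version 1).

    Returns the same network on every call; all CPT constants are
    committed literals except the outcome row, which is a logistic
    function of (pbg, ptb, afc, p) with a frozen intercept.
    """
    variables = (
        VariableSpec("age", ORDINAL3),
        VariableSpec("pbg", ORDINAL3),
        VariableSpec("p", BINARY),
        VariableSpec("hdop", BINARY),
        VariableSpec("ptb", BINARY),
        VariableSpec("prom", BINARY),
        VariableSpec("ms", BINARY),
        VariableSpec("nrds", BINARY),
        VariableSpec("nnj", BINARY),
        VariableSpec("pph", BINARY),
        VariableSpec("na", BINARY),
        VariableSpec("ngr", BINARY),
        VariableSpec("g", ORDINAL3),
        VariableSpec("afv", ORDINAL3),
        VariableSpec("afc", ORDINAL3),
        VariableSpec("crp", ORDINAL3),
        VariableSpec("np", BINARY),
    )
    edges = [
        ("age", "pbg"),
        ("g", "p"),
        ("g", "afv"),
        ("afv", "afc"),
        ("pbg", "hdop"),
        ("pbg", "ms"),
        ("pbg", "prom"),
        ("prom", "ptb"),
        ("afc", "crp"),
        ("pbg", "np"),
        ("ptb", "np"),
        ("afc", "np"),
        ("p", "np"),
        ("np", "nrds"),
        ("ptb", "nrds"),
        ("np", "nnj"),
        ("afc", "nnj"),
        ("np", "na"),
        ("np", "ngr"),
        ("np", "pph"),
        ("ms", "pph"),
    ]
    dag = DirectedGraph([v.name for v in variables], edges)

    a3 = [("age", ORDINAL3)]
    cpts = {
        "age": _cpt("age", ORDINAL3, [], [[0.30, 0.50, 0.20]]),
        "g": _cpt("g", ORDINAL3, [], [[0.45, 0.35, 0.20]]),
        "pbg": _cpt(
            "pbg", ORDINAL3, a3,
            [[0.70, 0.22, 0.08], [0.32, 0.42, 0.26], [0.10, 0.32, 0.58]],
        ),
        "p": _cpt(
            "p", BINARY, [("g", ORDINAL3)], _binary_rows([0.15, 0.55, 0.80])
        ),
        "afv": _cpt(
            "afv", ORDINAL3, [("g", ORDINAL3)],
            [[0.78, 0.16, 0.06], [0.42, 0.34, 0.24], [0.18, 0.36, 0.46]],
        ),
        "afc": _cpt(
            "afc", ORDINAL3, [("afv", ORDINAL3)],
            [[0.80, 0.15, 0.05], [0.35, 0.42, 0.23], [0.10, 0.38, 0.52]],
        ),
        "hdop": _cpt(
            "hdop", BINARY, [("pbg", ORDINAL3)], _binary_rows([0.05, 0.20, 0.45])
        ),
        "ms": _cpt(
            "ms", BINARY, [("pbg", ORDINAL3)], _binary_rows([0.04, 0.16, 0.48])
        ),
        "prom": _cpt(
            "prom", BINARY, [("pbg", ORDINAL3)], _binary_rows([0.10, 0.25, 0.45])
        ),
        "ptb": _cpt(
            "ptb", BINARY, [("prom", BINARY)], _binary_rows([0.08, 0.40])
        ),
        "crp": _cpt(
            "crp", ORDINAL3, [("afc", ORDINAL3)],
            [[0.75, 0.19, 0.06], [0.35, 0.41, 0.24], [0.12, 0.36, 0.52]],
        ),
        "np": _cpt(
            "np", BINARY,
            [("pbg", ORDINAL3), ("ptb", BINARY), ("afc", ORDINAL3), ("p", BINARY)],
            _np_rows(),
        ),
        "nrds": _cpt(
            "nrds", BINARY, [("np", BINARY), ("ptb", BINARY)],
            _binary_rows([0.03, 0.15, 0.25, 0.55]),
        ),
        "nnj": _cpt(
            "nnj", BINARY, [("np", BINARY), ("afc", ORDINAL3)],
            _binary_rows([0.12, 0.20, 0.28, 0.62, 0.72, 0.80]),
        ),
        "na": _cpt("na", BINARY, [("np", BINARY)], _binary_rows([0.02, 0.18])),
        "ngr": _cpt("ngr", BINARY, [("np", BINARY)], _binary_rows([0.05, 0.28])),
        "pph": _cpt(
            "pph", BINARY, [("np", BINARY), ("ms", BINARY)],
            _binary_rows([0.04, 0.12, 0.12, 0.30]),
        ),
    }
    return GroundTruthNetwork(variables=variables, dag=dag, cpts=cpts)


def sample_cohort(
    network: GroundTruthNetwork,
    n: int,
    seed: int,
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw ``n`` records by ancestral sampling.

    Nodes are visited in ``order`` (any topological order of the DAG;
    defaults to the deterministic one).  For a fixed (network, n, seed)
    and order the result is byte-identical across runs; any valid order
    yields the same distribution.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0; got {n}")
    if order is None:
        order = network.dag.topological_order()
    else:
        order = list(order)
        if sorted(order) != sorted(network.dag.nodes):
            raise ValueError("order must be a permutation of the network nodes")
        position = {node: i for i, node in enumerate(order)}
        for u, v in network.dag.directed_edges:
            if position[u] > position[v]:
                raise ValueError(f"order is not topological: {u!r} after {v!r}")

    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}  # node -> int codes
    for node in order:
        cpt = network.cpts[node]
        if cpt.parents:
            config = np.zeros(n, dtype=np.int64)
            for parent, p_states in zip(cpt.parents, cpt.parent_states):
                config = config * len(p_states) + columns[parent]
            probs = cpt.probs[config]
        else:
            probs = np.broadcast_to(cpt.probs[0], (n, cpt.probs.shape[1]))
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        columns[node] = (u[:, None] > cum[:, :-1]).sum(axis=1)

    data = {
        name: pd.Categorical.from_codes(
            columns[name] if n else np.empty(0, dtype=np.int64),
            categories=list(network.spec(name).states),
        ).astype(str)
        for name in network.names
    }
    return pd.DataFrame(data, columns=network.names, dtype=str)


def exact_marginal(network: GroundTruthNetwork, variable: str) -> dict[str, float]:
    """Exact marginal distribution of one variable by enumeration.

    Enumerates the joint over the variable's ancestral set (the variable
    plus all its ancestors), which is closed under the parent relation,
    and sums out everything else.
    """
    closure = network.dag.ancestors(variable) | {variable}
    order = [n for n in network.dag.topological_order() if n in closure]
    states = {n: network.spec(n).states for n in order}
    target = network.spec(variable)
    marginal = {s: 0.0 for s in target.states}
    for combo in itertools.product(*(states[n] for n in order)):
        assignment = dict(zip(order, combo))
        prob = 1.0
        for node in order:
            prob *= network.cpts[node].prob(assignment[node], assignment)
        marginal[assignment[variable]] += prob
    return marginal


def network_to_json(network: GroundTruthNetwork) -> str:
    """Serialize {variables, edges, cpts} as a JSON document."""
    doc = {
        "variables": [
            {"name": v.name, "states": list(v.states)} for v in network.variables
        ],
        "edges": [list(e) for e in network.dag.directed_edges],
        "cpts": {
            name: {
                "parents": list(cpt.parents),
                "probs": cpt.probs.tolist(),
            }
            for name, cpt in network.cpts.items()
        },
    }
    return json.dumps(doc, indent=2)
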