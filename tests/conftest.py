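"""Shared fixtures: the default ground-truth network, sampled cohorts,
and small hand-built tables used across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cohortbn.bn import ConditionalProbabilityTable
from cohortbn.graph import DirectedGraph
from cohortbn.synthetic import (
    GroundTruthNetwork,
    VariableSpec,
    default_ground_truth,
    sample_cohort,
)

COHORT_SEED = 42  # the documented seed for the n=2008 reference cohort


@pytest.fixture(scope="session")
def default_net() -> GroundTruthNetwork:
    return default_ground_truth()


@pytest.fixture(scope="session")
def cohort_2008(default_net) -> pd.DataFrame:
    return sample_cohort(default_net, 2008, COHORT_SEED)


def make_chain_network(
    p_a: float = 0.3, p_b: tuple[float, float] = (0.2, 0.8),
    p_c: tuple[float, float] = (0.1, 0.7),
) -> GroundTruthNetwork:
    """Binary chain A→B→C with hand-set CPTs.

    ``p_b[i]`` is P(B=1 | A=i); ``p_c[i]`` is P(C=1 | B=i).
    """
    binary = ("0", "1")
    variables = (
        VariableSpec("A", binary),
        VariableSpec("B", binary),
        VariableSpec("C", binary),
    )
    dag = DirectedGraph(["A", "B", "C"], [("A", "B"), ("B", "C")])
    cpts = {
        "A": ConditionalProbabilityTable(
            "A", (), binary, (), np.array([[1 - p_a, p_a]])
        ),
        "B": ConditionalProbabilityTable(
            "B", ("A",), binary, (binary,),
            np.array([[1 - p_b[0], p_b[0]], [1 - p_b[1], p_b[1]]]),
        ),
        "C": ConditionalProbabilityTable(
            "C", ("B",), binary, (binary,),
            np.array([[1 - p_c[0], p_c[0]], [1 - p_c[1], p_c[1]]]),
        ),
    }
    return GroundTruthNetwork(variables=variables, dag=dag, cpts=cpts)


@pytest.fixture
def chain_net() -> GroundTruthNetwork:
    return make_chain_network()


def make_collider_network(
    p_a: float = 0.5, p_b: float = 0.5,
    p_c: tuple[float, float, float, float] = (0.05, 0.8, 0.8, 0.95),
) -> GroundTruthNetwork:
    """Binary collider A→C←B; ``p_c`` is P(C=1 | A, B) in (A,B) mixed-
    radix order (00, 01, 10, 11)."""
    binary = ("0", "1")
    variables = (
        VariableSpec("A", binary),
        VariableSpec("B", binary),
        VariableSpec("C", binary),
    )
    dag = DirectedGraph(["A", "B", "C"], [("A", "C"), ("B", "C")])
    cpts = {
        "A": ConditionalProbabilityTable(
            "A", (), binary, (), np.array([[1 - p_a, p_a]])
        ),
        "B": ConditionalProbabilityTable(
            "B", (), binary, (), np.array([[1 - p_b, p_b]])
        ),
        "C": ConditionalProbabilityTable(
            "C", ("A", "B"), binary, (binary, binary),
            np.array([[1 - p, p] for p in p_c]),
        ),
    }
    return GroundTruthNetwork(variables=variables, dag=dag, cpts=cpts)


KDB_TRUE_PARENTS = {
    "X1": (),
    "X2": ("X1",),
    "X3": ("X1", "X2"),
    "X4": ("X2", "X3"),
    "X5": ("X3", "X4"),
}

# class-coupling strengths solved (by exact enumeration) so that the
# true MI(Xi; y) is strictly decreasing in i: 0.52/0.40/0.29/0.20/0.13
# bits — this makes the MI attribute ordering identifiable at large n
_KDB_CLASS_COUPLING = (2.1589, 1.1077, 0.1649, 0.045, -0.0404)
_KDB_PARENT_COUPLING = 1.0


def make_kdb_ground_truth() -> GroundTruthNetwork:
    """A binary KDB(2) generating model over class y and X1..X5.

    Each attribute is a logistic function of the class and of its
    at-most-two attribute parents (chain-of-pairs pattern), with strong
    parent couplings so the generating parent sets are recoverable.
    """
    import itertools
    import math

    binary = ("0", "1")
    names = ["y", "X1", "X2", "X3", "X4", "X5"]
    edges = [("y", x) for x in names[1:]]
    for x, ps in KDB_TRUE_PARENTS.items():
        edges.extend((p, x) for p in ps)
    dag = DirectedGraph(names, edges)
    cpts = {
        "y": ConditionalProbabilityTable(
            "y", (), binary, (), np.array([[0.5, 0.5]])
        )
    }
    for i, x in enumerate(names[1:]):
        parents = ("y",) + KDB_TRUE_PARENTS[x]
        rows = []
        for combo in itertools.product((0, 1), repeat=len(parents)):
            z = _KDB_CLASS_COUPLING[i] * (2 * combo[0] - 1)
            z += _KDB_PARENT_COUPLING * sum(2 * v - 1 for v in combo[1:])
            p_one = 1.0 / (1.0 + math.exp(-z))
            rows.append([1.0 - p_one, p_one])
        cpts[x] = ConditionalProbabilityTable(
            x, parents, binary, tuple(binary for _ in parents), np.array(rows)
        )
    return GroundTruthNetwork(
        variables=tuple(VariableSpec(n, binary) for n in names),
        dag=dag,
        cpts=cpts,
    )


def random_cohort(
    n_attributes: int, n_rows: int, seed: int, cardinality: int = 2
) -> pd.DataFrame:
    """A random categorical table with a binary class column ``y``.

    Attributes carry a mild dependence on the class so that MI/CMI
    rankings are non-degenerate.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n_rows)
    data = {"y": y.astype(str)}
    for j in range(n_attributes):
        shift = rng.uniform(-0.3, 0.3)
        probs = rng.dirichlet(np.ones(cardinality), size=2)
        mixed = np.clip(probs + shift * (rng.random(cardinality) - 0.5), 0.01, None)
        mixed = mixed / mixed.sum(axis=1, keepdims=True)
        draws = np.empty(n_rows, dtype=np.int64)
        for cls in (0, 1):
            mask = y == cls
            draws[mask] = rng.choice(
                cardinality, size=mask.sum(), p=mixed[cls]
            )
        data[f"x{j + 1}"] = draws.astype(str)
    return pd.DataFrame(data, dtype=str)
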