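"""NB / TAN / KDB construction and prediction, checked against hand
Bayes-rule computations, exhaustive spanning-tree enumeration, the
hand-executed KDB parent-selection rule, and structure recovery from
known generating models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cohortbn.bn import ConditionalProbabilityTable, class_posterior
from cohortbn.classifiers import (
    count_dependencies,
    log_likelihood,
    maximum_weight_spanning_tree,
    model_from_json,
    model_to_json,
    predict,
    train_kdb,
    train_nb,
    train_tan,
)
from cohortbn.graph import DirectedGraph
from cohortbn.synthetic import GroundTruthNetwork, VariableSpec, sample_cohort
from conftest import random_cohort
from oracles import (
    conditional_mutual_information_bits,
    enumeration_posterior,
    max_weight_tree_weight,
    mutual_information_bits,
)


def binary_cpt(child, parents, parent_cards, p_one):
    states = ("0", "1")
    return ConditionalProbabilityTable(
        child, tuple(parents), states,
        tuple(states for _ in parents),
        np.array([[1 - p, p] for p in p_one]),
    )


class TestNaiveBayes:
    def test_hand_bayes_rule_single_attribute(self):
        # counts: y=0: a=0 x30, a=1 x10; y=1: a=0 x20, a=1 x40
        rows = (
            [("0", "0")] * 30 + [("1", "0")] * 10
            + [("0", "1")] * 20 + [("1", "1")] * 40
        )
        table = pd.DataFrame(rows, columns=["a", "y"], dtype=str)
        model = train_nb(table, "y", ["a"], smoothing=0.0)
        post = class_posterior(model, {"a": "0"})
        # P(y=0|a=0) = (0.4 * 0.75) / (0.4 * 0.75 + 0.6 * 1/3)
        expected = (0.4 * 0.75) / (0.4 * 0.75 + 0.6 * (20 / 60))
        assert post["0"] == pytest.approx(expected, abs=1e-12)
        assert predict(model, {"a": "0"}).predicted_class == "0"

    def test_constant_attributes_return_the_prior(self):
        table = pd.DataFrame(
            {"a": ["0"] * 40, "b": ["1"] * 40,
             "y": ["0"] * 25 + ["1"] * 15},
            dtype=str,
        )
        model = train_nb(table, "y", ["a", "b"], smoothing=0.0)
        post = class_posterior(model, {"a": "0", "b": "1"})
        assert post["0"] == pytest.approx(25 / 40)

    def test_class_var_cannot_be_an_attribute(self):
        table = random_cohort(2, 30, seed=1)
        with pytest.raises(ValueError):
            train_nb(table, "y", ["x1", "y"])

    def test_class_is_parent_of_every_attribute(self):
        table = random_cohort(3, 100, seed=2)
        model = train_nb(table, "y", ["x1", "x2", "x3"])
        for a in model.attributes:
            assert model.dag.parents(a) == ["y"]


class TestTan:
    def test_two_attributes_forced_single_edge(self):
        table = random_cohort(2, 100, seed=3)
        model = train_tan(table, "y", ["x1", "x2"])
        assert len(model.attribute_edges()) == 1
        assert {u for e in model.attribute_edges() for u in e} == {"x1", "x2"}

    def test_fewer_than_two_attributes_rejected(self):
        table = random_cohort(1, 50, seed=4)
        with pytest.raises(ValueError, match="at least 2"):
            train_tan(table, "y", ["x1"])

    @pytest.mark.parametrize("n_nodes", [4, 5])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_mwst_matches_exhaustive_enumeration(self, n_nodes, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"v{i}" for i in range(n_nodes)]
        weights = {
            frozenset(pair): float(rng.random())
            for pair in itertools.combinations(nodes, 2)
        }
        tree = maximum_weight_spanning_tree(nodes, weights)
        got = sum(weights[frozenset(e)] for e in tree)
        assert got == pytest.approx(max_weight_tree_weight(nodes, weights))

    def test_attribute_edges_form_a_tree_with_n_minus_1_edges(self, cohort_2008):
        attrs = [c for c in cohort_2008.columns if c != "np"]
        model = train_tan(cohort_2008, "np", attrs)
        edges = model.attribute_edges()
        assert len(edges) == len(attrs) - 1
        # every attribute has at most one attribute parent
        for a in attrs:
            attr_parents = [p for p in model.dag.parents(a) if p != "np"]
            assert len(attr_parents) <= 1
        assert model.dag.is_acyclic()

    def test_recovers_generating_tree_skeleton(self):
        # ground truth: class y, augmenting edges X1->X2, X2->X3
        binary = ("0", "1")
        variables = tuple(
            VariableSpec(n, binary) for n in ("y", "X1", "X2", "X3")
        )
        dag = DirectedGraph(
            ["y", "X1", "X2", "X3"],
            [("y", "X1"), ("y", "X2"), ("y", "X3"),
             ("X1", "X2"), ("X2", "X3")],
        )
        cpts = {
            "y": binary_cpt("y", [], [], [0.5]),
            "X1": binary_cpt("X1", ["y"], [2], [0.2, 0.8]),
            "X2": binary_cpt("X2", ["y", "X1"], [2, 2], [0.1, 0.9, 0.2, 0.8]),
            "X3": binary_cpt("X3", ["y", "X2"], [2, 2], [0.15, 0.85, 0.1, 0.9]),
        }
        net = GroundTruthNetwork(variables=variables, dag=dag, cpts=cpts)
        table = sample_cohort(net, 5000, seed=13)
        model = train_tan(table, "y", ["X1", "X2", "X3"])
        skeleton = {frozenset(e) for e in model.attribute_edges()}
        assert skeleton == {
            frozenset(("X1", "X2")), frozenset(("X2", "X3")),
        }

    def test_explicit_root_is_respected(self):
        table = random_cohort(3, 200, seed=5)
        model = train_tan(table, "y", ["x1", "x2", "x3"], root="x2")
        assert [p for p in model.dag.parents("x2") if p != "y"] == []


class TestKdb:
    def test_k0_identical_posteriors_to_nb(self):
        table = random_cohort(4, 300, seed=6)
        attrs = ["x1", "x2", "x3", "x4"]
        nb = train_nb(table, "y", attrs)
        kdb0 = train_kdb(table, "y", attrs, k=0)
        for combo in itertools.product("01", repeat=4):
            evidence = dict(zip(attrs, combo))
            p_nb = class_posterior(nb, evidence)
            p_kdb = class_posterior(kdb0, evidence)
            for state in p_nb:
                assert p_kdb[state] == pytest.approx(p_nb[state], abs=1e-12)

    def test_saturated_k_gives_full_parent_sets(self):
        table = random_cohort(4, 300, seed=7)
        attrs = ["x1", "x2", "x3", "x4"]
        model = train_kdb(table, "y", attrs, k=3)
        n_parents = sorted(
            len([p for p in model.dag.parents(a) if p != "y"]) for a in attrs
        )
        assert n_parents == [0, 1, 2, 3]

    def test_k_out_of_range_rejected(self):
        table = random_cohort(3, 50, seed=8)
        for bad_k in (-1, 3):
            with pytest.raises(ValueError, match="k must be"):
                train_kdb(table, "y", ["x1", "x2", "x3"], k=bad_k)

    def test_parent_sets_match_hand_executed_selection_rule(self):
        table = random_cohort(3, 400, seed=9, cardinality=2)
        attrs = ["x1", "x2", "x3"]
        model = train_kdb(table, "y", attrs, k=1)
        # oracle: brute-force MI/CMI, then apply the rule by hand
        mi = {
            a: mutual_information_bits(
                list(zip(table[a], table["y"]))
            )
            for a in attrs
        }
        order = sorted(attrs, key=lambda a: (-mi[a], a))
        expected_parents = {order[0]: set()}
        for i, a in enumerate(order[1:], start=1):
            cmi = {
                b: conditional_mutual_information_bits(
                    list(zip(table[a], table[b], table["y"]))
                )
                for b in order[:i]
            }
            best = sorted(order[:i], key=lambda b: (-cmi[b], b))[0]
            expected_parents[a] = {best}
        for a in attrs:
            got = {p for p in model.dag.parents(a) if p != "y"}
            assert got == expected_parents[a]

    def test_arc_count_matches_closed_form(self, cohort_2008):
        attrs = [c for c in cohort_2008.columns if c != "np"]
        model = train_kdb(cohort_2008, "np", attrs, k=2)
        assert len(model.attribute_edges()) == count_dependencies(len(attrs), 2)


class TestCountDependencies:
    @pytest.mark.parametrize(
        "n, k, expected",
        [(17, 1, 16), (17, 2, 31), (17, 0, 0), (5, 4, 10), (1, 0, 0)],
    )
    def test_closed_form(self, n, k, expected):
        assert count_dependencies(n, k) == expected

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            count_dependencies(5, 5)
        with pytest.raises(ValueError):
            count_dependencies(5, -1)


class TestPredict:
    def test_tie_broken_by_class_state_order(self):
        table = pd.DataFrame(
            {"a": ["0", "1", "0", "1"], "y": ["0", "0", "1", "1"]}, dtype=str
        )
        model = train_nb(table, "y", ["a"], smoothing=0.0)
        pred = predict(model, {"a": "0"})
        assert pred.posterior["0"] == pytest.approx(0.5)
        assert pred.predicted_class == "0"

    @pytest.mark.parametrize("variant", ["nb", "tan", "kdb"])
    def test_argmax_agrees_with_enumeration_oracle(self, variant):
        table = random_cohort(4, 400, seed=10)
        attrs = ["x1", "x2", "x3", "x4"]
        if variant == "nb":
            model = train_nb(table, "y", attrs)
        elif variant == "tan":
            model = train_tan(table, "y", attrs)
        else:
            model = train_kdb(table, "y", attrs, k=2)
        for combo in itertools.product("01", repeat=4):
            evidence = dict(zip(attrs, combo))
            oracle = enumeration_posterior(model, evidence)
            pred = predict(model, evidence)
            assert pred.posterior[pred.predicted_class] == pytest.approx(
                max(oracle.values()), abs=1e-9
            )

    def test_missing_attribute_is_an_error(self):
        table = random_cohort(2, 50, seed=11)
        model = train_nb(table, "y", ["x1", "x2"])
        with pytest.raises(ValueError, match="x1"):
            predict(model, {"x2": "0"})


class TestModelFamilyNesting:
    def test_training_likelihood_never_decreases_with_capacity(self):
        # complete table (every config observed) so smoothing 0 is safe
        table = random_cohort(4, 600, seed=12)
        attrs = ["x1", "x2", "x3", "x4"]
        ll = {}
        ll["nb"] = log_likelihood(train_nb(table, "y", attrs, 0.0), table)
        ll["tan"] = log_likelihood(train_tan(table, "y", attrs, 0.0), table)
        for k in (0, 1, 2, 3):
            ll[f"kdb{k}"] = log_likelihood(
                train_kdb(table, "y", attrs, k, 0.0), table
            )
        assert ll["tan"] >= ll["nb"] - 1e-9
        assert ll["kdb0"] == pytest.approx(ll["nb"], abs=1e-9)
        for k in (0, 1, 2):
            assert ll[f"kdb{k + 1}"] >= ll[f"kdb{k}"] - 1e-9


class TestSerialization:
    def test_round_trip_preserves_posteriors(self):
        table = random_cohort(3, 200, seed=13)
        model = train_tan(table, "y", ["x1", "x2", "x3"])
        restored = model_from_json(model_to_json(model))
        assert restored.variant == "tan"
        assert restored.dag.directed_edges == model.dag.directed_edges
        for combo in itertools.product("01", repeat=3):
            evidence = dict(zip(["x1", "x2", "x3"], combo))
            a = class_posterior(model, evidence)
            b = class_posterior(restored, evidence)
            for state in a:
                assert b[state] == pytest.approx(a[state], abs=1e-12)
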