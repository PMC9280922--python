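import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import xlogy

from dbnpsy import (
    DAGStructure,
    family_bic,
    family_loglik,
    fit_cpts,
    network_score,
    predict_posterior_mode,
    temporal_constraints,
)
from dbnpsy.bn_core import CPTSet, ConstraintSet, NodeCPT, predict_posterior_mode_many

LN4 = float(np.log(4))


# ------------------------------------------------------------ constraints


def test_temporal_constraints_permitted_space_is_w1_cross_w2():
    cons = temporal_constraints(["a@W1", "b@W1"], ["a@W2", "b@W2"])
    nodes = ["a@W1", "b@W1", "a@W2", "b@W2"]
    permitted = set(cons.permitted_arcs(nodes))
    assert permitted == {
        (p, c) for p in ("a@W1", "b@W1") for c in ("a@W2", "b@W2")
    }
    assert ("a@W2", "a@W1") in cons.blacklist  # backward
    assert ("a@W1", "b@W1") in cons.blacklist  # within wave 1
    assert ("a@W2", "b@W2") in cons.blacklist  # within wave 2


def test_temporal_constraints_static_is_parent_only():
    cons = temporal_constraints(["a@W1"], ["a@W2"], ["twin"])
    nodes = ["a@W1", "a@W2", "twin"]
    permitted = set(cons.permitted_arcs(nodes))
    assert permitted == {("a@W1", "a@W2"), ("twin", "a@W2")}


def test_temporal_constraints_rejects_overlapping_sets():
    with pytest.raises(ValueError, match="overlap"):
        temporal_constraints(["x"], ["x"])


def test_constraintset_rejects_black_and_whitelisted_arc():
    with pytest.raises(ValueError):
        ConstraintSet(blacklist=frozenset({("a", "b")}), whitelist=frozenset({("a", "b")}))


# ---------------------------------------------------------------- scoring


@pytest.mark.parametrize(
    "column, parents, expected",
    [
        ([1, 1, 1, 1], [], 0.0),                       # constant: log 1 = 0
        ([1, 1, 0, 0], [], 4 * np.log(0.5)),           # = -2.7725887
        ([0, 1, 0, 1], ["p"], 0.0),                    # child copies its parent
    ],
)
def test_family_loglik_hand_values(column, parents, expected):
    panel = pd.DataFrame({"x": column, "p": column})
    assert family_loglik("x", parents, panel) == pytest.approx(expected, abs=1e-12)


def test_family_bic_hand_values():
    panel = pd.DataFrame({"x": [1, 1, 0, 0], "c": [1, 1, 1, 1]})
    assert family_bic("c", [], panel) == pytest.approx(-0.5 * LN4, abs=1e-12)
    assert family_bic("x", [], panel) == pytest.approx(4 * np.log(0.5) - 0.5 * LN4, abs=1e-12)


def test_family_loglik_rejects_self_parent():
    panel = pd.DataFrame({"x": [0, 1]})
    with pytest.raises(ValueError, match="own parents"):
        family_loglik("x", ["x"], panel)


def test_independent_parent_lowers_bic_in_expectation():
    """An irrelevant random parent costs (1/2) log N against an O(1) gain."""
    rng = np.random.default_rng(42)
    deltas = []
    for _ in range(40):
        panel = pd.DataFrame(rng.integers(0, 2, (200, 2)), columns=["x", "z"])
        deltas.append(family_bic("x", ["z"], panel) - family_bic("x", [], panel))
    assert np.mean(deltas) < 0


def _bruteforce_score(dag, panel):
    """Independent per-family recomputation with pandas groupby."""
    total = 0.0
    n = len(panel)
    for node in dag.nodes:
        parents = list(dag.parents(node))
        if parents:
            ll = 0.0
            for _, grp in panel.groupby(parents):
                counts = grp[node].value_counts().to_numpy(dtype=float)
                ll += float(xlogy(counts, counts).sum() - xlogy(counts.sum(), counts.sum()))
        else:
            counts = panel[node].value_counts().to_numpy(dtype=float)
            ll = float(xlogy(counts, counts).sum() - xlogy(n, n))
        total += ll - 0.5 * (2 ** len(parents)) * np.log(n)
    return total


def test_network_score_matches_bruteforce_on_all_three_node_dags():
    """Every acyclic 3-node graph scores identically to a from-scratch oracle."""
    rng = np.random.default_rng(3)
    panel = pd.DataFrame(rng.integers(0, 2, (40, 3)), columns=["x", "y", "z"])
    pairs = [(a, b) for a in "xyz" for b in "xyz" if a != b]
    n_dags = 0
    for keep in itertools.product([0, 1], repeat=6):
        arcs = [p for p, k in zip(pairs, keep) if k]
        try:
            dag = DAGStructure.from_arcs("xyz", arcs)
        except ValueError:
            continue  # cyclic
        n_dags += 1
        assert network_score(dag, panel) == pytest.approx(
            _bruteforce_score(dag, panel), abs=1e-9
        )
    assert n_dags == 25  # the number of DAGs on 3 labeled nodes


def test_network_score_decomposability_is_exact():
    rng = np.random.default_rng(7)
    panel = pd.DataFrame(rng.integers(0, 2, (100, 4)), columns=list("wxyz"))
    base = DAGStructure.from_arcs("wxyz", [("w", "y")])
    more = DAGStructure.from_arcs("wxyz", [("w", "y"), ("x", "y")])
    delta_network = network_score(more, panel) - network_score(base, panel)
    delta_family = family_bic("y", ["w", "x"], panel) - family_bic("y", ["w"], panel)
    # only y's family term differs; agreement up to summation rounding
    assert delta_network == pytest.approx(delta_family, abs=1e-9)


def test_scores_invariant_to_row_order():
    rng = np.random.default_rng(11)
    panel = pd.DataFrame(rng.integers(0, 2, (60, 3)), columns=["a", "b", "c"])
    shuffled = panel.sample(frac=1, random_state=5)
    dag = DAGStructure.from_arcs(["a", "b", "c"], [("a", "c"), ("b", "c")])
    assert network_score(dag, panel) == pytest.approx(
        network_score(dag, shuffled), abs=1e-9
    )


def test_dag_rejects_cycles_and_unknown_nodes():
    with pytest.raises(ValueError, match="cycle"):
        DAGStructure.from_arcs("ab", [("a", "b"), ("b", "a")])
    with pytest.raises(ValueError, match="unknown node"):
        DAGStructure.from_arcs("ab", [("a", "q")])


# ------------------------------------------------------------------- CPTs


def test_fit_cpts_dirichlet_posterior_mean():
    # counts 3 vs 1, no parents, iss=1 -> alpha = 0.5 per cell -> 3.5/5
    panel = pd.DataFrame({"x": [1, 1, 1, 0]})
    cpts = fit_cpts(DAGStructure.from_arcs(["x"], []), panel, iss=1.0)
    assert cpts["x"].table[0, 1] == pytest.approx(0.7)
    assert cpts["x"].table[0, 0] == pytest.approx(0.3)


def test_fit_cpts_unseen_configuration_is_uniform():
    panel = pd.DataFrame({"p": [0, 0, 0, 0], "x": [1, 0, 1, 0]})
    dag = DAGStructure.from_arcs(["p", "x"], [("p", "x")])
    cpts = fit_cpts(dag, panel, iss=1.0)
    np.testing.assert_allclose(cpts["x"].table[1], [0.5, 0.5])  # p=1 never seen


def test_fit_cpts_small_iss_limit_recovers_frequencies():
    panel = pd.DataFrame({"x": [1, 1, 1, 0]})
    dag = DAGStructure.from_arcs(["x"], [])
    cpts = fit_cpts(dag, panel, iss=1e-9)
    assert cpts["x"].table[0, 1] == pytest.approx(0.75, abs=1e-9)


def test_fit_cpts_rows_sum_to_one_and_stay_interior():
    rng = np.random.default_rng(9)
    for _ in range(10):
        panel = pd.DataFrame(rng.integers(0, 2, (30, 3)), columns=["a", "b", "c"])
        dag = DAGStructure.from_arcs(["a", "b", "c"], [("a", "c"), ("b", "c")])
        cpts = fit_cpts(dag, panel, iss=1.0)
        for node in "abc":
            t = cpts[node].table
            np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)
            assert ((t > 0) & (t < 1)).all()


def test_fit_cpts_rejects_nonpositive_iss():
    panel = pd.DataFrame({"x": [0, 1]})
    with pytest.raises(ValueError, match="imaginary sample size"):
        fit_cpts(DAGStructure.from_arcs(["x"], []), panel, iss=0)


# ------------------------------------------------------------- prediction


def test_predict_posterior_mode_argmax_and_tie_rule():
    cpt = CPTSet(
        cpts={
            "y": NodeCPT("y", (), np.array([[0.3, 0.7]])),
            "t": NodeCPT("t", (), np.array([[0.5, 0.5]])),
        }
    )
    assert predict_posterior_mode(cpt, "y", {}) == (1, 0.7)
    assert predict_posterior_mode(cpt, "t", {}) == (0, 0.5)  # tie breaks to 0


def test_predict_posterior_mode_requires_all_parents():
    panel = pd.DataFrame({"p": [0, 1, 0, 1], "x": [0, 1, 0, 1]})
    dag = DAGStructure.from_arcs(["p", "x"], [("p", "x")])
    cpts = fit_cpts(dag, panel)
    with pytest.raises(KeyError, match="p"):
        predict_posterior_mode(cpts, "x", {})
    value, prob = predict_posterior_mode(cpts, "x", {"p": 1})
    assert value == 1 and prob > 0.5


def test_parentless_low_prevalence_node_predicts_zero():
    panel = pd.DataFrame({"x": [1] * 20 + [0] * 80})
    cpts = fit_cpts(DAGStructure.from_arcs(["x"], []), panel)
    assert predict_posterior_mode(cpts, "x", {})[0] == 0
    preds = predict_posterior_mode_many(cpts, "x", panel)
    assert (preds == 0).all()


# ---------------------------------------------------------- serialization


def test_dag_and_cpt_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(13)
    panel = pd.DataFrame(rng.integers(0, 2, (50, 3)), columns=["a@W1", "b@W1", "a@W2"])
    dag = DAGStructure.from_arcs(panel.columns, [("a@W1", "a@W2"), ("b@W1", "a@W2")])
    tsv = tmp_path / "net.tsv"
    dag.to_tsv(tsv)
    assert DAGStructure.from_tsv(tsv, panel.columns).arcs == dag.arcs

    dot = dag.to_dot(strengths={("a@W1", "a@W2"): 0.98})
    assert '"a@W1" -> "a@W2" [label="98%"' in dot

    cpts = fit_cpts(dag, panel)
    jpath = tmp_path / "cpts.json"
    cpts.to_json(jpath)
    loaded = CPTSet.from_json(jpath)
    for node in panel.columns:
        np.testing.assert_allclose(loaded[node].table, cpts[node].table)
        assert loaded[node].parents == cpts[node].parents
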