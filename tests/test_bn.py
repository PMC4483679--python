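"""Bayesian-network scoring, search, parameters and exact inference."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import enumerate_joint_bruteforce
from tempmort import bn


class TestDag:
    def test_cycle_rejected(self):
        d = bn.Dag({"A": ["0", "1"], "B": ["0", "1"]}, [("A", "B")])
        with pytest.raises(ValueError):
            d.add_edge("B", "A")

    def test_reverse_preserves_acyclicity(self):
        states = {n: ["0", "1"] for n in "ABC"}
        d = bn.Dag(states, [("A", "B"), ("B", "C"), ("A", "C")])
        # reversing A->B gives B->A with B->C, A->C: still acyclic
        assert d.can_reverse("A", "B")
        # reversing A->C gives C->A with A->B->C: cycle
        assert not d.can_reverse("A", "C")

    def test_parents_sorted(self):
        states = {n: ["0", "1"] for n in "ZAB"}
        d = bn.Dag(states, [("Z", "B"), ("A", "B")])
        assert d.parents("B") == ("A", "Z")


class TestBicScore:
    def test_hand_computed_single_binary_node(self):
        """Counts (6, 4) on 10 rows: loglik = 6 ln .6 + 4 ln .4 and the
        BIC penalty is (log 10)/2 for the one free parameter."""
        data = pd.DataFrame({"X": ["1"] * 6 + ["0"] * 4})
        dag = bn.Dag({"X": ["0", "1"]})
        expected = 6 * math.log(0.6) + 4 * math.log(0.4) - math.log(10) / 2
        assert bn.bic_score(dag, data) == pytest.approx(expected, abs=1e-12)

    def test_edge_between_independent_variables_lowers_score(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame({
                "A": rng.choice(["0", "1"], 5000),
                "B": rng.choice(["0", "1"], 5000),
            })
            states = {"A": ["0", "1"], "B": ["0", "1"]}
            empty = bn.bic_score(bn.Dag(states), data)
            with_edge = bn.bic_score(bn.Dag(states, [("A", "B")]), data)
            hits += with_edge < empty
        assert hits >= 19

    def test_decomposability_against_independent_loop(self, chain_model):
        data = bn.sample(chain_model, 500, np.random.default_rng(0))
        dag = chain_model.dag
        total = bn.bic_score(dag, data)
        # independent recomputation: plain-Python counting per family
        n = len(data)
        acc = 0.0
        for node in dag.nodes:
            parents = dag.parents(node)
            groups = {}
            for _, row in data.iterrows():
                key = tuple(row[p] for p in parents)
                groups.setdefault(key, []).append(row[node])
            ll = 0.0
            for vals in groups.values():
                for s in set(vals):
                    c = vals.count(s)
                    ll += c * math.log(c / len(vals))
            q = int(np.prod([len(dag.states[p]) for p in parents])) if parents else 1
            acc += ll - math.log(n) / 2 * (len(dag.states[node]) - 1) * q
        assert total == pytest.approx(acc, abs=1e-9)

    def test_invariant_under_state_relabeling(self, chain_model):
        data = bn.sample(chain_model, 400, np.random.default_rng(1))
        states = dict(chain_model.dag.states)
        dag = bn.Dag(states, chain_model.dag.edges)
        base = bn.bic_score(dag, data)
        renamed = data.replace({"A": {"0": "x", "1": "y"}})
        states2 = dict(states, A=["x", "y"])
        dag2 = bn.Dag(states2, chain_model.dag.edges)
        assert bn.bic_score(dag2, renamed) == pytest.approx(base, abs=1e-9)


class TestSaSearch:
    def test_zero_iterations_returns_initial_graph(self, chain_model):
        data = bn.sample(chain_model, 100, np.random.default_rng(0))
        sched = bn.SaSchedule(max_iter=0, seed=0)
        dag = bn.sa_search(data, sched, states=chain_model.dag.states)
        assert dag.edges == []

    def test_best_visited_never_below_empty_graph(self, chain_model):
        data = bn.sample(chain_model, 300, np.random.default_rng(2))
        states = chain_model.dag.states
        for seed in range(5):
            got = bn.sa_search(data, bn.SaSchedule(seed=seed, max_iter=2000),
                               states=states)
            assert (bn.bic_score(got, data)
                    >= bn.bic_score(bn.Dag(states), data) - 1e-9)

    def test_blacklist_respected(self, chain_model):
        data = bn.sample(chain_model, 2000, np.random.default_rng(3))
        bl = [("A", "B"), ("B", "A")]
        dag = bn.sa_search(data, bn.SaSchedule(seed=1, max_iter=3000),
                           blacklist=bl, states=chain_model.dag.states)
        assert not dag.has_edge("A", "B") and not dag.has_edge("B", "A")

    def test_result_is_acyclic_and_reproducible(self, toy_4node_model):
        data = bn.sample(toy_4node_model, 1000, np.random.default_rng(4))
        sched = bn.SaSchedule(seed=9, max_iter=3000)
        a = bn.sa_search(data, sched, states=toy_4node_model.dag.states)
        b = bn.sa_search(data, sched, states=toy_4node_model.dag.states)
        assert a.edges == b.edges
        assert a.topological_order()  # raises if cyclic


class TestFitCpts:
    def test_parentless_frequencies(self):
        data = pd.DataFrame({"X": ["1", "1", "1", "0"]})
        dag = bn.Dag({"X": ["0", "1"]})
        mle = bn.fit_cpts(dag, data, smoothing=0.0)
        assert mle.cpts["X"].table[0, 1] == pytest.approx(0.75)
        lap = bn.fit_cpts(dag, data, smoothing=1.0)
        assert lap.cpts["X"].table[0, 1] == pytest.approx(4.0 / 6.0)

    def test_unseen_parent_configuration_uniform(self):
        data = pd.DataFrame({"A": ["0", "0"], "B": ["1", "0"]})
        dag = bn.Dag({"A": ["0", "1"], "B": ["0", "1"]}, [("A", "B")])
        model = bn.fit_cpts(dag, data, smoothing=0.0)
        assert np.allclose(model.cpts["B"].table[1], [0.5, 0.5])

    def test_rows_sum_to_one_fuzzed(self):
        """Random DAGs and random data: every CPT row sums to 1."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            names = [f"V{i}" for i in range(k)]
            states = {n: [str(s) for s in range(int(rng.integers(2, 4)))]
                      for n in names}
            dag = bn.Dag(states)
            for i in range(k):
                for j in range(i + 1, k):
                    if rng.random() < 0.4:
                        dag.add_edge(names[i], names[j])
            data = pd.DataFrame({n: rng.choice(states[n], 30) for n in names})
            model = bn.fit_cpts(dag, data, smoothing=float(rng.choice([0.0, 1.0])))
            for cpt in model.cpts.values():
                assert np.allclose(cpt.table.sum(axis=1), 1.0, atol=1e-9)

    def test_round_trip_recovers_truth(self, toy_4node_model):
        """CPTs re-estimated from 50,000 samples of a known model are
        within 0.01 of the truth (max absolute cell error)."""
        data = bn.sample(toy_4node_model, 50_000, np.random.default_rng(5))
        refit = bn.fit_cpts(toy_4node_model.dag, data, smoothing=0.0)
        for node, cpt in toy_4node_model.cpts.items():
            err = np.abs(refit.cpts[node].table - cpt.table).max()
            assert err < 0.01, f"{node}: {err}"


class TestInference:
    def test_two_factor_product(self):
        states = {"A": ["a0", "a1"], "B": ["b0", "b1"]}
        dag = bn.Dag(states, [("A", "B")])
        model = bn.BnModel(dag, {
            "A": bn.Cpt("A", (), [[0.4, 0.6]]),
            "B": bn.Cpt("B", ("A",), [[0.7, 0.3], [0.5, 0.5]]),
        })
        assert bn.joint_probability(model, {"A": "a1", "B": "b1"}) == pytest.approx(0.3)

    @pytest.mark.parametrize("model_fixture", ["chain_model", "toy_4node_model"])
    def test_joint_normalizes_and_matches_bruteforce(self, model_fixture, request):
        model = request.getfixturevalue(model_fixture)
        nodes, joint = enumerate_joint_bruteforce(model)
        total = 0.0
        for combo, p_ref in joint.items():
            a = dict(zip(nodes, combo))
            p = bn.joint_probability(model, a)
            assert p == pytest.approx(p_ref, abs=1e-12)
            total += p
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_missing_node_rejected(self, chain_model):
        with pytest.raises(KeyError):
            bn.joint_probability(chain_model, {"A": "0", "B": "0"})

    def test_marginal_cpt_collapse_case(self, chain_model):
        """Factor is the target's only parent: the marginal CPT equals the
        learned CPT row for row."""
        mc = bn.marginal_cpt(chain_model, "B", "A")
        assert np.allclose(mc.to_numpy(), chain_model.cpts["B"].table)

    def test_marginal_cpt_independence_gives_identical_rows(self):
        states = {"A": ["0", "1"], "B": ["0", "1"]}
        dag = bn.Dag(states)
        model = bn.BnModel(dag, {
            "A": bn.Cpt("A", (), [[0.3, 0.7]]),
            "B": bn.Cpt("B", (), [[0.8, 0.2]]),
        })
        mc = bn.marginal_cpt(model, "B", "A")
        assert np.allclose(mc.iloc[0], mc.iloc[1])

    def test_marginal_cpt_matches_bruteforce(self, toy_4node_model):
        nodes, joint = enumerate_joint_bruteforce(toy_4node_model)
        mc = bn.marginal_cpt(toy_4node_model, "D", "A")
        for ai, a_state in enumerate(["0", "1"]):
            num = {d: 0.0 for d in ["0", "1"]}
            den = 0.0
            for combo, p in joint.items():
                d = dict(zip(nodes, combo))
                if d["A"] == a_state:
                    num[d["D"]] += p
                    den += p
            for d_state in ["0", "1"]:
                assert mc.loc[a_state, d_state] == pytest.approx(num[d_state] / den,
                                                                 abs=1e-12)
        assert np.allclose(mc.sum(axis=1), 1.0, atol=1e-9)

    def test_predict_full_parent_evidence_equals_cpt_row(self, toy_4node_model):
        state, post = bn.predict(toy_4node_model, "C", {"A": "1", "B": "0"})
        assert np.allclose(post.to_numpy(), toy_4node_model.cpts["C"].table[2])

    def test_predict_no_evidence_equals_prior(self, chain_model):
        _, post = bn.predict(chain_model, "C", {})
        nodes, joint = enumerate_joint_bruteforce(chain_model)
        prior = {s: 0.0 for s in ["0", "1"]}
        for combo, p in joint.items():
            prior[dict(zip(nodes, combo))["C"]] += p
        assert post["0"] == pytest.approx(prior["0"], abs=1e-12)

    def test_predict_matches_bruteforce_conditional(self, toy_4node_model):
        nodes, joint = enumerate_joint_bruteforce(toy_4node_model)
        _, post = bn.predict(toy_4node_model, "D", {"A": "0"})
        num = {s: 0.0 for s in ["0", "1"]}
        for combo, p in joint.items():
            d = dict(zip(nodes, combo))
            if d["A"] == "0":
                num[d["D"]] += p
        z = sum(num.values())
        for s in ["0", "1"]:
            assert post[s] == pytest.approx(num[s] / z, abs=1e-12)

    def test_zero_probability_evidence_rejected(self):
        states = {"A": ["0", "1"], "B": ["0", "1"]}
        dag = bn.Dag(states, [("A", "B")])
        model = bn.BnModel(dag, {
            "A": bn.Cpt("A", (), [[1.0, 0.0]]),
            "B": bn.Cpt("B", ("A",), [[0.5, 0.5], [0.5, 0.5]]),
        })
        with pytest.raises(ValueError, match="zero probability"):
            bn.predict(model, "B", {"A": "1"})

    def test_tie_breaks_to_low_risk(self):
        states = {"risk": ["low_risk", "high_risk"]}
        model = bn.BnModel(bn.Dag(states),
                           {"risk": bn.Cpt("risk", (), [[0.5, 0.5]])})
        state, _ = bn.predict(model, "risk", {})
        assert state == "low_risk"


class TestSerialization:
    def test_json_round_trip(self, toy_4node_model):
        back = bn.BnModel.from_json(toy_4node_model.to_json())
        assert back.dag.edges == toy_4node_model.dag.edges
        for n, cpt in toy_4node_model.cpts.items():
            assert np.allclose(back.cpts[n].table, cpt.table)
        assert back.dag.states == toy_4node_model.dag.states

    def test_dot_export_contains_edges(self, chain_model):
        dot = chain_model.to_dot()
        assert '"A" -> "B"' in dot and '"B" -> "C"' in dot


class TestMarkovEquivalence:
    def test_equivalent_chains(self):
        states = {n: ["0", "1"] for n in "ABC"}
        chain = bn.Dag(states, [("A", "B"), ("B", "C")])
        rev = bn.Dag(states, [("C", "B"), ("B", "A")])
        collider = bn.Dag(states, [("A", "B"), ("C", "B")])
        assert bn.markov_equivalent(chain, rev)
        assert not bn.markov_equivalent(chain, collider)
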