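"""TAN / K2 structure learning, CPT fitting and exact inference."""
import math

import numpy as np
import pytest

from hces.bayesnet import (BayesClassifier, NetworkStructure,
                           UnobservedConfigError, build_tan, ch_score,
                           conditional_mutual_information, fit_cpts, k2_search,
                           naive_bayes_structure, posterior, posterior_batch,
                           predict_proba)
from hces.core import HcesError
from hces import synthetic
from conftest import build_table, random_discrete_table
from oracles import max_spanning_tree_weight, posterior_oracle


class TestCMI:
    def test_copy_channel_one_bit(self):
        t = build_table([0] * 8, {"x": [0, 1] * 4, "y": [0, 1] * 4})
        assert conditional_mutual_information(t, "x", "y") == pytest.approx(1.0)

    def test_conditional_independence_zero(self):
        # given the class, x and y are exact-count independent
        y_cls = [0] * 8 + [1] * 8
        x = [0, 0, 1, 1] * 4
        y = [0, 1, 0, 1] * 4
        t = build_table(y_cls, {"x": x, "y": y})
        assert conditional_mutual_information(t, "x", "y") == \
            pytest.approx(0.0, abs=1e-12)

    def test_worked_fixture_matches_triple_sum(self):
        cls = [0, 0, 0, 0, 1, 1, 1, 1]
        x = [0, 1, 0, 1, 1, 1, 0, 0]
        y = [0, 1, 1, 1, 1, 0, 0, 1]
        t = build_table(cls, {"x": x, "y": y})
        # brute-force triple sum over empirical frequencies
        n = 8
        cmi = 0.0
        for c in (0, 1):
            for xv in (0, 1):
                for yv in (0, 1):
                    pxyc = sum(1 for i in range(n)
                               if (cls[i], x[i], y[i]) == (c, xv, yv)) / n
                    if pxyc == 0:
                        continue
                    pc = cls.count(c) / n
                    pxc = sum(1 for i in range(n)
                              if (cls[i], x[i]) == (c, xv)) / n
                    pyc = sum(1 for i in range(n)
                              if (cls[i], y[i]) == (c, yv)) / n
                    cmi += pxyc * math.log2((pxyc / pc) / ((pxc / pc) * (pyc / pc)))
        assert conditional_mutual_information(t, "x", "y") == \
            pytest.approx(cmi, abs=1e-12)

    def test_class_argument_rejected(self, xor_table):
        with pytest.raises(HcesError):
            conditional_mutual_information(xor_table, "Exacer", "A")


class TestBuildTan:
    def test_single_predictor_naive_shape(self):
        t = build_table([0, 1] * 4, {"a": [0, 1] * 4})
        s = build_tan(t)
        assert s.parents["a"] == ("Exacer",)

    def test_recovers_planted_chain(self):
        spec = synthetic.make_spec(n=2000, n_emitted=0, n_noise_discrete=0,
                                   n_noise_continuous=0, n_relevant=4,
                                   seed=11, parent_shift=0.7, base=0.1,
                                   class_shift=0.1)
        table, truth = synthetic.sample_dataset(spec)
        learned = build_tan(table)
        assert learned.tree_edges() == truth.structure.tree_edges()

    @pytest.mark.parametrize("seed", range(6))
    def test_tree_attains_max_spanning_weight(self, seed):
        rng = np.random.default_rng(seed)
        t = random_discrete_table(rng, n=50, p=int(rng.integers(2, 6)), k=2)
        s = build_tan(t)
        preds = t.predictor_names
        w = [[0.0 if i == j else conditional_mutual_information(t, preds[i], preds[j])
              for j in range(len(preds))] for i in range(len(preds))]
        assert sum(s.edge_weights.values()) == \
            pytest.approx(max_spanning_tree_weight(w), abs=1e-10)

    def test_every_predictor_has_class_parent(self, rng):
        t = random_discrete_table(rng, n=60, p=5)
        s = build_tan(t)
        for p in t.predictor_names:
            assert s.parents[p][0] == "Exacer"
            assert len(s.parents[p]) <= 2


class TestChScore:
    def test_binary_node_counts_1_1(self):
        t = build_table([0, 1], {"a": [0, 1]})
        # (r-1)!/(N+r-1)! * prod N_k! = 1!/3! = 1/6
        assert ch_score(t, "a", []) == pytest.approx(math.log(1 / 6), abs=1e-12)

    def test_empty_table_scores_zero(self):
        t = build_table([0, 1], {"a": [0, 1]})
        empty = t.subset_rows(np.array([], dtype=int))
        assert ch_score(empty, "a", []) == 0.0

    def test_constant_parent_leaves_score_unchanged(self, xor_table):
        base = ch_score(xor_table, "B", ["A"])
        with_const = ch_score(xor_table, "B", ["A", "C"])
        assert with_const == pytest.approx(base, abs=1e-12)


class TestK2:
    def test_one_parent_is_naive_bayes(self, rng):
        t = random_discrete_table(rng, n=50, p=4)
        assert k2_search(t, max_parents=1).parents == \
            naive_bayes_structure(t).parents

    def test_planted_dependency_found(self):
        rng = np.random.default_rng(3)
        n = 1000
        y = rng.integers(0, 2, n)
        x1 = np.where(rng.random(n) < 0.7, y, rng.integers(0, 2, n))
        x2 = np.where(rng.random(n) < 0.9, x1, rng.integers(0, 2, n))
        t = build_table(y, {"X1": x1, "X2": x2})
        s = k2_search(t, order=["X1", "X2"], max_parents=2)
        assert s.parents["X2"] == ("Exacer", "X1")
        # sanity: the score itself prefers the added parent
        assert ch_score(t, "X2", ["Exacer", "X1"]) > ch_score(t, "X2", ["Exacer"])

    def test_first_node_never_gains_predictor_parent(self, rng):
        t = random_discrete_table(rng, n=80, p=4)
        s = k2_search(t, max_parents=3)
        first = t.predictor_names[0]
        assert s.parents[first] == ("Exacer",)

    def test_order_must_cover_predictors(self, xor_table):
        with pytest.raises(HcesError):
            k2_search(xor_table, order=["A"], max_parents=1)


class TestFitCpts:
    def test_smoothing_formula(self):
        t = build_table([0, 0, 0, 1], {"a": [0, 0, 0, 1]})
        m = fit_cpts(t, naive_bayes_structure(t), pseudocount=0.5)
        # class=0 row of a: counts (3, 0) -> (3.5/4, 0.5/4)
        np.testing.assert_allclose(m.cpts["a"].table[0], [0.875, 0.125])
        # class=1 row: counts (0, 1) -> (0.25, 0.75)
        np.testing.assert_allclose(m.cpts["a"].table[1], [0.25, 0.75])

    def test_hand_smoothed_counts(self):
        t = build_table([0] * 4, {"a": [0, 0, 0, 1]})
        m = fit_cpts(t, naive_bayes_structure(t), pseudocount=0.5)
        np.testing.assert_allclose(m.cpts["a"].table[0], [0.7, 0.3])

    def test_unobserved_config_uniform(self):
        t = build_table([0] * 4, {"a": [0, 0, 1, 1]})
        m = fit_cpts(t, naive_bayes_structure(t), pseudocount=0.5)
        np.testing.assert_allclose(m.cpts["a"].table[1], [0.5, 0.5])

    def test_ml_estimate_without_smoothing(self):
        t = build_table([0, 0, 1, 1], {"a": [0, 1, 1, 1]})
        m = fit_cpts(t, naive_bayes_structure(t), pseudocount=0.0)
        np.testing.assert_allclose(m.cpts["a"].table, [[0.5, 0.5], [0.0, 1.0]])

    def test_unobserved_config_errors_on_use(self):
        t = build_table([0, 0, 1, 1], {"a": [0, 0, 0, 1], "b": [0, 1, 0, 1]})
        struct = NetworkStructure(("Exacer", "a", "b"), "Exacer",
                                  {"Exacer": (), "a": ("Exacer",),
                                   "b": ("Exacer", "a")})
        m = fit_cpts(t, struct, pseudocount=0.0)
        # parent configuration (class=0, a=1) never occurs in the data
        assert np.isnan(m.cpts["b"].table[0, 1]).all()
        with pytest.raises(UnobservedConfigError):
            posterior(m, {"a": "1", "b": "0"})


class TestPosterior:
    @pytest.fixture
    def toy_model(self):
        rng = np.random.default_rng(5)
        t = random_discrete_table(rng, n=40, p=3, k=2)
        return fit_cpts(t, build_tan(t), pseudocount=0.5)

    def test_empty_evidence_is_prior(self, toy_model):
        prior = toy_model.cpts["Exacer"].table
        assert posterior(toy_model, {}) == pytest.approx(
            prior[1] / prior.sum(), abs=1e-12)

    def test_full_evidence_matches_enumeration(self, toy_model):
        ev = {"P0": "1", "P1": "0", "P2": "1"}
        assert posterior(toy_model, ev) == pytest.approx(
            posterior_oracle(toy_model, ev), abs=1e-12)

    def test_partial_evidence_matches_enumeration(self, toy_model):
        for ev in ({"P1": "1"}, {"P0": "0", "P2": "1"}, {"P2": "0"}):
            assert posterior(toy_model, ev) == pytest.approx(
                posterior_oracle(toy_model, ev), abs=1e-10)

    def test_noninformative_evidence_keeps_prior(self):
        t = build_table([0, 0, 1, 1], {"a": [0, 1, 0, 1]})
        m = fit_cpts(t, naive_bayes_structure(t), pseudocount=0.0)
        # a's CPT rows identical across class states -> posterior == prior
        assert posterior(m, {"a": "1"}) == pytest.approx(0.5, abs=1e-12)

    def test_complement_sums_to_one(self, toy_model):
        # P(c=1|ev) computed directly and via the oracle's complement
        ev = {"P0": "1"}
        p1 = posterior(toy_model, ev)
        p0 = 1.0 - posterior_oracle(toy_model, ev)
        assert p1 + p0 == pytest.approx(1.0, abs=1e-12)

    def test_unknown_attribute_rejected(self, toy_model):
        with pytest.raises(HcesError):
            posterior(toy_model, {"nope": "1"})
        with pytest.raises(HcesError):
            posterior(toy_model, {"Exacer": "1"})

    def test_batch_full_evidence_equals_vectorized(self, toy_model, rng):
        t = random_discrete_table(rng, n=30, p=3, k=2)
        batch = posterior_batch(toy_model, t, ["P0", "P1", "P2"])
        np.testing.assert_array_equal(batch, predict_proba(toy_model, t))

    def test_batch_partial_matches_single(self, toy_model, rng):
        t = random_discrete_table(rng, n=20, p=3, k=2)
        batch = posterior_batch(toy_model, t, ["P1"])
        singles = [posterior(toy_model, {"P1": str(v)})
                   for v in t.frame["P1"]]
        np.testing.assert_allclose(batch, singles, atol=1e-12)


class TestTanOrientationAndSerialization:
    def test_root_choice_does_not_change_likelihood(self):
        rng = np.random.default_rng(8)
        t = random_discrete_table(rng, n=200, p=4, k=2)
        s = build_tan(t)
        # re-root the undirected tree at the last predictor
        edges = [tuple(e) for e in s.tree_edges()]
        preds = t.predictor_names
        adj = {p: [] for p in preds}
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        root = preds[-1]
        parents = {t.class_name: (), root: (t.class_name,)}
        seen, frontier = {root}, [root]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        parents[v] = (t.class_name, u)
                        nxt.append(v)
            frontier = nxt
        s2 = NetworkStructure(s.nodes, t.class_name, parents)
        m1 = fit_cpts(t, s, pseudocount=0.0)
        m2 = fit_cpts(t, s2, pseudocount=0.0)
        np.testing.assert_allclose(predict_proba(m1, t), predict_proba(m2, t),
                                   atol=1e-10)

    def test_json_round_trip_bit_exact(self):
        rng = np.random.default_rng(9)
        t = random_discrete_table(rng, n=50, p=3, k=3)
        m = fit_cpts(t, build_tan(t), pseudocount=0.5)
        back = BayesClassifier.from_json(m.to_json())
        assert back.structure.parents == m.structure.parents
        for node in m.structure.nodes:
            np.testing.assert_array_equal(back.cpts[node].table,
                                          m.cpts[node].table)

    def test_cpt_rows_sum_to_one(self, rng):
        t = random_discrete_table(rng, n=60, p=4, k=3)
        m = fit_cpts(t, build_tan(t), pseudocount=0.5)
        for cpt in m.cpts.values():
            np.testing.assert_allclose(cpt.table.sum(axis=-1), 1.0, atol=1e-12)

    def test_cycle_rejected(self):
        with pytest.raises(HcesError):
            NetworkStructure(("c", "a", "b"), "c",
                             {"c": (), "a": ("b",), "b": ("a",)})
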