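"""BD scoring, structure searches (K2 / HC / LHC), CPTs and prediction."""

from collections import Counter
from math import lgamma

import numpy as np
import pandas as pd
import pytest

import eegfc as E
from eegfc.bayesclf import (
    CyclicStructureError,
    _enumerate_ops,
    _ScoreCache,
    bd_score,
    fit_cpts,
    hc_search,
    k2_search,
    lhc_search,
    predict,
)


def chain_data(seed=0, n=500, flip=0.1):
    """Y -> X1 -> X2 with strong CPTs (the 3-node benchmark)."""
    r = np.random.default_rng(seed)
    y = r.integers(0, 2, n)
    x1 = np.where(r.random(n) < 1 - flip, y, 1 - y)
    x2 = np.where(r.random(n) < 1 - flip, x1, 1 - x1)
    return pd.DataFrame({"class": y, "X1": x1, "X2": x2})


def bench_data(seed, n=60, n_features=4):
    """Random feature chain with varying noise (HC/LHC benchmark)."""
    r = np.random.default_rng(seed)
    y = r.integers(0, 2, n)
    cols = {"class": y}
    prev = y
    for i in range(n_features):
        flip = r.random(n) < r.uniform(0.1, 0.4)
        prev = np.where(flip, r.integers(0, 2, n), prev)
        cols[f"F{i}"] = prev
    return pd.DataFrame(cols)


def dirichlet_multinomial_oracle(data: pd.DataFrame, parents: dict, ess=1.0):
    """Independent closed-form evaluation: per node, the Dirichlet-
    multinomial marginal likelihood from raw counts (Counter-based)."""
    total = 0.0
    cards = {c: int(data[c].max()) + 1 for c in data.columns}
    for node, pset in parents.items():
        r = cards[node]
        q = int(np.prod([cards[p] for p in pset])) if pset else 1
        a_j, a_jk = ess / q, ess / (q * r)
        joint = Counter(tuple(row) for row in data[list(pset) + [node]].to_numpy())
        parent_counts = Counter(tuple(row) for row in data[list(pset)].to_numpy())
        for cfg, n_j in parent_counts.items():
            total += lgamma(a_j) - lgamma(a_j + n_j)
        for key, n_jk in joint.items():
            total += lgamma(a_jk + n_jk) - lgamma(a_jk)
    return total


class TestBdScore:
    def test_empty_graph_matches_counting_oracle(self):
        data = chain_data(1, n=80)
        parents = {"class": (), "X1": ("class",), "X2": ("class",)}
        expected = dirichlet_multinomial_oracle(data, parents)
        assert bd_score([], data).total == pytest.approx(expected, abs=1e-9)

    def test_arbitrary_structure_matches_counting_oracle(self):
        data = chain_data(2, n=80)
        parents = {"class": (), "X1": ("class",), "X2": ("class", "X1")}
        expected = dirichlet_multinomial_oracle(data, parents)
        assert bd_score([("X1", "X2")], data).total == pytest.approx(expected, abs=1e-9)

    def test_edge_to_deterministic_copy_increases_score(self):
        r = np.random.default_rng(3)
        y = r.integers(0, 2, 40)
        x = r.integers(0, 2, 40)
        data = pd.DataFrame({"class": y, "X": x, "Z": x})  # Z == X
        assert bd_score([("X", "Z")], data).total > bd_score([], data).total

    def test_row_order_invariant(self):
        data = chain_data(4, n=60)
        shuffled = data.sample(frac=1.0, random_state=0)
        assert bd_score([("X1", "X2")], data).total == pytest.approx(
            bd_score([("X1", "X2")], shuffled).total)

    def test_per_node_terms_sum_to_total(self):
        data = chain_data(5, n=60)
        s = bd_score([("X1", "X2")], data)
        assert s.total == pytest.approx(sum(s.per_node.values()))

    def test_cyclic_structure_rejected(self):
        data = chain_data(6, n=30)
        with pytest.raises(CyclicStructureError):
            bd_score([("X1", "X2"), ("X2", "X1")], data)


class TestK2:
    def test_recovers_chain_edge_with_true_ordering(self):
        data = chain_data(7)
        model = k2_search(data, order=["class", "X1", "X2"])
        assert model.edges == (("X1", "X2"),)

    def test_matches_exhaustive_scoring_on_three_nodes(self):
        # the two orientations of the X1-X2 edge are Markov equivalent, so
        # compare the achieved score against the exhaustive optimum
        data = chain_data(8)
        best = max((bd_score(e, data).total
                    for e in ([], [("X1", "X2")], [("X2", "X1")])))
        model = k2_search(data, order=["class", "X1", "X2"])
        assert model.score == pytest.approx(best)

    def test_conditionally_independent_features_get_no_edges(self):
        r = np.random.default_rng(9)
        n = 500
        y = r.integers(0, 2, n)
        f1 = np.where(r.random(n) < 0.9, y, 1 - y)
        f2 = np.where(r.random(n) < 0.9, y, 1 - y)
        # break the marginal correlation channel: condition on Y is weak at n
        data = pd.DataFrame({"class": y, "F1": f1, "F2": f2})
        model = k2_search(data, order=["class", "F1", "F2"])
        assert model.edges == ()

    def test_zero_max_parents_is_naive_bayes(self):
        model = k2_search(chain_data(10), max_parents=0)
        assert model.edges == ()
        assert set(model.all_edges()) == {("class", "X1"), ("class", "X2")}

    def test_ordering_must_cover_columns(self):
        with pytest.raises(E.ConfigurationError):
            k2_search(chain_data(11), order=["class", "X1"])

    def test_class_must_lead_ordering(self):
        with pytest.raises(E.ConfigurationError):
            k2_search(chain_data(12), order=["X1", "class", "X2"])


class TestHillClimbing:
    def test_result_is_local_optimum(self):
        data = bench_data(0)
        model = hc_search(data)
        cache = _ScoreCache(data)
        features = model.features
        informative = tuple(f for f in features if cache.cards[f] > 1)
        ops = list(_enumerate_ops(features, set(model.edges), informative,
                                  2, cache))
        assert all(delta <= 1e-9 for _, _, _, delta in ops)

    def test_score_at_least_k2_on_chain(self):
        data = chain_data(13)
        assert hc_search(data).score >= k2_search(
            data, order=["class", "X1", "X2"]).score - 1e-9

    def test_deterministic(self):
        data = bench_data(1)
        a, b = hc_search(data), hc_search(data)
        assert a.edges == b.edges and a.score == b.score


class TestLookAheadHillClimbing:
    def test_beam1_depth1_equals_plain_hill_climbing(self):
        for seed in range(5):
            data = bench_data(seed)
            hc = hc_search(data)
            lhc = lhc_search(data, beam=1, depth=1)
            assert lhc.edges == hc.edges
            assert lhc.score == pytest.approx(hc.score)

    def test_beats_or_matches_hc_on_most_benchmarks(self):
        wins = sum(
            lhc_search(d).score >= hc_search(d).score - 1e-9
            for d in (bench_data(seed + 1000) for seed in range(50)))
        assert wins >= 48  # >= 95% of 50 paired benchmarks

    def test_deterministic(self):
        data = bench_data(2)
        assert lhc_search(data).edges == lhc_search(data).edges

    def test_invalid_beam_rejected(self):
        with pytest.raises(E.ConfigurationError):
            lhc_search(bench_data(3), beam=0)


class TestStructureInvariants:
    @pytest.mark.parametrize("search", [k2_search, hc_search, lhc_search])
    def test_class_edges_always_present_and_acyclic(self, search):
        data = bench_data(4)
        model = search(data)
        for f in model.features:
            assert ("class", f) in model.all_edges()
        bd_score(model.edges, data)  # raises on a cycle


class TestFitPredict:
    def test_laplace_smoothing_arithmetic(self):
        # child=1 in 3 of 7 rows for one parent state -> (3+1)/(7+2)
        data = pd.DataFrame({
            "class": [0] * 7 + [1] * 2,
            "X": [1, 1, 1, 0, 0, 0, 0, 0, 1],
        })
        model = k2_search(data, max_parents=0)
        model = fit_cpts(model, data)
        assert model.cpts["X"][0, 1] == pytest.approx(4 / 9)
        assert model.cpts["X"][0, 0] == pytest.approx(5 / 9)

    def test_cpt_rows_sum_to_one(self):
        data = bench_data(5)
        model = fit_cpts(hc_search(data), data)
        for node, cpt in model.cpts.items():
            assert np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-12)

    def test_unseen_parent_configuration_is_uniform(self):
        data = pd.DataFrame({"class": [0, 0, 1, 1],
                             "A": [0, 0, 1, 1], "B": [0, 0, 1, 1]})
        model = k2_search(data, order=["class", "A", "B"], max_parents=1)
        model = fit_cpts(model, data)
        if ("A", "B") in model.edges:  # B | class, A: config (0, 1) unseen
            assert np.allclose(model.cpts["B"][0, 1], 0.5)

    def test_naive_bayes_posterior_matches_hand_rule(self):
        data = pd.DataFrame({
            "class": [1, 1, 1, 0, 0],
            "A": [1, 1, 0, 0, 0],
            "B": [1, 0, 1, 0, 1],
        })
        model = fit_cpts(k2_search(data, max_parents=0), data)
        label, post = predict(model, {"A": 1, "B": 1})
        # Laplace-smoothed: P(y=1)=4/7, P(A=1|1)=3/5, P(B=1|1)=3/5
        #                   P(y=0)=3/7, P(A=1|0)=1/4, P(B=1|0)=2/4
        p1 = (4 / 7) * (3 / 5) * (3 / 5)
        p0 = (3 / 7) * (1 / 4) * (2 / 4)
        assert post[1] == pytest.approx(p1 / (p0 + p1))
        assert label == 1

    def test_exact_tie_resolves_to_control_class(self):
        # constant feature, balanced classes: posterior is exactly (1/2, 1/2)
        data = pd.DataFrame({"class": [0, 1], "A": [0, 0]})
        model = fit_cpts(k2_search(data, max_parents=0), data)
        label, post = predict(model, {"A": 0})
        assert post[0] == pytest.approx(post[1])
        assert label == 0

    def test_posterior_sums_to_one(self):
        data = bench_data(6)
        model = fit_cpts(k2_search(data), data)
        _, post = predict(model, {f: 0 for f in model.features})
        assert post.sum() == pytest.approx(1.0)

    def test_missing_feature_rejected(self):
        data = chain_data(14, n=30)
        model = fit_cpts(k2_search(data), data)
        with pytest.raises(E.ConfigurationError):
            predict(model, {"X1": 0})
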