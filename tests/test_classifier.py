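"""Standardization, neighbor search, weighting, budgets and consensus."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from neurolbn.bayesnet import enumerate_joint, free_parameter_count
from neurolbn.classifier import (
    FeatureStandardizer,
    LbnConsensusKnn,
    allocate_samples,
    consensus_network,
    fit_standardizer,
    nearest_neighbors,
    neighbor_weights,
    predict_lbn,
    sample_budget,
)
from neurolbn.evaluation import js_divergence
from neurolbn.labels import DEFAULT_SCHEMA

from conftest import make_point_mass_bn, make_random_bn, make_uniform_bn

PM_A = ("intralaminar", "intracolumnar", "centered", "no", "NG")
PM_B = ("translaminar", "transcolumnar", "displaced", "both", "MA")


class TestStandardizer:
    def test_two_point_column_sample_sd(self):
        model = fit_standardizer(np.array([[0.0], [10.0]]))
        z = model.transform(np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(z.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_training_matrix_standardized(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(40, 18))
        Z = fit_standardizer(X).transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_mean_vector_maps_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        model = fit_standardizer(X)
        np.testing.assert_allclose(
            model.transform(X.mean(axis=0)[None, :]), 0.0, atol=1e-9)

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 6))
        model = fit_standardizer(X)
        np.testing.assert_allclose(model.inverse_transform(model.transform(X)), X)

    def test_zero_variance_feature_excluded(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_standardizer(X)
        Z = model.transform(X)
        assert np.all(Z[:, 1] == 0.0)


class TestNearestNeighbors:
    def test_exact_duplicate_is_first_neighbor(self):
        train = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        idx, d = nearest_neighbors(train[1], train, k=2)
        assert idx[0] == 1 and d[0] == 0.0

    def test_one_dimensional_example(self):
        train = np.array([[0.0], [1.0], [2.0], [10.0]])
        idx, _ = nearest_neighbors(np.array([0.4]), train, k=2)
        assert set(idx) == {0, 1}

    def test_k_out_of_range(self):
        train = np.zeros((4, 2))
        for bad in (1, 4, 5):
            with pytest.raises(ValueError):
                nearest_neighbors(np.zeros(2), train, k=bad)

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        train = rng.normal(size=(50, 18))
        q = rng.normal(size=18)
        idx, d = nearest_neighbors(q, train, k=7)
        full = np.linalg.norm(train - q, axis=1)
        assert np.all(np.sort(full)[:7] == d)

    def test_tie_keeps_lowest_index(self):
        train = np.array([[1.0], [-1.0], [1.0], [5.0]])
        idx, _ = nearest_neighbors(np.array([0.0]), train, k=3)
        assert list(idx) == [0, 1, 2]


class TestWeights:
    def test_formula_substitution(self):
        np.testing.assert_allclose(neighbor_weights([1, 2, 3]),
                                   [5 / 12, 4 / 12, 3 / 12])

    def test_equal_distances_uniform(self):
        np.testing.assert_allclose(neighbor_weights([2.0] * 5), [0.2] * 5)

    def test_closest_takes_all_at_zero(self):
        np.testing.assert_allclose(neighbor_weights([0.0, 4.0]), [1.0, 0.0])

    def test_all_zero_distances_limit(self):
        np.testing.assert_allclose(neighbor_weights([0.0, 0.0, 0.0]), [1 / 3] * 3)

    def test_normalization_and_monotonicity_random(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            d = np.sort(rng.uniform(0, 100, size=rng.integers(2, 10)))
            w = neighbor_weights(d)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(w >= -1e-12)
            assert np.all(np.diff(w) <= 1e-12)  # non-increasing in distance


class TestWeightProperties:
    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=2,
                    max_size=12))
    def test_weights_normalize_and_order(self, distances):
        w = neighbor_weights(sorted(distances))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w >= -1e-12)
        assert np.all(np.diff(w) <= 1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=100_000),
           st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                    max_size=9),
           )
    def test_allocation_sums_to_budget(self, M, raw):
        w = np.asarray(raw) / np.sum(raw)
        counts = allocate_samples(w, M)
        assert counts.sum() == M
        assert np.all(np.abs(counts - w * M) < 1.0)


class TestBudgetsAndAllocation:
    def test_budget_formula(self):
        bns = [make_random_bn(s) for s in (0, 1, 2)]
        M, c = sample_budget(bns, k=3)
        assert c == max(free_parameter_count(b) for b in bns)
        assert M == 3 * 500 * c

    def test_empty_graph_budget(self):
        bns = [make_uniform_bn()] * 5
        M, c = sample_budget(bns, k=5)
        assert (M, c) == (5 * 500 * 15, 15)

    def test_per_param_scales_linearly(self):
        bns = [make_uniform_bn()] * 2
        assert sample_budget(bns, 2, per_param=10)[0] * 50 == \
            sample_budget(bns, 2, per_param=500)[0]

    @pytest.mark.parametrize("w, M, expected", [
        ((0.5, 0.5), 100, (50, 50)),
        ((5 / 12, 4 / 12, 3 / 12), 12, (5, 4, 3)),
    ])
    def test_exact_allocations(self, w, M, expected):
        np.testing.assert_array_equal(allocate_samples(w, M), expected)

    def test_largest_remainder_property(self):
        counts = allocate_samples([1 / 3] * 3, 10)
        assert counts.sum() == 10 and counts.max() - counts.min() <= 1
        rng = np.random.default_rng(5)
        for _ in range(200):
            w = rng.dirichlet(np.ones(rng.integers(2, 9)))
            M = int(rng.integers(0, 10_000))
            counts = allocate_samples(w, M)
            assert counts.sum() == M
            assert np.all(np.abs(counts - w * M) < 1.0)


class TestConsensus:
    def test_self_consensus_close_to_source(self):
        bn = make_random_bn(11)
        cons = consensus_network([bn] * 3, np.full(3, 1 / 3), M=12_000, seed=0)
        d = js_divergence(enumerate_joint(bn).ravel(),
                          enumerate_joint(cons).ravel())
        assert d <= 0.05

    def test_degenerate_weight_ignores_other_network(self):
        a, b = make_point_mass_bn(PM_A), make_point_mass_bn(PM_B)
        cons = consensus_network([a, b], np.array([1.0, 0.0]), M=5_000, seed=1)
        joint = enumerate_joint(cons).ravel()
        assert joint[DEFAULT_SCHEMA.config_index(PM_A)] == pytest.approx(1.0)

    def test_point_mass_mixture(self):
        a, b = make_point_mass_bn(PM_A), make_point_mass_bn(PM_B)
        cons = consensus_network([a, b], np.array([0.75, 0.25]), M=40_000, seed=2)
        joint = enumerate_joint(cons).ravel()
        target = np.zeros(320)
        target[DEFAULT_SCHEMA.config_index(PM_A)] = 0.75
        target[DEFAULT_SCHEMA.config_index(PM_B)] = 0.25
        assert 0.5 * np.abs(joint - target).sum() <= 0.02

    def test_neighbor_order_irrelevant(self):
        bns = [make_random_bn(s) for s in (1, 2, 3)]
        w = np.array([0.5, 0.3, 0.2])
        ids = ["x", "y", "z"]
        cons1 = consensus_network(bns, w, M=9_000, seed=5, neighbor_ids=ids)
        perm = [2, 0, 1]
        cons2 = consensus_network([bns[i] for i in perm], w[perm], M=9_000,
                                  seed=5, neighbor_ids=[ids[i] for i in perm])
        np.testing.assert_allclose(enumerate_joint(cons1), enumerate_joint(cons2))

    def test_convergence_with_budget(self):
        bn = make_random_bn(17)
        exact = enumerate_joint(bn).ravel()
        tvs = []
        for M in (100, 1_000, 10_000):
            cons = consensus_network([bn] * 2, np.array([0.5, 0.5]), M=M, seed=3)
            tvs.append(0.5 * np.abs(enumerate_joint(cons).ravel() - exact).sum())
        assert tvs[2] < tvs[0]

    def test_schema_mismatch_rejected(self):
        from neurolbn.bayesnet import Cpt, DagStructure, BayesianNetwork, VariableSpec
        v = (VariableSpec("A", ("a", "b")),)
        other = BayesianNetwork(v, DagStructure(("A",), frozenset()),
                                {"A": Cpt("A", (), np.array([[0.5, 0.5]]))})
        with pytest.raises(ValueError, match="schema"):
            consensus_network([make_uniform_bn(), other], np.array([0.5, 0.5]),
                              M=100)


class TestEstimator:
    def _toy(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 18))
        lbns = [make_random_bn(s) for s in range(n)]
        return X, lbns

    def test_sklearn_params_and_clone(self):
        est = LbnConsensusKnn(k=3, per_param=10)
        assert clone(est).get_params()["k"] == 3
        est.set_params(k=5)
        assert est.get_params()["k"] == 5

    def test_k_validation_at_fit(self):
        X, lbns = self._toy(4)
        with pytest.raises(ValueError, match="k must"):
            LbnConsensusKnn(k=1).fit(X, lbns)
        with pytest.raises(ValueError, match="k must"):
            LbnConsensusKnn(k=4).fit(X, lbns)

    def test_k_equals_n_minus_one_on_three_point_set(self):
        X, lbns = self._toy(3)
        est = LbnConsensusKnn(k=2, per_param=5).fit(X, lbns)
        ns = est.neighbor_set(X[0])
        assert len(ns.ids) == 2 and 0 in ns.ids

    def test_fixed_seed_is_bit_reproducible(self):
        X, lbns = self._toy(8, seed=1)
        q = np.random.default_rng(2).normal(size=18)
        est = LbnConsensusKnn(k=3, per_param=20, random_state=9)
        a = est.fit(X, lbns).predict(q[None, :])[0]
        b = LbnConsensusKnn(k=3, per_param=20, random_state=9).fit(
            X, lbns).predict(q[None, :])[0]
        assert json.dumps(a.to_dict(), sort_keys=True) == \
            json.dumps(b.to_dict(), sort_keys=True)

    def test_query_in_tight_cluster_recovers_archetype(self):
        """Neighbors sharing one archetype dominate the consensus."""
        rng = np.random.default_rng(3)
        arch = make_random_bn(23)
        X = np.vstack([rng.normal(0, 0.1, size=(6, 18)),
                       rng.normal(30, 0.1, size=(4, 18))])
        lbns = [arch] * 6 + [make_random_bn(s) for s in range(4)]
        pred = predict_lbn(X[0], X, lbns, k=5, per_param=100, seed=4)
        d = js_divergence(enumerate_joint(arch).ravel(),
                          enumerate_joint(pred).ravel())
        assert d <= 0.1

    def test_neighbor_set_bookkeeping(self):
        X, lbns = self._toy(9, seed=5)
        est = LbnConsensusKnn(k=4, per_param=50).fit(X, lbns)
        ns = est.neighbor_set(X[2])
        assert ns.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert int(ns.sample_counts.sum()) == ns.budget
        assert ns.budget == 4 * 50 * ns.max_free_params
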