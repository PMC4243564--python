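"""Bayesian-network representation, scoring, learning and inference."""

import itertools
import math

import numpy as np
import pytest

from neurolbn.bayesnet import (
    BayesianNetwork,
    Cpt,
    DagStructure,
    DiscreteDataset,
    VariableSpec,
    enumerate_joint,
    fit_mle,
    free_parameter_count,
    joint_probability,
    logic_sample,
    mpe,
    node_marginal,
    score_structure,
    tabu_learn,
)
from neurolbn.labels import DEFAULT_SCHEMA

from conftest import make_point_mass_bn, make_random_bn, make_uniform_bn, oracle_joint

AB = (VariableSpec("A", ("a", "b")), VariableSpec("B", ("a", "b")))


def _single_var_abb_dataset():
    v = VariableSpec("A", ("a", "b"))
    return DiscreteDataset((v,), np.array([[0], [0], [1]])), DagStructure(("A",), frozenset())


class TestStructures:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DagStructure(("A", "B"), frozenset({("A", "B"), ("B", "A")}))

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            DagStructure(("A",), frozenset({("A", "A")}))

    def test_cpt_rows_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            Cpt("A", (), np.array([[0.5, 0.4]]))

    def test_network_serialization_round_trip(self):
        bn = make_random_bn(7)
        clone = BayesianNetwork.from_dict(bn.to_dict())
        assert clone.structure.arcs == bn.structure.arcs
        for name in bn.names:
            np.testing.assert_array_equal(clone.cpts[name].table, bn.cpts[name].table)


class TestFreeParameters:
    @pytest.mark.parametrize("arcs, expected", [
        (frozenset(), 15),                      # sum (r_i - 1) over (2,2,2,4,10)
        (frozenset({("C4", "C5")}), 42),        # 1+1+1+3 + 9*4
    ])
    def test_on_nomenclature(self, arcs, expected):
        rng = np.random.default_rng(0)
        codes = np.column_stack([
            rng.integers(0, c, 30) for c in DEFAULT_SCHEMA.cardinalities
        ])
        data = DiscreteDataset(DEFAULT_SCHEMA.variables, codes)
        bn = fit_mle(DagStructure(DEFAULT_SCHEMA.names, arcs), data)
        assert free_parameter_count(bn) == expected

    def test_single_binary_node(self):
        v = VariableSpec("A", ("a", "b"))
        bn = fit_mle(DagStructure(("A",), frozenset()),
                     DiscreteDataset((v,), np.array([[0], [1]])))
        assert free_parameter_count(bn) == 1


class TestScores:
    def test_closed_form_values(self):
        data, struct = _single_var_abb_dataset()
        assert score_structure(struct, data, "bde", ess=1.0) == pytest.approx(
            math.log(1 / 16), abs=1e-9)
        assert score_structure(struct, data, "k2") == pytest.approx(
            math.log(1 / 12), abs=1e-9)
        assert score_structure(struct, data, "bic") == pytest.approx(
            2 * math.log(2 / 3) + math.log(1 / 3) - 0.5 * math.log(3), abs=1e-9)

    def test_unknown_score_and_empty_data(self):
        data, struct = _single_var_abb_dataset()
        with pytest.raises(ValueError, match="unknown score"):
            score_structure(struct, data, "aic")
        empty = DiscreteDataset(data.variables, np.empty((0, 1), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            score_structure(struct, empty, "bic")

    def test_bde_equal_on_markov_equivalent_dags(self):
        """BDe is score-equivalent: chains and forks share one score."""
        rng = np.random.default_rng(3)
        vs = tuple(VariableSpec(n, ("a", "b", "c")[:2]) for n in "ABC")
        a = rng.integers(0, 2, 400)
        b = np.where(rng.random(400) < 0.8, a, 1 - a)
        c = np.where(rng.random(400) < 0.7, b, 1 - b)
        data = DiscreteDataset(vs, np.column_stack([a, b, c]))
        chains = [
            frozenset({("A", "B"), ("B", "C")}),
            frozenset({("C", "B"), ("B", "A")}),
            frozenset({("B", "A"), ("B", "C")}),  # fork
        ]
        scores = [
            score_structure(DagStructure(("A", "B", "C"), arcs), data, "bde", ess=1.0)
            for arcs in chains
        ]
        assert scores[0] == pytest.approx(scores[1], abs=1e-9)
        assert scores[0] == pytest.approx(scores[2], abs=1e-9)

    def test_bde_equal_on_two_node_reversal(self):
        rng = np.random.default_rng(4)
        codes = np.column_stack([rng.integers(0, 2, 100), rng.integers(0, 2, 100)])
        data = DiscreteDataset(AB, codes)
        s_ab = score_structure(DagStructure(("A", "B"), frozenset({("A", "B")})), data, "bde")
        s_ba = score_structure(DagStructure(("A", "B"), frozenset({("B", "A")})), data, "bde")
        assert s_ab == pytest.approx(s_ba, abs=1e-9)


class TestMle:
    def test_relative_frequencies(self):
        v = VariableSpec("A", ("a", "b"))
        data = DiscreteDataset((v,), np.array([[0], [0], [0], [1]]))
        bn = fit_mle(DagStructure(("A",), frozenset()), data)
        assert bn.cpts["A"].table[0, 0] == pytest.approx(0.75)

    def test_degenerate_data_gives_degenerate_cpts(self):
        rng = np.random.default_rng(1)
        row = [rng.integers(0, c) for c in DEFAULT_SCHEMA.cardinalities]
        data = DiscreteDataset(DEFAULT_SCHEMA.variables, np.tile(row, (10, 1)))
        bn = fit_mle(DagStructure(DEFAULT_SCHEMA.names, frozenset()), data)
        for j, v in enumerate(DEFAULT_SCHEMA.variables):
            assert bn.cpts[v.name].table[0, row[j]] == 1.0

    def test_chain_conditionals_equal_count_ratios(self):
        data = DiscreteDataset(AB, np.array([[0, 0], [0, 0], [0, 1], [1, 1]]))
        bn = fit_mle(DagStructure(("A", "B"), frozenset({("A", "B")})), data)
        # P(B=a | A=a) = 2/3, P(B=b | A=b) = 1
        assert bn.cpts["B"].table[0, 0] == pytest.approx(2 / 3)
        assert bn.cpts["B"].table[1, 1] == pytest.approx(1.0)

    def test_unseen_parent_config_is_uniform(self):
        data = DiscreteDataset(AB, np.array([[0, 0], [0, 1]]))  # A=b never seen
        bn = fit_mle(DagStructure(("A", "B"), frozenset({("A", "B")})), data)
        np.testing.assert_allclose(bn.cpts["B"].table[1], [0.5, 0.5])

    def test_mle_round_trip_recovers_degenerate_network(self):
        bn = make_point_mass_bn(("translaminar", "transcolumnar", "displaced", "both", "MA"))
        data = logic_sample(bn, 25, seed=0)
        refit = fit_mle(DagStructure(DEFAULT_SCHEMA.names, frozenset()), data)
        for name in bn.names:
            np.testing.assert_array_equal(refit.cpts[name].table, bn.cpts[name].table)


class TestTabuLearn:
    def test_recovers_strong_dependence(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 5000)
        b = np.where(rng.random(5000) < 0.95, a, 1 - a)
        data = DiscreteDataset(AB, np.column_stack([a, b]))
        # oracle: exhaustive score of the three 2-node DAGs
        dags = [frozenset(), frozenset({("A", "B")}), frozenset({("B", "A")})]
        best = max(dags, key=lambda arcs: score_structure(
            DagStructure(("A", "B"), arcs), data, "bic"))
        assert len(best) == 1
        learned = tabu_learn(data, "bic")
        assert len(learned.arcs) == 1  # Markov-equivalent to A->B

    def test_independent_variables_give_empty_graph(self):
        rng = np.random.default_rng(1)
        codes = np.column_stack([rng.integers(0, 2, 5000), rng.integers(0, 2, 5000)])
        learned = tabu_learn(DiscreteDataset(AB, codes), "bic")
        assert learned.arcs == frozenset()

    def test_single_row_gives_empty_graph(self):
        learned = tabu_learn(DiscreteDataset(AB, np.array([[0, 1]])), "bic")
        assert learned.arcs == frozenset()

    def test_never_scores_below_empty_graph(self):
        rng = np.random.default_rng(2)
        codes = np.column_stack([
            rng.integers(0, c, 42) for c in DEFAULT_SCHEMA.cardinalities
        ])
        data = DiscreteDataset(DEFAULT_SCHEMA.variables, codes)
        learned = tabu_learn(data, "bde")
        empty = DagStructure(DEFAULT_SCHEMA.names, frozenset())
        assert score_structure(learned, data, "bde") >= score_structure(
            empty, data, "bde") - 1e-9

    def test_deterministic_for_fixed_inputs(self):
        rng = np.random.default_rng(5)
        codes = np.column_stack([
            rng.integers(0, c, 42) for c in DEFAULT_SCHEMA.cardinalities
        ])
        data = DiscreteDataset(DEFAULT_SCHEMA.variables, codes)
        a = tabu_learn(data, "bde", seed=11)
        b = tabu_learn(data, "bde", seed=11)
        assert a.arcs == b.arcs


class TestSamplingAndInference:
    def test_degenerate_network_samples_identical_rows(self):
        bn = make_point_mass_bn(("intralaminar", "intracolumnar", "centered", "no", "CB"))
        data = logic_sample(bn, 30, seed=4)
        assert len(np.unique(data.codes, axis=0)) == 1

    def test_zero_samples(self):
        assert len(logic_sample(make_uniform_bn(), 0, seed=0)) == 0

    def test_sampling_converges_to_exact_joint(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, 200)
        b = np.where(rng.random(200) < 0.7, a, 1 - a)
        bn = fit_mle(DagStructure(("A", "B"), frozenset({("A", "B")})),
                     DiscreteDataset(AB, np.column_stack([a, b])))
        sample = logic_sample(bn, 50_000, seed=7)
        emp = np.bincount(sample.codes[:, 0] * 2 + sample.codes[:, 1],
                          minlength=4) / 50_000
        exact = enumerate_joint(bn).ravel()
        assert 0.5 * np.abs(emp - exact).sum() < 0.02

    def test_joint_probability_uniform_and_point_mass(self):
        uniform = make_uniform_bn()
        config = dict(zip(DEFAULT_SCHEMA.names,
                          ("translaminar", "intracolumnar", "displaced", "both", "HT")))
        assert joint_probability(uniform, config) == pytest.approx(1 / 320)
        pm_tuple = ("intralaminar", "transcolumnar", "centered", "no", "AR")
        pm = make_point_mass_bn(pm_tuple)
        assert joint_probability(pm, dict(zip(DEFAULT_SCHEMA.names, pm_tuple))) == 1.0
        assert joint_probability(pm, config) == 0.0

    def test_unknown_category_rejected(self):
        config = dict(zip(DEFAULT_SCHEMA.names,
                          ("intralaminar", "intracolumnar", "centered", "no", "Martinotti")))
        with pytest.raises(KeyError):
            joint_probability(make_uniform_bn(), config)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_joint_matches_brute_force_enumeration(self, seed):
        bn = make_random_bn(seed)
        oracle = oracle_joint(bn)
        grid = enumerate_joint(bn)
        for config, p in list(oracle.items())[::7]:
            assert joint_probability(bn, dict(zip(bn.names, config))) == pytest.approx(p, abs=1e-12)
        flat_oracle = np.array([oracle[c] for c in sorted(
            oracle, key=DEFAULT_SCHEMA.config_index)])
        np.testing.assert_allclose(grid.ravel(), flat_oracle, atol=1e-12)

    def test_enumerate_joint_normalizes(self):
        for seed in range(5):
            assert enumerate_joint(make_random_bn(seed)).sum() == pytest.approx(1.0, abs=1e-8)

    def test_point_mass_enumeration(self, point_mass_bn):
        grid = enumerate_joint(point_mass_bn).ravel()
        assert grid.max() == 1.0 and np.count_nonzero(grid) == 1

    @pytest.mark.parametrize("seed", range(0, 20, 4))
    def test_mpe_matches_oracle_argmax(self, seed):
        bn = make_random_bn(seed)
        oracle = oracle_joint(bn)
        best = max(oracle.items(), key=lambda kv: kv[1])
        assert mpe(bn) == best[0] or oracle[mpe(bn)] == pytest.approx(best[1], abs=1e-12)

    def test_mpe_uniform_tie_is_first_canonical(self, uniform_bn):
        assert mpe(uniform_bn) == ("intralaminar", "intracolumnar", "centered",
                                   "ascending", "AR")

    def test_node_marginal_root_equals_cpt(self):
        bn = make_random_bn(9)
        roots = [n for n in bn.names if not bn.structure.parents(n)]
        assert roots, "random net should have at least one root"
        np.testing.assert_allclose(
            node_marginal(bn, roots[0]), bn.cpts[roots[0]].table[0], atol=1e-12)

    def test_node_marginal_uniform_c5(self, uniform_bn):
        np.testing.assert_allclose(node_marginal(uniform_bn, "C5"), np.full(10, 0.1))

    def test_node_marginal_matches_oracle(self):
        bn = make_random_bn(13)
        oracle = oracle_joint(bn)
        for node in bn.names:
            v = bn.variable(node)
            j = bn.names.index(node)
            expected = np.zeros(v.cardinality)
            for config, p in oracle.items():
                expected[v.code(config[j])] += p
            np.testing.assert_allclose(node_marginal(bn, node), expected, atol=1e-10)

    def test_unknown_node_rejected(self, uniform_bn):
        with pytest.raises(KeyError):
            node_marginal(uniform_bn, "C9")
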