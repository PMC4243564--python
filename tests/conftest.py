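"""Shared fixtures: small networks, brute-force oracles, random builders."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from neurolbn.bayesnet import (
    BayesianNetwork,
    Cpt,
    DagStructure,
    VariableSpec,
)
from neurolbn.labels import DEFAULT_SCHEMA
from neurolbn.synthetic import SyntheticStudyConfig, generate_archetypes


@pytest.fixture
def schema():
    return DEFAULT_SCHEMA


def make_point_mass_bn(config: tuple[str, ...], schema=DEFAULT_SCHEMA) -> BayesianNetwork:
    """Empty-graph network putting all mass on one configuration."""
    structure = DagStructure(schema.names, frozenset())
    cpts = {}
    for v, value in zip(schema.variables, config):
        row = np.zeros((1, v.cardinality))
        row[0, v.code(value)] = 1.0
        cpts[v.name] = Cpt(v.name, (), row)
    return BayesianNetwork(schema.variables, structure, cpts)


def make_uniform_bn(schema=DEFAULT_SCHEMA) -> BayesianNetwork:
    structure = DagStructure(schema.names, frozenset())
    cpts = {
        v.name: Cpt(v.name, (), np.full((1, v.cardinality), 1.0 / v.cardinality))
        for v in schema.variables
    }
    return BayesianNetwork(schema.variables, structure, cpts)


def make_random_bn(seed: int, schema=DEFAULT_SCHEMA) -> BayesianNetwork:
    """A random archetype network over the nomenclature."""
    cfg = SyntheticStudyConfig(n_archetypes=1, seed=seed, schema=schema)
    return generate_archetypes(cfg)[0]


def oracle_joint(bn: BayesianNetwork) -> dict[tuple[str, ...], float]:
    """Brute-force joint: per-configuration chain-rule product, pure Python.

    Independent of ``enumerate_joint``: iterates configurations explicitly
    and indexes CPT rows by manually accumulated odometer strides.
    """
    names = list(bn.names)
    cats = {v.name: list(v.categories) for v in bn.variables}
    joint: dict[tuple[str, ...], float] = {}
    for config in itertools.product(*(cats[n] for n in names)):
        assignment = dict(zip(names, config))
        p = 1.0
        for name in names:
            cpt = bn.cpts[name]
            row = 0
            for parent in cpt.parents:
                row = row * len(cats[parent]) + cats[parent].index(assignment[parent])
            p *= cpt.table[row, cats[name].index(assignment[name])]
        joint[config] = p
    return joint


@pytest.fixture
def point_mass_bn():
    return make_point_mass_bn(
        ("intralaminar", "intracolumnar", "centered", "no", "NG")
    )


@pytest.fixture
def uniform_bn():
    return make_uniform_bn()
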