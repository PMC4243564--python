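"""Multi-annotator class labels and their Bayesian-network encodings.

Each reconstructed interneuron was independently categorized by a panel of
annotators according to five categorical axonal features:

* C1 — laminar reach: intralaminar / translaminar
* C2 — columnar reach: intracolumnar / transcolumnar
* C3 — dendritic centering: centered / displaced
* C4 — vertical orientation: ascending / descending / both / no
* C5 — interneuron type: AR, CR, CH, CB, CT, HT, LB, MA, NG, OT

plus a characterized/uncharacterized flag (C6) marking whether the
annotator considered the reconstruction classifiable at all.  The joint
state space Omega of C1..C5 has 2*2*2*4*10 = 320 configurations.

This module turns per-neuron annotation matrices into (a) empirical label
distributions over Omega, (b) learned label Bayesian networks (LBNs), and
(c) crisp "truth" label vectors (joint and marginal majority).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import (
    BayesianNetwork,
    DiscreteDataset,
    VariableSpec,
    fit_mle,
    tabu_learn,
)

__all__ = [
    "CLASS_VARIABLES",
    "DEFAULT_SCHEMA",
    "NomenclatureSchema",
    "AnnotationMatrix",
    "EmpiricalDistribution",
    "filter_characterized",
    "apply_c4_no_rule",
    "apply_c4_rule",
    "empirical_distribution",
    "learn_lbn",
    "joint_truth",
    "marginal_truth",
]

log = logging.getLogger(__name__)

CLASS_VARIABLES = ("C1", "C2", "C3", "C4", "C5")


@dataclass(frozen=True)
class NomenclatureSchema:
    """The ordered class-variable specs defining Omega and all tie-breaks."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(v.cardinality for v in self.variables)

    def n_states(self) -> int:
        return int(np.prod(self.cardinalities, dtype=np.int64))

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def config_index(self, config: tuple[str, ...]) -> int:
        """Canonical (odometer, last variable fastest) index of a config."""
        codes = tuple(v.code(c) for v, c in zip(self.variables, config))
        return int(np.ravel_multi_index(codes, self.cardinalities))

    def config_at(self, index: int) -> tuple[str, ...]:
        codes = np.unravel_index(index, self.cardinalities)
        return tuple(v.categories[c] for v, c in zip(self.variables, codes))


DEFAULT_SCHEMA = NomenclatureSchema((
    VariableSpec("C1", ("intralaminar", "translaminar")),
    VariableSpec("C2", ("intracolumnar", "transcolumnar")),
    VariableSpec("C3", ("centered", "displaced")),
    VariableSpec("C4", ("ascending", "descending", "both", "no")),
    VariableSpec("C5", ("AR", "CR", "CH", "CB", "CT", "HT", "LB", "MA", "NG", "OT")),
))

_C4_DIRECTIONAL = ("ascending", "descending", "both")


@dataclass
class AnnotationMatrix:
    """Per-neuron annotation matrix: one row per annotator.

    ``rows`` holds columns annotator_id, characterized (bool) and C1..C5;
    uncharacterized rows carry no C1..C5 values (NaN).
    """

    neuron_id: str
    rows: pd.DataFrame
    annotator_count_total: int | None = None
    schema: NomenclatureSchema = field(default=DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        df = self.rows.copy().reset_index(drop=True)
        if "characterized" not in df.columns:
            df["characterized"] = True
        df["characterized"] = df["characterized"].astype(bool)
        if "annotator_id" not in df.columns:
            df["annotator_id"] = [f"a{i}" for i in range(len(df))]
        for name in self.schema.names:
            if name not in df.columns:
                df[name] = pd.NA
        if self.annotator_count_total is None:
            self.annotator_count_total = len(df)
        if len(df) > self.annotator_count_total:
            raise ValueError("more rows than annotator_count_total")
        char = df[df["characterized"]]
        for name in self.schema.names:
            vals = char[name].dropna()
            allowed = set(self.schema.variable(name).categories)
            bad = set(vals) - allowed
            if bad:
                raise ValueError(
                    f"neuron {self.neuron_id}: value {sorted(bad)[0]!r} "
                    f"not a category of {name}"
                )
        self.rows = df

    def __len__(self) -> int:
        return len(self.rows)

    def characterized_rows(self) -> pd.DataFrame:
        return self.rows[self.rows["characterized"]].reset_index(drop=True)

    def complete_rows(self) -> pd.DataFrame:
        """Characterized rows with all five class values present."""
        char = self.characterized_rows()
        mask = char[list(self.schema.names)].notna().all(axis=1)
        dropped = int((~mask).sum())
        if dropped:
            log.warning(
                "neuron %s: dropping %d partially-labeled row(s)",
                self.neuron_id, dropped,
            )
        return char[mask].reset_index(drop=True)

    def to_dataset(self) -> DiscreteDataset:
        return DiscreteDataset.from_frame(
            self.complete_rows(), self.schema.variables
        )


@dataclass
class EmpiricalDistribution:
    """Sparse relative-frequency distribution over Omega."""

    schema: NomenclatureSchema
    distribution: dict[tuple[str, ...], float]

    def __post_init__(self) -> None:
        total = sum(self.distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("empirical probabilities must sum to 1")

    @property
    def support_size(self) -> int:
        return len(self.distribution)

    def dense(self) -> np.ndarray:
        """Probability vector over Omega in canonical configuration order."""
        vec = np.zeros(self.schema.n_states())
        for config, p in self.distribution.items():
            vec[self.schema.config_index(config)] = p
        return vec


# ---------------------------------------------------------------------------
# filtering and the C4 "no" rule
# ---------------------------------------------------------------------------

def filter_characterized(matrix: AnnotationMatrix,
                         majority_threshold: int | None = None
                         ) -> tuple[AnnotationMatrix, bool]:
    """Drop uncharacterized rows; flag the neuron excluded on a majority.

    A neuron is excluded when at least ``majority_threshold`` annotators
    (default ceil(total/2); 21 of 42 for the full panel) marked it
    uncharacterized — such a cell cannot be reliably classified.
    """
    total = matrix.annotator_count_total
    if majority_threshold is None:
        majority_threshold = math.ceil(total / 2)
    n_unchar = int((~matrix.rows["characterized"]).sum())
    excluded = n_unchar >= majority_threshold
    kept = matrix.characterized_rows()
    if len(kept) == 0 and not excluded:
        raise ValueError(
            f"neuron {matrix.neuron_id}: no characterized rows but not excluded"
        )
    filtered = AnnotationMatrix(
        matrix.neuron_id, kept, matrix.annotator_count_total, matrix.schema
    )
    return filtered, excluded


def apply_c4_no_rule(row, schema: NomenclatureSchema = DEFAULT_SCHEMA):
    """Force C4 = "no" unless the cell is translaminar *and* displaced.

    The vertical-orientation feature only discriminates among translaminar,
    displaced cells; for every other cell it is fixed to the "no" category.
    """
    row = dict(row)
    if pd.isna(row.get("C1")) or pd.isna(row.get("C3")):
        raise ValueError("C1 and C3 required before applying the C4 rule")
    if row["C1"] == "translaminar" and row["C3"] == "displaced":
        if row.get("C4") not in _C4_DIRECTIONAL:
            raise ValueError(
                "translaminar+displaced row must have C4 in "
                f"{_C4_DIRECTIONAL}, got {row.get('C4')!r}"
            )
    else:
        row["C4"] = "no"
    return row


def apply_c4_rule_to_distribution(vec: np.ndarray,
                                  schema: NomenclatureSchema = DEFAULT_SCHEMA
                                  ) -> np.ndarray:
    """Push a joint distribution over Omega through the C4 "no" rule.

    Label distributions expressed by annotators are always rule-consistent,
    so a generating distribution must be transformed before comparing it
    with empirical or learned label distributions: mass on cells that are
    not translaminar-and-displaced moves to their C4 = "no" counterpart,
    and (translaminar, displaced, C4 = "no") mass — unreachable under the
    rule — spreads uniformly over the three directional categories.
    """
    names = schema.names
    i1, i3, i4 = names.index("C1"), names.index("C3"), names.index("C4")
    c1 = schema.variable("C1").code("translaminar")
    c3 = schema.variable("C3").code("displaced")
    no = schema.variable("C4").code("no")
    directional = [c for c in range(schema.variable("C4").cardinality) if c != no]
    g = np.asarray(vec, dtype=float).reshape(schema.cardinalities)
    out = np.zeros_like(g)

    def sel(axis_values: dict[int, int]) -> tuple:
        return tuple(axis_values.get(ax, slice(None)) for ax in range(g.ndim))

    # rule applies: translaminar & displaced keeps directional mass,
    # "no" mass is redistributed
    td = {i1: c1, i3: c3}
    for c in directional:
        out[sel({**td, i4: c})] += g[sel({**td, i4: c})]
        out[sel({**td, i4: c})] += g[sel({**td, i4: no})] / len(directional)
    # everywhere else all C4 mass collapses onto "no"
    mask = np.ones(g.shape, dtype=bool)
    mask[sel(td)] = False
    collapsed = np.where(mask, g, 0.0).sum(axis=i4)
    out[sel({i4: no})] += np.where(mask[sel({i4: no})], collapsed, 0.0)
    return out.ravel()


def apply_c4_rule(matrix: AnnotationMatrix) -> AnnotationMatrix:
    """Apply the C4 "no" rule to every characterized row of a matrix."""
    df = matrix.rows.copy()
    mask = df["characterized"]
    for i in df.index[mask]:
        fixed = apply_c4_no_rule(df.loc[i, list(matrix.schema.names)], matrix.schema)
        df.loc[i, "C4"] = fixed["C4"]
    return AnnotationMatrix(
        matrix.neuron_id, df, matrix.annotator_count_total, matrix.schema
    )


# ---------------------------------------------------------------------------
# distributions, LBNs and crisp truths
# ---------------------------------------------------------------------------

def empirical_distribution(matrix: AnnotationMatrix) -> EmpiricalDistribution:
    """Relative frequency of each complete label vector in the matrix."""
    rows = matrix.complete_rows()
    if len(rows) == 0:
        raise ValueError(f"neuron {matrix.neuron_id}: empty annotation matrix")
    tuples = [tuple(r) for r in rows[list(matrix.schema.names)].itertuples(index=False)]
    n = len(tuples)
    counts: dict[tuple[str, ...], int] = {}
    for t in tuples:
        counts[t] = counts.get(t, 0) + 1
    return EmpiricalDistribution(
        matrix.schema, {t: c / n for t, c in counts.items()}
    )


def learn_lbn(matrix: AnnotationMatrix, score: str = "bde", ess: float = 1.0,
              seed: int = 0, **tabu_kwargs) -> BayesianNetwork:
    """Learn a label Bayesian network from one annotation matrix.

    Structure by tabu search under ``score``, parameters by maximum
    likelihood.  The fit quality (Jensen–Shannon divergence between the
    network's joint and the empirical label distribution) is logged.
    """
    data = matrix.to_dataset()
    if len(data) == 0:
        raise ValueError(f"neuron {matrix.neuron_id}: empty annotation matrix")
    structure = tabu_learn(data, score=score, ess=ess, seed=seed, **tabu_kwargs)
    bn = fit_mle(structure, data)
    from .evaluation import js_divergence  # local import avoids a cycle
    from .bayesnet import enumerate_joint
    djs = js_divergence(
        empirical_distribution(matrix).dense(), enumerate_joint(bn).ravel()
    )
    log.info("neuron %s: LBN d_JS to empirical = %.4f", matrix.neuron_id, djs)
    return bn


def _mode_with_canonical_ties(tuples: list[tuple[str, ...]],
                              schema: NomenclatureSchema) -> tuple[str, ...]:
    counts: dict[tuple[str, ...], int] = {}
    for t in tuples:
        counts[t] = counts.get(t, 0) + 1
    best_count = max(counts.values())
    tied = [t for t, c in counts.items() if c == best_count]
    return min(tied, key=schema.config_index)


def joint_truth(matrix: AnnotationMatrix) -> tuple[str, ...]:
    """Most common complete label vector; ties go to canonical order."""
    rows = matrix.complete_rows()
    if len(rows) == 0:
        raise ValueError(f"neuron {matrix.neuron_id}: empty annotation matrix")
    tuples = [tuple(r) for r in rows[list(matrix.schema.names)].itertuples(index=False)]
    return _mode_with_canonical_ties(tuples, matrix.schema)


def marginal_truth(matrix: AnnotationMatrix) -> tuple[str, ...]:
    """Concatenation of per-variable majority labels; same tie rule."""
    rows = matrix.complete_rows()
    if len(rows) == 0:
        raise ValueError(f"neuron {matrix.neuron_id}: empty annotation matrix")
    out = []
    for v in matrix.schema.variables:
        col = rows[v.name]
        counts = col.value_counts()
        best = counts.max()
        tied = [c for c in counts.index[counts == best]]
        out.append(min(tied, key=v.code))
    return tuple(out)
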