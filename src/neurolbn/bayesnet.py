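"""Discrete Bayesian networks over small categorical domains.

This module implements the probabilistic machinery behind label Bayesian
networks (LBNs): a network is a pair (G, Theta) where G is a DAG over the
class variables and Theta the conditional probability tables (CPTs) of the
factorization

    p(c_1, ..., c_d) = prod_i p(c_i | pa(c_i)).

Everything here assumes complete categorical data and state spaces small
enough to enumerate exactly (the interneuron nomenclature has |Omega| = 320
joint states), which keeps inference, most-probable-explanation queries and
divergence computations exact.

Structure learning follows the search+score paradigm: a tabu search over
single-arc moves (add / delete / reverse) guided by a decomposable score
(BIC, K2 or BDe).  Local scores are memoized per (child, parent-set), so on
a handful of variables the search itself is effectively free after one pass
of counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "VariableSpec",
    "DagStructure",
    "Cpt",
    "BayesianNetwork",
    "DiscreteDataset",
    "free_parameter_count",
    "score_structure",
    "fit_mle",
    "tabu_learn",
    "logic_sample",
    "joint_probability",
    "enumerate_joint",
    "mpe",
    "node_marginal",
]

SCORES = ("bic", "k2", "bde")

#: guard for exact enumeration of the joint state space
MAX_ENUMERABLE_STATES = 10**6


@dataclass(frozen=True)
class VariableSpec:
    """A categorical variable: a name plus an ordered category list.

    The category order is part of the contract — it fixes CPT column
    layout, the canonical (odometer) order of joint configurations, and
    therefore every tie-break in the package.
    """

    name: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        if len(self.categories) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"variable {self.name!r} has duplicate categories")

    @property
    def cardinality(self) -> int:
        return len(self.categories)

    def code(self, value: str) -> int:
        try:
            return self.categories.index(value)
        except ValueError:
            raise KeyError(
                f"value {value!r} not among categories of {self.name!r}"
            ) from None


@dataclass(frozen=True)
class DagStructure:
    """A directed acyclic graph over named nodes."""

    nodes: tuple[str, ...]
    arcs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "arcs", frozenset(self.arcs))
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        for u, v in self.arcs:
            if u not in node_set or v not in node_set:
                raise ValueError(f"arc ({u}, {v}) references undeclared node")
            if u == v:
                raise ValueError(f"self-loop on {u}")
        self.topological_order()  # raises on cycles

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in declaration (node-list) order."""
        ps = {u for u, v in self.arcs if v == node}
        return tuple(n for n in self.nodes if n in ps)

    def topological_order(self) -> tuple[str, ...]:
        indeg = {n: 0 for n in self.nodes}
        for _, v in self.arcs:
            indeg[v] += 1
        order: list[str] = []
        ready = [n for n in self.nodes if indeg[n] == 0]
        while ready:
            n = ready.pop(0)
            order.append(n)
            for u, v in sorted(self.arcs):
                if u == n:
                    indeg[v] -= 1
                    if indeg[v] == 0:
                        ready.append(v)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return tuple(order)


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table of one child given its parents.

    ``table`` has shape (q, r): one row per parent configuration, one
    column per child category.  Rows are laid out in odometer order over
    the parent categories with the *rightmost* parent cycling fastest.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 2:
            raise ValueError("CPT table must be 2-D (parent configs x categories)")
        if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
            raise ValueError("CPT entries must lie in [0, 1]")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every CPT row must sum to 1")
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "table", t)


@dataclass(frozen=True)
class BayesianNetwork:
    """(structure, CPTs) over a fixed list of categorical variables."""

    variables: tuple[VariableSpec, ...]
    structure: DagStructure
    cpts: Mapping[str, Cpt]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "cpts", dict(self.cpts))
        names = tuple(v.name for v in self.variables)
        if names != self.structure.nodes:
            raise ValueError("structure nodes must match variable order")
        card = {v.name: v.cardinality for v in self.variables}
        for name in names:
            cpt = self.cpts.get(name)
            if cpt is None:
                raise ValueError(f"missing CPT for {name}")
            if cpt.parents != self.structure.parents(name):
                raise ValueError(f"CPT parents of {name} disagree with graph")
            q = int(np.prod([card[p] for p in cpt.parents], dtype=int)) if cpt.parents else 1
            if cpt.table.shape != (q, card[name]):
                raise ValueError(f"CPT of {name} has shape {cpt.table.shape}, expected {(q, card[name])}")

    # -- helpers -----------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(v.cardinality for v in self.variables)

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def n_states(self) -> int:
        return int(np.prod(self.cardinalities, dtype=np.int64))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "categories": list(v.categories)}
                for v in self.variables
            ],
            "arcs": sorted([list(a) for a in self.structure.arcs]),
            "cpts": {
                name: {
                    "parents": list(cpt.parents),
                    "rows": cpt.table.tolist(),
                }
                for name, cpt in self.cpts.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BayesianNetwork":
        variables = tuple(
            VariableSpec(v["name"], tuple(v["categories"])) for v in d["variables"]
        )
        structure = DagStructure(
            tuple(v.name for v in variables),
            frozenset((a[0], a[1]) for a in d["arcs"]),
        )
        cpts = {
            name: Cpt(name, tuple(c["parents"]), np.asarray(c["rows"], dtype=float))
            for name, c in d["cpts"].items()
        }
        return cls(variables, structure, cpts)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BayesianNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DiscreteDataset:
    """Complete categorical observations, stored as integer codes.

    ``codes`` has shape (n_rows, n_variables); entry (i, j) indexes into
    ``variables[j].categories``.
    """

    variables: tuple[VariableSpec, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        codes = np.asarray(self.codes)
        if codes.size == 0:
            codes = codes.reshape(0, len(self.variables))
        if codes.ndim != 2 or codes.shape[1] != len(self.variables):
            raise ValueError("codes must have one column per variable")
        for j, v in enumerate(self.variables):
            col = codes[:, j]
            if col.size and (col.min() < 0 or col.max() >= v.cardinality):
                raise ValueError(f"out-of-range code in column {v.name}")
        self.codes = codes.astype(np.int64, copy=False)

    def __len__(self) -> int:
        return self.codes.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variables: Sequence[VariableSpec]) -> "DiscreteDataset":
        variables = tuple(variables)
        cols = []
        for v in variables:
            if v.name not in df.columns:
                raise ValueError(f"missing column {v.name}")
            cat = pd.Categorical(df[v.name], categories=list(v.categories))
            if cat.isna().any():
                bad = df[v.name][np.asarray(cat.codes) == -1].iloc[0]
                raise ValueError(f"value {bad!r} not a category of {v.name}")
            cols.append(np.asarray(cat.codes, dtype=np.int64))
        codes = np.column_stack(cols) if cols and len(df) else np.empty((0, len(variables)), dtype=np.int64)
        return cls(variables, codes)

    def to_frame(self) -> pd.DataFrame:
        data = {
            v.name: [v.categories[c] for c in self.codes[:, j]]
            for j, v in enumerate(self.variables)
        }
        return pd.DataFrame(data, columns=[v.name for v in self.variables])

    @classmethod
    def from_csv(cls, path, variables: Sequence[VariableSpec]) -> "DiscreteDataset":
        return cls.from_frame(pd.read_csv(path, dtype=str), variables)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# parameter counting and scoring
# ---------------------------------------------------------------------------

def free_parameter_count(bn: BayesianNetwork) -> int:
    """Number of independent CPT entries, sum_i (r_i - 1) * q_i."""
    total = 0
    for name, cpt in bn.cpts.items():
        r = bn.variable(name).cardinality
        q = cpt.table.shape[0]
        total += (r - 1) * q
    return total


def _counts(codes: np.ndarray, cards: Sequence[int], child: int,
            parents: Sequence[int]) -> np.ndarray:
    """Contingency table N_jk, shape (q, r); odometer parent rows."""
    r = cards[child]
    if parents:
        pcards = [cards[p] for p in parents]
        q = int(np.prod(pcards, dtype=int))
        pc = np.ravel_multi_index(
            tuple(codes[:, p] for p in parents), tuple(pcards)
        )
    else:
        q = 1
        pc = np.zeros(len(codes), dtype=np.int64)
    flat = pc * r + codes[:, child]
    return np.bincount(flat, minlength=q * r).reshape(q, r).astype(float)


def _local_score(counts: np.ndarray, n_total: int, score: str, ess: float) -> float:
    """Decomposable local score of one child given one parent set."""
    q, r = counts.shape
    nj = counts.sum(axis=1)
    if score == "bic":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(counts > 0, counts / np.where(nj[:, None] > 0, nj[:, None], 1), 1.0)
            ll = float(np.sum(counts * np.log(ratio)))
        return ll - 0.5 * np.log(n_total) * (r - 1) * q
    if score == "k2":
        return float(
            np.sum(gammaln(r) - gammaln(nj + r)) + np.sum(gammaln(counts + 1))
        )
    if score == "bde":
        a = ess / (r * q)
        aj = ess / q
        return float(
            np.sum(gammaln(aj) - gammaln(aj + nj))
            + np.sum(gammaln(a + counts) - gammaln(a))
        )
    raise ValueError(f"unknown score {score!r}; expected one of {SCORES}")


def score_structure(structure: DagStructure, data: DiscreteDataset,
                    score: str = "bde", ess: float = 1.0) -> float:
    """Log score of a DAG on complete data (higher is better).

    ``score`` is one of ``bic`` (penalized log-likelihood), ``k2``
    (Cooper–Herskovits marginal likelihood, Dirichlet(1) cells) or ``bde``
    (likelihood-equivalent Dirichlet marginal likelihood with equivalent
    sample size ``ess``).
    """
    score = score.lower()
    if score not in SCORES:
        raise ValueError(f"unknown score {score!r}; expected one of {SCORES}")
    if len(data) == 0:
        raise ValueError("cannot score an empty dataset")
    names = tuple(v.name for v in data.variables)
    if names != structure.nodes:
        raise ValueError("structure nodes must match dataset variables")
    cards = [v.cardinality for v in data.variables]
    idx = {n: i for i, n in enumerate(names)}
    total = 0.0
    for name in names:
        pidx = [idx[p] for p in structure.parents(name)]
        counts = _counts(data.codes, cards, idx[name], pidx)
        total += _local_score(counts, len(data), score, ess)
    return total


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

def fit_mle(structure: DagStructure, data: DiscreteDataset) -> BayesianNetwork:
    """Maximum-likelihood CPTs: relative frequencies per parent config.

    A parent configuration never observed in the data gets a uniform row
    (the sampling data cannot inform it; the fallback keeps the network
    valid).
    """
    if len(data) == 0:
        raise ValueError("cannot fit on an empty dataset")
    names = tuple(v.name for v in data.variables)
    if names != structure.nodes:
        raise ValueError("structure nodes must match dataset variables")
    cards = [v.cardinality for v in data.variables]
    idx = {n: i for i, n in enumerate(names)}
    cpts = {}
    for name in names:
        parents = structure.parents(name)
        pidx = [idx[p] for p in parents]
        counts = _counts(data.codes, cards, idx[name], pidx)
        nj = counts.sum(axis=1, keepdims=True)
        r = cards[idx[name]]
        table = np.where(nj > 0, counts / np.where(nj > 0, nj, 1), 1.0 / r)
        cpts[name] = Cpt(name, parents, table)
    return BayesianNetwork(data.variables, structure, cpts)


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

def tabu_learn(data: DiscreteDataset, score: str = "bde", ess: float = 1.0,
               tabu_len: int = 10, max_iter: int | None = None,
               seed: int = 0) -> DagStructure:
    """Tabu search over DAG structures with add/delete/reverse arc moves.

    The search starts from the empty graph, applies the best admissible
    move each iteration (even if worsening, to escape local optima), keeps
    a tabu list of recently undone moves, and returns the best-scoring
    structure visited.  Ties between equal-score moves are broken by the
    canonical (node-order, arc-lexicographic) move order, which together
    with the memoized local scores makes the run fully deterministic;
    ``seed`` is accepted for interface uniformity but the default search
    uses no randomness.
    """
    score = score.lower()
    if score not in SCORES:
        raise ValueError(f"unknown score {score!r}; expected one of {SCORES}")
    if len(data) == 0:
        raise ValueError("cannot learn from an empty dataset")
    names = tuple(v.name for v in data.variables)
    d = len(names)
    if max_iter is None:
        max_iter = 100 * d * d
    cards = [v.cardinality for v in data.variables]
    n = len(data)

    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(child: int, parents: frozenset[int]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in cache:
            counts = _counts(data.codes, cards, child, sorted(parents))
            cache[key] = _local_score(counts, n, score, ess)
        return cache[key]

    parent_sets: list[frozenset[int]] = [frozenset() for _ in range(d)]

    def creates_cycle(u: int, v: int, psets: list[frozenset[int]]) -> bool:
        # would arc u->v close a directed path v ~> u?
        stack, seen = [u], {u}
        while stack:
            x = stack.pop()
            if x == v:
                return True
            for p in psets[x]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return False

    def total_score(psets: list[frozenset[int]]) -> float:
        return sum(local(i, psets[i]) for i in range(d))

    current = total_score(parent_sets)
    best = current
    best_sets = [frozenset(s) for s in parent_sets]
    # tabu maps a forbidden move to its expiry iteration
    tabu: dict[tuple[str, int, int], int] = {}
    since_best = 0  # iterations since the incumbent last improved

    for it in range(max_iter):
        candidates: list[tuple[float, tuple[str, int, int]]] = []
        for u in range(d):
            for v in range(d):
                if u == v:
                    continue
                if u in parent_sets[v]:
                    # delete u->v, or reverse to v->u
                    delta_del = local(v, parent_sets[v] - {u}) - local(v, parent_sets[v])
                    candidates.append((delta_del, ("del", u, v)))
                    trial = [set(s) for s in parent_sets]
                    trial[v] = set(parent_sets[v]) - {u}
                    if not creates_cycle(v, u, [frozenset(s) for s in trial]):
                        delta_rev = delta_del + (
                            local(u, parent_sets[u] | {v}) - local(u, parent_sets[u])
                        )
                        candidates.append((delta_rev, ("rev", u, v)))
                else:
                    if v in parent_sets[u]:
                        continue  # adding u->v handled as reverse of v->u
                    if creates_cycle(u, v, parent_sets):
                        continue
                    delta_add = local(v, parent_sets[v] | {u}) - local(v, parent_sets[v])
                    candidates.append((delta_add, ("add", u, v)))

        chosen = None
        for delta, move in sorted(candidates, key=lambda c: (-c[0], c[1])):
            expired = tabu.get(move, -1) <= it
            aspiration = current + delta > best + 1e-12
            if expired or aspiration:
                chosen = (delta, move)
                break
        if chosen is None:
            break
        delta, (kind, u, v) = chosen
        if kind == "add":
            parent_sets[v] = parent_sets[v] | {u}
            tabu[("del", u, v)] = it + 1 + tabu_len
        elif kind == "del":
            parent_sets[v] = parent_sets[v] - {u}
            tabu[("add", u, v)] = it + 1 + tabu_len
        else:  # reverse u->v into v->u
            parent_sets[v] = parent_sets[v] - {u}
            parent_sets[u] = parent_sets[u] | {v}
            tabu[("rev", v, u)] = it + 1 + tabu_len
        current += delta
        if current > best + 1e-12:
            best = current
            best_sets = [frozenset(s) for s in parent_sets]
            since_best = 0
        else:
            since_best += 1
            if since_best >= max(tabu_len, 1):
                break

    arcs = frozenset(
        (names[u], names[v]) for v in range(d) for u in best_sets[v]
    )
    return DagStructure(names, arcs)


# ---------------------------------------------------------------------------
# sampling and inference
# ---------------------------------------------------------------------------

def logic_sample(bn: BayesianNetwork, n: int, seed: int | np.random.SeedSequence = 0) -> DiscreteDataset:
    """Probabilistic logic (forward / ancestral) sampling: n complete rows."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    names = bn.names
    idx = {name: i for i, name in enumerate(names)}
    cards = bn.cardinalities
    codes = np.zeros((n, len(names)), dtype=np.int64)
    for name in bn.structure.topological_order():
        i = idx[name]
        cpt = bn.cpts[name]
        if n == 0:
            continue
        if cpt.parents:
            pcards = tuple(cards[idx[p]] for p in cpt.parents)
            pc = np.ravel_multi_index(
                tuple(codes[:, idx[p]] for p in cpt.parents), pcards
            )
        else:
            pc = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(cpt.table, axis=1)
        u = rng.random(n)
        codes[:, i] = np.minimum(
            (u[:, None] > cum[pc]).sum(axis=1), cards[i] - 1
        )
    return DiscreteDataset(bn.variables, codes)


def joint_probability(bn: BayesianNetwork, assignment: Mapping[str, str]) -> float:
    """p(c) for one complete configuration, by the chain-rule product."""
    idx = {name: i for i, name in enumerate(bn.names)}
    codes = {}
    for name in bn.names:
        if name not in assignment:
            raise ValueError(f"assignment missing variable {name}")
        codes[name] = bn.variable(name).code(assignment[name])
    cards = bn.cardinalities
    p = 1.0
    for name in bn.names:
        cpt = bn.cpts[name]
        if cpt.parents:
            pcards = tuple(cards[idx[q]] for q in cpt.parents)
            pc = int(np.ravel_multi_index(
                tuple(np.asarray(codes[q]) for q in cpt.parents), pcards
            ))
        else:
            pc = 0
        p *= float(cpt.table[pc, codes[name]])
    return p


def enumerate_joint(bn: BayesianNetwork) -> np.ndarray:
    """Exact joint over all configurations, shape = variable cardinalities.

    Flattening in C order yields the canonical configuration order: the
    odometer over variables in schema order, last variable fastest.
    """
    if bn.n_states() > MAX_ENUMERABLE_STATES:
        raise ValueError("state space too large to enumerate")
    names = bn.names
    idx = {name: i for i, name in enumerate(names)}
    cards = bn.cardinalities
    d = len(names)
    joint = np.ones(cards, dtype=float)
    for name in names:
        cpt = bn.cpts[name]
        src_axes = [idx[p] for p in cpt.parents] + [idx[name]]
        t = cpt.table.reshape(
            [cards[idx[p]] for p in cpt.parents] + [cards[idx[name]]]
        )
        order = np.argsort(src_axes)
        t = t.transpose(order)
        shape = [cards[i] if i in src_axes else 1 for i in range(d)]
        joint = joint * t.reshape(shape)
    return joint


def mpe(bn: BayesianNetwork) -> tuple[str, ...]:
    """Most probable explanation: argmax configuration of the joint.

    Ties resolve to the first configuration in canonical odometer order.
    """
    joint = enumerate_joint(bn)
    flat = int(np.argmax(joint))
    codes = np.unravel_index(flat, joint.shape)
    return tuple(v.categories[c] for v, c in zip(bn.variables, codes))


def node_marginal(bn: BayesianNetwork, node: str) -> np.ndarray:
    """Marginal distribution of one variable, by exact enumeration."""
    names = bn.names
    if node not in names:
        raise KeyError(node)
    joint = enumerate_joint(bn)
    axes = tuple(i for i, n in enumerate(names) if n != node)
    return joint.sum(axis=axes)
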