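"""Distance-weighted k-NN consensus of label Bayesian networks.

The classifier is instance-based: to predict the label Bayesian network
(LBN) of an unseen neuron it (1) standardizes the 18 morphometric
predictors, (2) finds the k nearest training neurons by Euclidean
distance, (3) weights each neighbor by its relative closeness,

    w_j = (sum_i d_i - d_j) / ((k - 1) * sum_i d_i),

(4) draws M = k * 500 * c forward samples from the neighbors' LBNs in
proportion to the weights (c = maximal free-parameter count among the k
networks), and (5) learns the consensus network from the pooled samples
with the same search+score procedure used to learn LBNs.

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscores) and compose
with sklearn model selection; the module-level functions are thin wrappers
kept for pipeline scripting.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .bayesnet import (
    BayesianNetwork,
    DiscreteDataset,
    fit_mle,
    free_parameter_count,
    logic_sample,
    tabu_learn,
)

__all__ = [
    "FeatureStandardizer",
    "LbnConsensusKnn",
    "NeighborSet",
    "fit_standardizer",
    "apply_standardizer",
    "nearest_neighbors",
    "neighbor_weights",
    "sample_budget",
    "allocate_samples",
    "consensus_network",
    "predict_lbn",
]


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Z-score features with the sample (n-1) standard deviation.

    Zero-variance features carry no distance information; they are flagged
    and mapped to 0 so they drop out of Euclidean distances.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        if X.shape[0] < 2:
            raise ValueError("need >= 2 training rows to standardize")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=self.ddof)
        self.retained_ = self.scale_ > 0
        if not self.retained_.all():
            warnings.warn(
                f"{int((~self.retained_).sum())} zero-variance feature(s) "
                "excluded from distances",
                stacklevel=2,
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        safe = np.where(self.retained_, self.scale_, 1.0)
        Z = (X - self.mean_) / safe
        Z[:, ~self.retained_] = 0.0
        return Z

    def inverse_transform(self, Z):
        check_is_fitted(self, "mean_")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        safe = np.where(self.retained_, self.scale_, 1.0)
        return Z * safe + self.mean_


@dataclass
class NeighborSet:
    """The k nearest neighbors of one query with weights and sample counts."""

    ids: tuple
    distances: np.ndarray
    weights: np.ndarray
    sample_counts: np.ndarray
    budget: int
    max_free_params: int

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if not np.all(np.diff(d) >= 0):
            raise ValueError("distances must be sorted ascending")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if int(self.sample_counts.sum()) != self.budget:
            raise ValueError("sample counts must sum to the budget")


# ---------------------------------------------------------------------------
# functional building blocks
# ---------------------------------------------------------------------------

def fit_standardizer(train_features) -> FeatureStandardizer:
    return FeatureStandardizer().fit(np.asarray(train_features, dtype=float))


def apply_standardizer(model: FeatureStandardizer, features) -> np.ndarray:
    return model.transform(features)


def nearest_neighbors(query, train_features, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the k nearest training rows.

    Ties at the k-th position keep the lowest training index (stable sort).
    """
    train = np.asarray(train_features, dtype=float)
    q = np.asarray(query, dtype=float).ravel()
    n = train.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n_train ({n}), got {k}")
    d = np.linalg.norm(train - q, axis=1)
    order = np.argsort(d, kind="stable")[:k]
    return order, d[order]


def neighbor_weights(distances) -> np.ndarray:
    """Relative-closeness weights; all-zero distances give uniform 1/k."""
    d = np.asarray(distances, dtype=float)
    k = d.size
    if k < 2:
        raise ValueError("need k >= 2 neighbors")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    s = d.sum()
    if s == 0:
        return np.full(k, 1.0 / k)
    return (s - d) / ((k - 1) * s)


def sample_budget(neighbor_lbns, k: int, per_param: int = 500) -> tuple[int, int]:
    """Total sample count M = k * per_param * c and the driver c."""
    if k < 2:
        raise ValueError("need k >= 2")
    c = max(free_parameter_count(bn) for bn in neighbor_lbns)
    return k * per_param * c, c


def allocate_samples(weights, M: int) -> np.ndarray:
    """Largest-remainder rounding of w_j * M; counts sum to M exactly."""
    w = np.asarray(weights, dtype=float)
    if M < 0:
        raise ValueError("M must be >= 0")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    exact = w * M
    base = np.floor(exact).astype(int)
    short = M - int(base.sum())
    if short:
        remainders = exact - base
        # largest remainders win; ties go to the lowest index
        order = np.lexsort((np.arange(w.size), -remainders))
        base[order[:short]] += 1
    return base


def _neighbor_seed(base_seed: int, neighbor_id) -> np.random.SeedSequence:
    """Stable per-neighbor seed so that neighbor order is irrelevant."""
    h = zlib.crc32(f"{base_seed}:{neighbor_id}".encode())
    return np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, h])


def consensus_network(neighbor_lbns, weights, M: int, score: str = "bde",
                      ess: float = 1.0, seed: int = 0,
                      neighbor_ids=None) -> BayesianNetwork:
    """Learn a consensus network from weight-proportional pooled samples."""
    lbns = list(neighbor_lbns)
    if len(lbns) < 2:
        raise ValueError("need >= 2 networks to form a consensus")
    variables = lbns[0].variables
    for bn in lbns[1:]:
        if bn.variables != variables:
            raise ValueError("neighbor LBNs must share one schema")
    if neighbor_ids is None:
        neighbor_ids = list(range(len(lbns)))
    counts = allocate_samples(weights, M)
    if counts.sum() == 0:
        raise ValueError("sampling budget M must be positive")
    chunks = []
    for bn, m_j, nid in zip(lbns, counts, neighbor_ids):
        if m_j == 0:
            continue
        chunks.append(logic_sample(bn, int(m_j), seed=_neighbor_seed(seed, nid)).codes)
    pooled = DiscreteDataset(variables, np.vstack(chunks))
    structure = tabu_learn(pooled, score=score, ess=ess, seed=seed)
    return fit_mle(structure, pooled)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class LbnConsensusKnn(BaseEstimator):
    """k-NN classifier over label Bayesian networks.

    Parameters
    ----------
    k : number of neighbors (>= 2; the weight formula divides by k - 1).
    score, ess : structure score and BDe equivalent sample size used when
        learning the consensus network.
    per_param : samples per free parameter; the budget is M = k*per_param*c.
    standardize : z-score predictors with training-fold statistics.
    random_state : base seed; per-neighbor sampling seeds are derived from
        it and the neighbor id, so neighbor order cannot change the result.

    Fitted attributes: ``standardizer_``, ``X_``, ``lbns_``, ``ids_``.
    """

    def __init__(self, k: int = 7, score: str = "bde", ess: float = 1.0,
                 per_param: int = 500, standardize: bool = True,
                 random_state: int = 0):
        self.k = k
        self.score = score
        self.ess = ess
        self.per_param = per_param
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y, ids=None):
        """Store training features and their LBNs.

        ``y`` is a sequence of :class:`BayesianNetwork` (one per row of X).
        """
        X = np.asarray(X, dtype=float)
        y = list(y)
        if X.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        if len(y) != X.shape[0]:
            raise ValueError("one LBN required per training row")
        if not 2 <= self.k < X.shape[0]:
            raise ValueError(
                f"k must satisfy 2 <= k < n_train ({X.shape[0]}), got {self.k}"
            )
        for bn in y:
            if not isinstance(bn, BayesianNetwork):
                raise TypeError("y must contain BayesianNetwork instances")
        self.n_features_in_ = X.shape[1]
        self.standardizer_ = FeatureStandardizer().fit(X) if self.standardize else None
        self.X_ = self.standardizer_.transform(X) if self.standardize else X.copy()
        self.lbns_ = y
        self.ids_ = tuple(ids) if ids is not None else tuple(range(X.shape[0]))
        return self

    def _transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return self.standardizer_.transform(X) if self.standardize else X

    def neighbor_set(self, x) -> NeighborSet:
        """The full neighbor bookkeeping for one (already raw) query row."""
        check_is_fitted(self, "X_")
        z = self._transform(x)[0]
        idx, dists = nearest_neighbors(z, self.X_, self.k)
        w = neighbor_weights(dists)
        M, c = sample_budget([self.lbns_[i] for i in idx], self.k, self.per_param)
        counts = allocate_samples(w, M)
        return NeighborSet(
            ids=tuple(self.ids_[i] for i in idx),
            distances=dists, weights=w, sample_counts=counts,
            budget=M, max_free_params=c,
        )

    def predict(self, X) -> list[BayesianNetwork]:
        """Predict one consensus LBN per query row."""
        check_is_fitted(self, "X_")
        Z = self._transform(X)
        out = []
        for z in Z:
            idx, dists = nearest_neighbors(z, self.X_, self.k)
            w = neighbor_weights(dists)
            lbns = [self.lbns_[i] for i in idx]
            M, _ = sample_budget(lbns, self.k, self.per_param)
            out.append(consensus_network(
                lbns, w, M, score=self.score, ess=self.ess,
                seed=self.random_state,
                neighbor_ids=[self.ids_[i] for i in idx],
            ))
        return out

    def predict_crisp(self, X) -> list[tuple[str, ...]]:
        """Most-probable-explanation label vectors of the predicted LBNs."""
        from .bayesnet import mpe
        return [mpe(bn) for bn in self.predict(X)]


def predict_lbn(query_features, train_features, train_lbns, k: int = 7,
                score: str = "bde", ess: float = 1.0, per_param: int = 500,
                seed: int = 0) -> BayesianNetwork:
    """One-shot wrapper: fit on the training set, predict a single query."""
    est = LbnConsensusKnn(k=k, score=score, ess=ess, per_param=per_param,
                          random_state=seed)
    est.fit(np.asarray(train_features, dtype=float), list(train_lbns))
    return est.predict(np.atleast_2d(np.asarray(query_features, dtype=float)))[0]
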