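"""Probabilistic and crisp-label evaluation of LBN predictions.

Probabilistic performance is the Jensen–Shannon divergence (base-2 logs,
so 0 <= d_JS <= 1) between the true and predicted label distributions over
the 320-state joint space, computed by exact enumeration of both networks.

Crisp performance extracts the most probable explanation (MPE) from the
predicted network and compares it against two majority "truths" derived
from the annotation matrix: *global* and *mean* accuracy use the joint
truth (most common complete label vector), per-class *marginal* accuracy
uses the marginal truth (concatenated per-variable modes).

The cross-validation driver runs repeated unstratified k-fold CV
(stratification is impractical with 320 joint classes), learning the
standardization on each training fold, and reports mean +/- sd across
repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import BayesianNetwork, enumerate_joint, mpe
from .classifier import LbnConsensusKnn
from .labels import AnnotationMatrix, joint_truth, marginal_truth

__all__ = [
    "CvPlan",
    "EvaluationReport",
    "js_divergence",
    "multi_dim_accuracies",
    "marginal_accuracy",
    "crisp_from_lbn",
    "cross_validate",
]


def js_divergence(p, q) -> float:
    """Jensen–Shannon divergence between two distributions (base-2 logs).

    d_JS = 1/2 d_KL(p || m) + 1/2 d_KL(q || m) with m = (p + q)/2;
    symmetric, bounded in [0, 1], zero iff p = q.  Inputs are probability
    vectors on the same support ordering.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("distributions must share one support")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not normalized (sum={v.sum():.6g})")
        if np.any(v < -1e-12):
            raise ValueError(f"{name} has negative entries")
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return min(max(0.5 * kl(p, m) + 0.5 * kl(q, m), 0.0), 1.0)


def multi_dim_accuracies(predicted, truths) -> tuple[float, float]:
    """(global, mean) accuracy of predicted label vectors vs joint truths.

    Global accuracy rewards only full 5-tuple matches; mean accuracy
    averages the per-variable match fractions.
    """
    predicted = [tuple(t) for t in predicted]
    truths = [tuple(t) for t in truths]
    if len(predicted) != len(truths):
        raise ValueError("prediction/truth length mismatch")
    if not predicted:
        raise ValueError("empty prediction set")
    d = len(predicted[0])
    n = len(predicted)
    global_acc = sum(p == t for p, t in zip(predicted, truths)) / n
    mean_acc = sum(
        sum(p[l] == t[l] for p, t in zip(predicted, truths)) / n
        for l in range(d)
    ) / d
    return global_acc, mean_acc


def marginal_accuracy(predicted, truths, l: int) -> float:
    """Accuracy of class variable C_l (1-based) vs the marginal truths."""
    predicted = [tuple(t) for t in predicted]
    truths = [tuple(t) for t in truths]
    if len(predicted) != len(truths):
        raise ValueError("prediction/truth length mismatch")
    d = len(predicted[0])
    if not 1 <= l <= d:
        raise ValueError(f"l must be in 1..{d}")
    return sum(p[l - 1] == t[l - 1] for p, t in zip(predicted, truths)) / len(predicted)


def crisp_from_lbn(bn: BayesianNetwork) -> tuple[str, ...]:
    """Crisp label vector of a network: its most probable explanation."""
    return mpe(bn)


@dataclass
class CvPlan:
    """Repeated plain (unstratified) k-fold cross-validation."""

    repetitions: int = 20
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need >= 2 folds")
        if self.repetitions < 1:
            raise ValueError("need >= 1 repetition")

    def fold_indices(self, n: int, repetition: int) -> list[np.ndarray]:
        """Deterministic fold assignment for one repetition."""
        if n < self.folds:
            raise ValueError("fewer instances than folds")
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, repetition])
        )
        return np.array_split(rng.permutation(n), self.folds)


@dataclass
class EvaluationReport:
    """CV summary: probabilistic fit and crisp accuracies, mean +/- sd."""

    js_mean: float
    js_sd: float
    global_acc: float
    global_sd: float
    mean_acc: float
    mean_sd: float
    marginal_acc: dict[str, float]
    marginal_sd: dict[str, float]
    per_repetition: pd.DataFrame
    confusion_c5: pd.DataFrame

    def __post_init__(self) -> None:
        for v in (self.js_mean, self.global_acc, self.mean_acc,
                  *self.marginal_acc.values()):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError("metrics must lie in [0, 1]")
        if self.global_acc > self.mean_acc + 1e-9:
            raise ValueError("global accuracy cannot exceed mean accuracy")

    def to_dict(self) -> dict:
        return {
            "js": {"mean": self.js_mean, "sd": self.js_sd},
            "global_acc": {"mean": self.global_acc, "sd": self.global_sd},
            "mean_acc": {"mean": self.mean_acc, "sd": self.mean_sd},
            "marginal_acc": {
                name: {"mean": self.marginal_acc[name], "sd": self.marginal_sd[name]}
                for name in self.marginal_acc
            },
            "confusion_c5": {
                "labels_true": list(self.confusion_c5.index),
                "labels_predicted": list(self.confusion_c5.columns),
                "counts": self.confusion_c5.values.tolist(),
            },
            "per_repetition": self.per_repetition.to_dict(orient="list"),
        }


def cross_validate(features, matrices: list[AnnotationMatrix],
                   lbns: list[BayesianNetwork], k: int = 7,
                   plan: CvPlan | None = None, score: str = "bde",
                   ess: float = 1.0, per_param: int = 500) -> EvaluationReport:
    """Repeated k-fold CV of the LBN consensus classifier.

    LBNs are learned once, outside this function: the labels do not depend
    on the train/test split.  Within each repetition every instance is
    tested exactly once; JS divergences are averaged per repetition and
    summarized as mean +/- sd across repetitions, as are the accuracies.
    """
    plan = plan or CvPlan()
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if not (len(matrices) == len(lbns) == n):
        raise ValueError("features, matrices and LBNs must align")
    jt = [joint_truth(m) for m in matrices]
    mt = [marginal_truth(m) for m in matrices]
    true_joints = [enumerate_joint(bn).ravel() for bn in lbns]
    schema = matrices[0].schema
    d = len(schema.names)
    c5 = schema.variable("C5")
    confusion = np.zeros((c5.cardinality, c5.cardinality), dtype=int)

    rows = []
    for rep in range(plan.repetitions):
        preds: list[tuple[str, ...] | None] = [None] * n
        js_vals = np.empty(n)
        for fold_id, test_idx in enumerate(plan.fold_indices(n, rep)):
            if len(test_idx) == 0:
                raise ValueError("empty test fold")
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            fold_seed = int(np.random.SeedSequence(
                [plan.seed, rep, fold_id]).generate_state(1)[0] % (2**31))
            est = LbnConsensusKnn(k=k, score=score, ess=ess,
                                  per_param=per_param, random_state=fold_seed)
            est.fit(X[train_idx], [lbns[i] for i in train_idx],
                    ids=[int(i) for i in train_idx])
            predicted = est.predict(X[test_idx])
            for local, i in enumerate(test_idx):
                bn_hat = predicted[local]
                js_vals[i] = js_divergence(
                    true_joints[i], enumerate_joint(bn_hat).ravel()
                )
                preds[i] = mpe(bn_hat)
        global_acc, mean_acc = multi_dim_accuracies(preds, jt)
        rec = {"repetition": rep, "js": float(js_vals.mean()),
               "global_acc": global_acc, "mean_acc": mean_acc}
        for l in range(1, d + 1):
            rec[f"acc_C{l}"] = marginal_accuracy(preds, mt, l)
        rows.append(rec)
        for p, t in zip(preds, mt):
            confusion[c5.code(t[4]), c5.code(p[4])] += 1

    per_rep = pd.DataFrame(rows)
    marg_mean = {f"C{l}": float(per_rep[f"acc_C{l}"].mean()) for l in range(1, d + 1)}
    marg_sd = {f"C{l}": float(per_rep[f"acc_C{l}"].std(ddof=0)) for l in range(1, d + 1)}
    conf = pd.DataFrame(confusion, index=list(c5.categories),
                        columns=list(c5.categories))
    return EvaluationReport(
        js_mean=float(per_rep["js"].mean()), js_sd=float(per_rep["js"].std(ddof=0)),
        global_acc=float(per_rep["global_acc"].mean()),
        global_sd=float(per_rep["global_acc"].std(ddof=0)),
        mean_acc=float(per_rep["mean_acc"].mean()),
        mean_sd=float(per_rep["mean_acc"].std(ddof=0)),
        marginal_acc=marg_mean, marginal_sd=marg_sd,
        per_repetition=per_rep, confusion_c5=conf,
    )
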