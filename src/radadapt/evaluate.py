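"""Final classification and evaluation: LOO random forest, metric suite, .632+ bootstrap.

The classifier is a random forest (bootstrapped trees, m < p split
candidates per node).  Evaluation pools the out-of-fold positive-class
probabilities of a leave-one-out cross-validation into a single ROC, and
reports AUC, accuracy, precision, sensitivity and specificity at the 0.5
vote threshold, predictive values adjusted to an assumed prevalence by
Bayes' rule, Wald 95% confidence intervals (Hanley-McNeil for the AUC),
and the Efron-Tibshirani .632+ bootstrap error estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data_io import FeatureTable, InputError
from .selection import design_matrix, positive_class_of

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class RFParams:
    """Random-forest hyperparameters; m (split candidates) stays below p."""

    n_trees: int = 500
    max_features: int | None = None  # None -> floor(sqrt(p))
    bootstrap: bool = True
    seed: int = 0

    def resolve_m(self, p: int) -> int:
        if self.max_features is None:
            m = max(1, int(np.floor(np.sqrt(p))))
        else:
            m = self.max_features
        if p > 1 and m >= p:
            raise InputError(f"split-candidate count m={m} must be < p={p}")
        return min(m, p)


def _fit_rf(X: np.ndarray, y: np.ndarray, rf: RFParams, seed: int) -> RandomForestClassifier:
    model = RandomForestClassifier(
        n_estimators=rf.n_trees,
        max_features=rf.resolve_m(X.shape[1]),
        bootstrap=rf.bootstrap,
        random_state=int(seed) % (2 ** 31),
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def _vote_fraction(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting the positive class (label 1) for each row."""
    if 1 not in model.classes_:  # single-class training fold
        return np.zeros(X.shape[0])
    if len(model.classes_) == 1:
        return np.ones(X.shape[0])
    pos_idx = int(np.where(model.classes_ == 1)[0][0])
    votes = np.zeros(X.shape[0])
    for est in model.estimators_:
        votes += (est.predict(X) == pos_idx)
    return votes / len(model.estimators_)


def loo_predict(table: FeatureTable, signature: list[str], rf: RFParams | None = None,
                positive_class: str | None = None) -> np.ndarray:
    """Pooled out-of-fold positive-class probabilities of a LOO cross-validation."""
    rf = rf or RFParams()
    if table.n < 3:
        raise InputError("need at least 3 rows for leave-one-out evaluation")
    if not signature:
        raise InputError("signature must be non-empty")
    sub = table.select(list(signature))  # raises on unknown names
    pos = positive_class or positive_class_of(table)
    y = (sub.labels == pos).astype(np.int64)
    if y.min() == y.max():
        raise InputError("both classes must be present")
    X = design_matrix(sub)
    probs = np.empty(table.n)
    for i in range(table.n):
        tr = np.ones(table.n, dtype=bool)
        tr[i] = False
        model = _fit_rf(X[tr], y[tr], rf, seed=rf.seed + i)
        probs[i] = _vote_fraction(model, X[i:i + 1])[0]
    return probs


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _wald_ci(p: float, n: int) -> tuple[float, float]:
    half = Z95 * np.sqrt(p * (1.0 - p) / n)
    return (p - half, p + half)


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class EvaluationReport:
    probs: np.ndarray
    labels: np.ndarray
    positive_class: str
    prevalence: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    ppv_adj: float
    npv_adj: float
    loo_error: float
    wald_cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    b632plus_error: float | None = None

    def to_dict(self) -> dict:
        d = {
            "positive_class": self.positive_class,
            "prevalence": self.prevalence,
            "confusion": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
            "auc": self.auc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv_adj": self.ppv_adj,
            "npv_adj": self.npv_adj,
            "loo_error": self.loo_error,
            "wald_cis": {k: list(v) for k, v in self.wald_cis.items()},
            "probs": [float(x) for x in self.probs],
        }
        if self.b632plus_error is not None:
            d["b632plus_error"] = self.b632plus_error
        return d

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def auc_trapezoidal(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC of the pooled ROC by the trapezoidal rule (ties handled at midpoint).

    Equivalent to the Mann-Whitney statistic with ties counted 1/2.
    """
    y = np.asarray(y).astype(bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y]
    neg = scores[~y]
    if pos.size == 0 or neg.size == 0:
        raise InputError("AUC needs both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))


def compute_metrics(probs: np.ndarray, labels: np.ndarray, positive_class: str,
                    prevalence: float = 0.40) -> EvaluationReport:
    """Metric suite from pooled out-of-fold probabilities.

    Confusion counts use the 0.5 vote threshold.  PPV/NPV are adjusted to the
    assumed prevalence pi: ppv = sens*pi / (sens*pi + (1-spec)(1-pi)) and
    npv = spec(1-pi) / (spec(1-pi) + (1-sens)pi).  Wald 95% CIs use
    n = number of predictions; the AUC CI uses the Hanley-McNeil SE.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if probs.shape[0] != labels.shape[0]:
        raise InputError("probs and labels must be aligned")
    if not (0 < prevalence < 1):
        raise InputError("assumed prevalence pi must lie in (0, 1)")
    y = (labels == positive_class)
    if y.all() or (~y).all():
        raise InputError("labels contain a single class")
    n = probs.size
    pred = probs >= 0.5
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    pi = prevalence
    denom_p = sensitivity * pi + (1.0 - specificity) * (1.0 - pi)
    denom_n = specificity * (1.0 - pi) + (1.0 - sensitivity) * pi
    ppv_adj = sensitivity * pi / denom_p if denom_p > 0 else 0.0
    npv_adj = specificity * (1.0 - pi) / denom_n if denom_n > 0 else 0.0
    auc = auc_trapezoidal(y, probs)
    se_auc = hanley_mcneil_se(auc, int(y.sum()), int((~y).sum()))
    cis = {
        "accuracy": _wald_ci(accuracy, n),
        "precision": _wald_ci(precision, n),
        "sensitivity": _wald_ci(sensitivity, n),
        "specificity": _wald_ci(specificity, n),
        "ppv_adj": _wald_ci(ppv_adj, n),
        "npv_adj": _wald_ci(npv_adj, n),
        "auc": (auc - Z95 * se_auc, auc + Z95 * se_auc),
    }
    return EvaluationReport(
        probs=probs, labels=labels, positive_class=positive_class, prevalence=pi,
        tp=tp, fp=fp, tn=tn, fn=fn, auc=auc, accuracy=accuracy,
        precision=precision, sensitivity=sensitivity, specificity=specificity,
        ppv_adj=ppv_adj, npv_adj=npv_adj, loo_error=1.0 - accuracy, wald_cis=cis,
    )


# ---------------------------------------------------------------------------
# .632+ bootstrap
# ---------------------------------------------------------------------------

def b632plus_from_components(err_bar: float, eps0: float, gamma: float) -> float:
    """Combine resubstitution error, leave-one-out bootstrap error and the
    no-information rate into the .632+ estimate."""
    eps0p = min(eps0, gamma)
    denom = gamma - err_bar
    if denom <= 0:
        r = 0.0
    else:
        r = (eps0 - err_bar) / denom
        r = min(max(r, 0.0), 1.0)
    w = 0.632 / (1.0 - 0.368 * r)
    return (1.0 - w) * err_bar + w * eps0p


@dataclass
class Bootstrap632Result:
    value: float
    err_bar: float
    eps0: float
    gamma: float
    B: int


def bootstrap_632plus(table: FeatureTable, signature: list[str],
                      rf: RFParams | None = None, B: int = 200,
                      positive_class: str | None = None) -> Bootstrap632Result:
    """.632+ bootstrap misclassification estimate of the signature classifier.

    err_bar: resubstitution error of a forest trained on the full table.
    eps0: leave-one-out bootstrap error — for each row, the mean error over
    the replicates in which it is out-of-bag (rows never out-of-bag are
    excluded).  gamma: no-information rate sum_k p_k (1 - q_k) from the
    observed class proportions p and predicted proportions q.
    """
    rf = rf or RFParams()
    if B < 2:
        raise InputError("bootstrap replicate count B must be >= 2")
    sub = table.select(list(signature))
    pos = positive_class or positive_class_of(table)
    y = (sub.labels == pos).astype(np.int64)
    X = design_matrix(sub)
    n = table.n

    full = _fit_rf(X, y, rf, seed=rf.seed)
    resub_pred = (_vote_fraction(full, X) >= 0.5).astype(np.int64)
    err_bar = float((resub_pred != y).mean())

    p1 = float(y.mean())
    q1 = float(resub_pred.mean())
    gamma = p1 * (1.0 - q1) + (1.0 - p1) * q1

    rng = np.random.default_rng(rf.seed)
    err_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[rows] = False
        if not oob.any() or len(np.unique(y[rows])) < 2:
            continue
        model = _fit_rf(X[rows], y[rows], rf, seed=rf.seed + 1 + b)
        pred = (_vote_fraction(model, X[oob]) >= 0.5).astype(np.int64)
        err_sum[oob] += (pred != y[oob])
        oob_cnt[oob] += 1
    covered = oob_cnt > 0
    if not covered.any():
        raise InputError("no row was ever out-of-bag; increase B")
    eps0 = float((err_sum[covered] / oob_cnt[covered]).mean())
    value = b632plus_from_components(err_bar, eps0, gamma)
    return Bootstrap632Result(value=value, err_bar=err_bar, eps0=eps0, gamma=gamma, B=B)
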