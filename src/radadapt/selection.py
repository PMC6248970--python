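"""Wrapper feature selection with an outer leave-one-out loop.

The signature is found in two nested stages.  Per outer LOO fold, a wrapper
searches the feature-subset space with a greedy forward best-first strategy:
starting from the empty set, each step adds the candidate feature whose
subset scores the highest mean accuracy of a random forest over stratified
2-fold cross-validation of the training rows (averaged over a few repeated
splits, which keeps single-split chance improvements from steering the
search); the search keeps expanding
through non-improving steps and stops after ``backtrack_limit`` consecutive
expansions that fail to improve on the best subset seen, which is returned.
Across the n outer folds every feature accumulates a selection frequency,
and the final signature keeps the features selected in at least a fraction
tau (default 10%) of the folds.

All randomness (fold splits, forest seeds) derives from the run seed, with
per-fold seeds ``seed + fold``; ties are broken by registry (table column)
order throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._wrapper_rf import forest_votes
from .data_io import FeatureTable, InputError


def positive_class_of(table: FeatureTable) -> str:
    """'adaptive' when present, otherwise the first class value of the table."""
    if "adaptive" in table.class_values:
        return "adaptive"
    return table.class_values[0]


def design_matrix(table: FeatureTable) -> np.ndarray:
    """Feature matrix with missing values imputed by the column median."""
    X = table.X.copy()
    for j in np.where(np.isnan(X).any(axis=0))[0]:
        col = X[:, j]
        med = np.nanmedian(col)
        col[np.isnan(col)] = 0.0 if np.isnan(med) else med
    return X


@dataclass
class SelectionReport:
    per_fold_subsets: list[set[str]]
    frequencies: dict[str, float]
    signature: list[str]
    tau: float
    seed: int
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "seed": self.seed,
            "signature": list(self.signature),
            "frequencies": {k: float(v) for k, v in self.frequencies.items()},
            "per_fold_subsets": [sorted(s) for s in self.per_fold_subsets],
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def ranking_log(self) -> str:
        """Human-readable ranking of features by selection frequency."""
        lines = [f"wrapper selection: tau={self.tau} seed={self.seed} "
                 f"folds={len(self.per_fold_subsets)}"]
        order = sorted(self.frequencies.items(), key=lambda kv: (-kv[1], self.feature_names.index(kv[0]) if kv[0] in self.feature_names else 0))
        for name, freq in order:
            if freq > 0:
                mark = " *" if name in self.signature else ""
                lines.append(f"{freq:8.4f}  {name}{mark}")
        return "\n".join(lines) + "\n"


def _stratified_two_fold(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Assign each row to fold 0 or 1, stratified by class."""
    fold = np.empty(y.size, dtype=np.int64)
    for cls in (0, 1):
        rows = np.where(y == cls)[0]
        rows = rng.permutation(rows)
        half = rows.size // 2 + (rows.size % 2 if cls == 0 else 0)
        fold[rows[:half]] = 0
        fold[rows[half:]] = 1
    return fold


def _cv2_accuracy(X: np.ndarray, y: np.ndarray, cols: list[int], folds: np.ndarray,
                  n_trees: int, seed: int) -> float:
    """Wrapper objective: accuracy of the inner forest, averaged over the
    stratified 2-fold splits in ``folds`` (one column per repetition)."""
    accs = []
    Xs = X[:, cols]
    mtry = max(1, int(np.floor(np.sqrt(len(cols)))))
    for rep in range(folds.shape[1]):
        for f in (0, 1):
            tr = folds[:, rep] != f
            te = ~tr
            votes = forest_votes(Xs[tr], y[tr], Xs[te], n_trees=n_trees,
                                 max_features=mtry,
                                 seed=(seed * 64 + 2 * rep + f) % (2 ** 31))
            preds = (votes >= 0.5).astype(np.int64)
            accs.append(float((preds == y[te]).mean()))
    return float(np.mean(accs))


def _majority_baseline(y: np.ndarray, folds: np.ndarray) -> float:
    accs = []
    for rep in range(folds.shape[1]):
        for f in (0, 1):
            tr = folds[:, rep] != f
            maj = 1 if y[tr].sum() * 2 > tr.sum() else 0
            accs.append(float((y[~tr] == maj).mean()))
    return float(np.mean(accs))


def wrapper_search(train_table: FeatureTable, n_trees: int = 100, seed: int = 0,
                   backtrack_limit: int = 5, cv_repeats: int = 5,
                   min_improvement: float = 0.005) -> set[str]:
    """Greedy forward best-first subset search on one training table.

    The objective is the inner forest's accuracy under stratified 2-fold
    cross-validation, averaged over ``cv_repeats`` independent splits to
    keep chance improvements from steering the search.  Returns the
    best-scoring subset found; may be empty when no feature beats the
    majority-class baseline.
    """
    if train_table.n < 4:
        raise InputError("wrapper search needs at least 4 training rows")
    pos = positive_class_of(train_table)
    y = (train_table.labels == pos).astype(np.int64)
    if y.min() == y.max():
        raise InputError("wrapper search needs both classes in the training rows")
    X = design_matrix(train_table)
    rng = np.random.default_rng(seed)
    fold = np.column_stack([_stratified_two_fold(y, rng) for _ in range(cv_repeats)])

    p = train_table.p
    rf_seed = seed * 1009 % (2 ** 31)

    def evaluate(subset: tuple[int, ...]) -> float:
        if not subset:
            return _majority_baseline(y, fold)
        return _cv2_accuracy(X, y, list(subset), fold, n_trees, seed=rf_seed)

    # Best-first over the subset lattice: expand the best unexpanded subset;
    # children add one unused feature each.  Ties resolve to the node pushed
    # first, which follows registry order.
    root: tuple[int, ...] = ()
    root_score = evaluate(root)
    open_list: list[tuple[float, tuple[int, ...]]] = [(root_score, root)]
    seen: set[tuple[int, ...]] = {root}
    best_subset, best_score = root, root_score
    stall = 0
    while open_list and stall < backtrack_limit:
        k_best = max(range(len(open_list)), key=lambda k: open_list[k][0])
        node_score, node = open_list.pop(k_best)
        improved = False
        for j in range(p):  # registry order
            if j in node:
                continue
            child = tuple(sorted(node + (j,)))
            if child in seen:
                continue
            seen.add(child)
            s = evaluate(child)
            open_list.append((s, child))
            if s > best_score + max(min_improvement, 1e-12):
                best_score, best_subset = s, child
                improved = True
        stall = 0 if improved else stall + 1
    return {train_table.feature_names[j] for j in best_subset}


def loo_wrapper_selection(table: FeatureTable, tau: float = 0.10, n_trees: int = 100,
                          seed: int = 0, backtrack_limit: int = 5,
                          cv_repeats: int = 5,
                          min_improvement: float = 0.005) -> SelectionReport:
    """Outer LOO loop around the wrapper; signature = features with frequency >= tau."""
    if not (0 < tau <= 1):
        raise InputError("selection threshold tau must lie in (0, 1]")
    if table.n < 3:
        raise InputError("need at least 3 rows for leave-one-out selection")
    n = table.n
    subsets: list[set[str]] = []
    for i in range(n):
        rows = np.ones(n, dtype=bool)
        rows[i] = False
        fold_table = table.subset_rows(rows)
        subsets.append(wrapper_search(fold_table, n_trees=n_trees,
                                      seed=(seed + i) % (2 ** 31),
                                      backtrack_limit=backtrack_limit,
                                      cv_repeats=cv_repeats,
                                      min_improvement=min_improvement))
    counts = {name: 0 for name in table.feature_names}
    for s in subsets:
        for name in s:
            counts[name] += 1
    freqs = {name: counts[name] / n for name in table.feature_names}
    order = {name: j for j, name in enumerate(table.feature_names)}
    retained = [name for name in table.feature_names if freqs[name] + 1e-12 >= tau]
    retained.sort(key=lambda nm: (-freqs[nm], order[nm]))
    return SelectionReport(
        per_fold_subsets=subsets,
        frequencies=freqs,
        signature=retained,
        tau=tau,
        seed=seed,
        feature_names=list(table.feature_names),
    )
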