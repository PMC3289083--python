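"""Feature ranking and best-first forward selection under chain-level CV.

Features are ranked by the absolute point-biserial correlation with the
binding labels, averaged over the training portions of a 5-fold per-chain
split; a single best-first forward pass then accepts each feature iff it
strictly improves the mean test-fold AUC of a linear-kernel SVM (C = 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)


@dataclass
class FoldSplit:
    """A per-chain assignment of chains to k cross-validation folds."""

    k: int
    assignment: dict
    seed: int

    def fold_of(self, chain_ids: Sequence) -> np.ndarray:
        return np.asarray([self.assignment[c] for c in chain_ids])

    def splits(self, chain_ids: Sequence):
        """Yield (train_mask, test_mask) index masks over residues."""
        folds = self.fold_of(chain_ids)
        for f in range(self.k):
            test = folds == f
            yield ~test, test


def make_folds(chain_ids: Sequence, k: int = 5, seed: int = 0) -> FoldSplit:
    """Assign chains to k folds by a seeded shuffle (round-robin)."""
    unique = list(dict.fromkeys(chain_ids))
    if len(unique) < k:
        raise ValueError(f"need at least {k} chains for {k}-fold CV, "
                         f"got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(unique)))
    assignment = {unique[j]: i % k for i, j in enumerate(order)}
    return FoldSplit(k=k, assignment=assignment, seed=seed)


def biserial_correlation(values: np.ndarray, labels: np.ndarray) -> float:
    """Point-biserial correlation between a feature and binary labels.

    Equals the Pearson correlation of the feature with the 0/1 labels:
    (mean1 - mean0) / sd * sqrt(n1 * n0 / n^2). A zero-variance feature
    returns 0 with a warning; single-class labels are an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length vectors")
    if values.size < 2:
        raise ValueError("need at least 2 samples")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both label classes must be present")
    sd = values.std()
    if sd == 0.0:
        logger.warning("zero-variance feature; biserial correlation set to 0")
        return 0.0
    m1 = values[labels == 1].mean()
    m0 = values[labels == 0].mean()
    return float((m1 - m0) / sd * np.sqrt(n1 * n0 / values.size ** 2))


def _biserial_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized point-biserial correlation of every column with y."""
    y = np.asarray(y, dtype=float)
    n = y.size
    n1 = y.sum()
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both label classes must be present")
    sd = X.std(axis=0)
    m1 = X[y == 1].mean(axis=0)
    m0 = X[y == 0].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (m1 - m0) / sd * np.sqrt(n1 * n0 / n ** 2)
    return np.where(sd == 0.0, 0.0, r)


def rank_features(X: pd.DataFrame, y: np.ndarray,
                  folds: FoldSplit) -> pd.DataFrame:
    """Rank features by |biserial correlation| averaged over fold training sets.

    Correlations are computed on each of the k training sets (union of k-1
    folds), their absolute values averaged, and features sorted descending
    with name as the deterministic tie-break. Returns a DataFrame with
    columns (feature, avg_abs_corr) in rank order.
    """
    y = np.asarray(y, dtype=int)
    chain_ids = X.index.get_level_values(0)
    vals = X.to_numpy()
    acc = np.zeros(vals.shape[1])
    nfolds = 0
    for train, _ in folds.splits(chain_ids):
        acc += np.abs(_biserial_matrix(vals[train], y[train]))
        nfolds += 1
    avg = acc / nfolds
    order = sorted(range(len(avg)), key=lambda j: (-avg[j], X.columns[j]))
    return pd.DataFrame({"feature": [X.columns[j] for j in order],
                         "avg_abs_corr": [avg[j] for j in order]})


@dataclass
class SelectionTrace:
    """Record of a best-first forward selection run."""

    ranking: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    auc_path: list = field(default_factory=list)     # AUC after each acceptance
    decisions: list = field(default_factory=list)    # (feature, auc, kept)
    base_auc: float = 0.0
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "ranking": list(self.ranking),
            "accepted": list(self.accepted),
            "auc_path": [float(a) for a in self.auc_path],
            "decisions": [(f, float(a), bool(k)) for f, a, k in self.decisions],
            "seed": self.seed,
        }


def default_selection_classifier(seed: int = 0):
    """Linear-kernel SVM with C = 1 used to score candidate feature sets."""
    return LinearSVC(C=1.0, random_state=seed)


def _mean_cv_auc(X: np.ndarray, y: np.ndarray, chain_ids, folds: FoldSplit,
                 estimator) -> float:
    aucs = []
    for train, test in folds.splits(chain_ids):
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            logger.warning("degenerate single-class fold skipped in AUC")
            continue
        clf = clone(estimator)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X[train], y[train])
        score = clf.decision_function(X[test])
        aucs.append(roc_auc_score(y[test], score))
    if not aucs:
        raise ValueError("no fold with both classes present")
    return float(np.mean(aucs))


def best_first_forward(X: pd.DataFrame, y: np.ndarray, folds: FoldSplit,
                       estimator=None, tol: float = 1e-6,
                       max_candidates: Optional[int] = None,
                       seed: int = 0) -> SelectionTrace:
    """Single-pass best-first forward selection over the biserial ranking.

    Candidates are visited in rank order; each is retained iff it improves
    the mean test-fold AUC of the evaluation SVM by more than ``tol``.
    ``max_candidates`` truncates the visited portion of the ranking (the
    ranking itself is always complete).
    """
    y = np.asarray(y, dtype=int)
    if estimator is None:
        estimator = default_selection_classifier(seed)
    ranking = rank_features(X, y, folds)
    chain_ids = X.index.get_level_values(0)
    vals = X.to_numpy()
    col_index = {c: j for j, c in enumerate(X.columns)}

    trace = SelectionTrace(ranking=list(ranking["feature"]), seed=seed)
    candidates = trace.ranking
    if max_candidates is not None:
        candidates = candidates[:max_candidates]

    selected: list[int] = []
    best_auc = -np.inf
    for name in candidates:
        j = col_index[name]
        trial = selected + [j]
        auc = _mean_cv_auc(vals[:, trial], y, chain_ids, folds, estimator)
        keep = auc > best_auc + tol if np.isfinite(best_auc) else True
        trace.decisions.append((name, auc, keep))
        if keep:
            selected.append(j)
            best_auc = auc
            trace.accepted.append(name)
            trace.auc_path.append(auc)
    trace.base_auc = best_auc if np.isfinite(best_auc) else 0.0
    return trace


class BestFirstSelector(BaseEstimator):
    """Feature selector: biserial ranking + best-first forward search.

    Fitted attributes: ``ranking_`` (DataFrame), ``trace_``
    (:class:`SelectionTrace`), ``selected_features_`` (column names in
    acceptance order).
    """

    def __init__(self, k_folds: int = 5, tol: float = 1e-6,
                 max_candidates: Optional[int] = None, seed: int = 0):
        self.k_folds = k_folds
        self.tol = tol
        self.max_candidates = max_candidates
        self.seed = seed

    def fit(self, X: pd.DataFrame, y, folds: Optional[FoldSplit] = None):
        if folds is None:
            folds = make_folds(X.index.get_level_values(0), k=self.k_folds,
                               seed=self.seed)
        self.folds_ = folds
        self.ranking_ = rank_features(X, np.asarray(y, dtype=int), folds)
        self.trace_ = best_first_forward(
            X, y, folds, tol=self.tol, max_candidates=self.max_candidates,
            seed=self.seed)
        self.selected_features_ = list(self.trace_.accepted)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.selected_features_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing selected columns: {missing}")
        return X[self.selected_features_]
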