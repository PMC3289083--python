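"""SVM training, kernel/C parameterization and probability binarization.

The predictor is a support vector machine with Platt-scaled probability
outputs, trained on the selected features at the natural class distribution
(~4% binding residues; no resampling). The probability threshold is not fixed
at 0.5 but calibrated to maximize the MCC on the training folds, averaged
over the 5 cross-validation splits; a residue is called binding when its
predicted probability is >= that threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .io import PredictionTrack
from .selection import BestFirstSelector, FoldSplit, make_folds

logger = logging.getLogger(__name__)


def _pow2(lo: int, hi: int) -> tuple[float, ...]:
    return tuple(float(2.0 ** e) for e in range(lo, hi + 1))


@dataclass
class ModelConfig:
    """Kernel/parameter grids for the two-stage SVM search.

    C runs over consecutive powers of 2 in [2^-3, 2^5]. Polynomial degrees
    use the integer grid {1..5}; the RBF gamma grid defaults to powers of 2
    in [2^-7, 2^1].
    """

    kernels: tuple[str, ...] = ("poly", "rbf")
    degree_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    gamma_grid: tuple[float, ...] = _pow2(-7, 1)
    c_grid: tuple[float, ...] = _pow2(-3, 5)

    def __post_init__(self):
        if not (self.kernels and self.degree_grid and self.gamma_grid
                and self.c_grid):
            raise ValueError("grids must be non-empty")


def _make_svc(kernel: str, params: dict, seed: int = 0,
              probability: bool = False) -> SVC:
    kw = dict(params)
    if probability:
        # explicit probability=True: Platt-scaled outputs from libsvm
        return SVC(kernel=kernel, probability=True, random_state=seed, **kw)
    return SVC(kernel=kernel, random_state=seed, **kw)


def _mean_cv_auc(X: np.ndarray, y: np.ndarray, chain_ids, folds: FoldSplit,
                 estimator) -> float:
    aucs = []
    for train, test in folds.splits(chain_ids):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            logger.warning("single-class fold skipped in parameterization")
            continue
        clf = clone(estimator)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X[train], y[train])
        aucs.append(roc_auc_score(y[test], clf.decision_function(X[test])))
    if not aucs:
        raise ValueError("no usable fold in parameterization")
    return float(np.mean(aucs))


def parameterize(X: pd.DataFrame, y: np.ndarray, folds: FoldSplit,
                 config: ModelConfig = ModelConfig(),
                 seed: int = 0) -> tuple[str, dict, list[dict]]:
    """Two-stage kernel parameter search maximizing mean cross-validated AUC.

    For each kernel, the shape parameter (polynomial degree or RBF gamma) is
    tuned first at C = 1, then C over its grid with the shape fixed. The
    winner is the kernel/parameter pair with the highest mean test-fold AUC;
    ties are broken by kernel order in the config. Returns (kernel, params,
    search_log).
    """
    y = np.asarray(y, dtype=int)
    vals = X.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("non-finite feature values")
    chain_ids = X.index.get_level_values(0)
    log: list[dict] = []
    best: Optional[tuple[float, str, dict]] = None

    for kernel in config.kernels:
        if kernel == "poly":
            shape_name, shape_grid = "degree", config.degree_grid
        elif kernel == "rbf":
            shape_name, shape_grid = "gamma", config.gamma_grid
        elif kernel == "linear":
            shape_name, shape_grid = None, (None,)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")

        best_shape = None
        best_shape_auc = -np.inf
        for val in shape_grid:
            params = {shape_name: val} if shape_name else {}
            auc = _mean_cv_auc(vals, y, chain_ids, folds,
                               _make_svc(kernel, {**params, "C": 1.0}, seed))
            log.append({"kernel": kernel, "stage": "shape", **params,
                        "C": 1.0, "auc": auc})
            if auc > best_shape_auc:
                best_shape_auc, best_shape = auc, params

        best_c_auc = -np.inf
        best_c = 1.0
        for c in config.c_grid:
            auc = _mean_cv_auc(vals, y, chain_ids, folds,
                               _make_svc(kernel, {**best_shape, "C": c}, seed))
            log.append({"kernel": kernel, "stage": "C", **best_shape,
                        "C": c, "auc": auc})
            if auc > best_c_auc:
                best_c_auc, best_c = auc, c

        params = {**best_shape, "C": best_c}
        if best is None or best_c_auc > best[0]:
            best = (best_c_auc, kernel, params)

    assert best is not None
    logger.info("parameterization winner: %s %s (AUC %.4f)",
                best[1], best[2], best[0])
    return best[1], best[2], log


def mcc_max_threshold(probabilities: np.ndarray,
                      labels: np.ndarray) -> float:
    """The probability threshold (>= rule) that maximizes the MCC.

    Candidates are the unique predicted probabilities; on ties the smallest
    maximizing candidate is returned. Equivalent to an exhaustive scan over
    all distinct cut points.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to calibrate a threshold")
    order = np.argsort(-p, kind="mergesort")
    ps, ys = p[order], y[order]
    n1 = int(ys.sum())
    n0 = ys.size - n1
    # cumulative TP/FP when thresholding at each sorted value (>= rule)
    tp_cum = np.cumsum(ys)
    fp_cum = np.cumsum(1 - ys)
    # last index of each distinct probability value in the sorted order
    last = np.nonzero(np.append(ps[1:] != ps[:-1], True))[0]
    thresholds = ps[last]
    tp = tp_cum[last].astype(float)
    fp = fp_cum[last].astype(float)
    fn = n1 - tp
    tn = n0 - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(divide="ignore", invalid="ignore"):
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(denom), 0.0)
    best = mcc.max()
    # thresholds are in descending order; the last maximizer is the smallest
    idx = np.nonzero(mcc == best)[0][-1]
    return float(thresholds[idx])


def calibrate_threshold(fold_probabilities: Sequence[np.ndarray],
                        fold_labels: Sequence[np.ndarray]) -> float:
    """Average the per-fold MCC-maximizing thresholds.

    Folds with a single label class are skipped with a warning.
    """
    maximizers = []
    for i, (p, y) in enumerate(zip(fold_probabilities, fold_labels)):
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            logger.warning("fold %d has a single class; skipped in "
                           "threshold calibration", i)
            continue
        maximizers.append(mcc_max_threshold(p, y))
    if not maximizers:
        raise ValueError("no fold usable for threshold calibration")
    return float(np.mean(maximizers))


class AtpSiteClassifier(BaseEstimator, ClassifierMixin):
    """Per-residue binding-site SVM with selection, tuning and calibration.

    ``fit(X, y)`` expects a feature DataFrame indexed by (chain, position)
    (as produced by :class:`~atpsite.features.ResidueFeatureEncoder`) and
    binary labels. Internally it

    1. splits the chains into ``k_folds`` seeded folds,
    2. optionally runs biserial ranking + best-first forward selection,
    3. optionally runs the two-stage kernel/C parameter search
       (``kernel="auto"``), otherwise uses the given kernel and parameters,
    4. calibrates the binarization threshold as the mean of the per-fold
       MCC-maximizing thresholds on training-fold predictions, and
    5. fits the final probability-output SVM on all training residues.

    Fitted attributes: ``selected_features_``, ``kernel_``, ``params_``,
    ``threshold_``, ``estimator_``, ``cv_probabilities_`` (cross-validated
    per-residue probabilities), ``cv_auc_``, ``selection_trace_``.
    """

    def __init__(self, kernel: str = "auto", C: float = 1.0,
                 gamma="scale", degree: int = 3, k_folds: int = 5,
                 select: bool = True, max_candidates: Optional[int] = None,
                 selection_tol: float = 1e-6,
                 config: Optional[ModelConfig] = None,
                 threshold: Optional[float] = None, seed: int = 0):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.k_folds = k_folds
        self.select = select
        self.max_candidates = max_candidates
        self.selection_tol = selection_tol
        self.config = config
        self.threshold = threshold
        self.seed = seed

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y, folds: Optional[FoldSplit] = None):
        y = np.asarray(y, dtype=int)
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a (chain, position)-indexed DataFrame")
        chain_ids = X.index.get_level_values(0)
        if folds is None:
            folds = make_folds(chain_ids, k=self.k_folds, seed=self.seed)
        self.folds_ = folds

        if self.select:
            selector = BestFirstSelector(
                k_folds=self.k_folds, tol=self.selection_tol,
                max_candidates=self.max_candidates, seed=self.seed)
            selector.fit(X, y, folds=folds)
            self.selection_trace_ = selector.trace_
            self.selected_features_ = selector.selected_features_
            if not self.selected_features_:
                logger.warning("selection accepted no features; "
                               "falling back to the top-ranked one")
                self.selected_features_ = list(
                    selector.ranking_["feature"].iloc[:1])
        else:
            self.selection_trace_ = None
            self.selected_features_ = list(X.columns)

        Xs = X[self.selected_features_]

        if self.kernel == "auto":
            config = self.config or ModelConfig()
            self.kernel_, self.params_, self.search_log_ = parameterize(
                Xs, y, folds, config, seed=self.seed)
        else:
            self.kernel_ = self.kernel
            self.params_ = {"C": self.C}
            if self.kernel == "rbf":
                self.params_["gamma"] = self.gamma
            elif self.kernel == "poly":
                self.params_["degree"] = self.degree
            self.search_log_ = []

        vals = Xs.to_numpy()
        fold_train_probs, fold_train_labels = [], []
        cv_probs = np.full(y.shape, np.nan)
        fold_aucs = []
        for train, test in folds.splits(chain_ids):
            if len(np.unique(y[train])) < 2:
                logger.warning("single-class training fold skipped")
                continue
            clf = _make_svc(self.kernel_, self.params_, seed=self.seed,
                            probability=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", FutureWarning)
                clf.fit(vals[train], y[train])
            pos = list(clf.classes_).index(1)
            fold_train_probs.append(clf.predict_proba(vals[train])[:, pos])
            fold_train_labels.append(y[train])
            p_test = clf.predict_proba(vals[test])[:, pos]
            cv_probs[test] = p_test
            if len(np.unique(y[test])) == 2:
                fold_aucs.append(roc_auc_score(y[test], p_test))

        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
        else:
            self.threshold_ = calibrate_threshold(fold_train_probs,
                                                  fold_train_labels)
        self.cv_probabilities_ = pd.Series(cv_probs, index=X.index)
        self.cv_fold_aucs_ = fold_aucs
        self.cv_auc_ = float(np.mean(fold_aucs)) if fold_aucs else None

        final = _make_svc(self.kernel_, self.params_, seed=self.seed,
                          probability=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            final.fit(vals, y)
        self.estimator_ = final
        self.classes_ = final.classes_
        return self

    # -- prediction ---------------------------------------------------------

    def _check_columns(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.selected_features_ if c not in X.columns]
        if missing:
            extra = [c for c in X.columns if c not in self.selected_features_]
            raise ValueError(
                f"feature columns do not match the fitted model; missing="
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}, "
                f"n_extra={len(extra)}")
        return X[self.selected_features_].to_numpy()

    def predict_proba_1(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the binding class per residue."""
        vals = self._check_columns(X)
        pos = list(self.estimator_.classes_).index(1)
        return self.estimator_.predict_proba(vals)[:, pos]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = self.predict_proba_1(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Binary calls: probability >= calibrated threshold."""
        return (self.predict_proba_1(X) >= self.threshold_).astype(int)

    def predict_tracks(self, X: pd.DataFrame,
                       sequences: dict) -> list[PredictionTrack]:
        """Per-chain PredictionTracks for a (chain, position)-indexed matrix."""
        p = self.predict_proba_1(X)
        calls = (p >= self.threshold_).astype(int)
        tracks = []
        chain_ids = X.index.get_level_values(0)
        for cid in dict.fromkeys(chain_ids):
            sel = chain_ids == cid
            tracks.append(PredictionTrack(
                chain_id=cid, residues=sequences[cid],
                probabilities=p[sel], calls=calls[sel],
                threshold=self.threshold_, method="atpsite"))
        return tracks
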