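"""Per-residue and per-sequence evaluation of binding-residue predictions.

Binary calls are scored with sensitivity, specificity, accuracy and the
Matthews correlation coefficient (MCC, defined as 0 when a denominator factor
vanishes, e.g. when everything is predicted binding or non-binding).
Probabilities are scored by the ROC curve obtained by sweeping the threshold
over the predicted values under the >= convention, summarized by the AUC.
Method comparisons use per-chain MCC/AUC vectors, a paired Wilcoxon
signed-rank test, and a Shapiro-Wilk normality check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .io import PredictionTrack

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class BinaryMetrics:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


def confusion_counts(calls: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have equal length")
    tp = int(np.sum((calls == 1) & (labels == 1)))
    tn = int(np.sum((calls == 0) & (labels == 0)))
    fp = int(np.sum((calls == 1) & (labels == 0)))
    fn = int(np.sum((calls == 0) & (labels == 1)))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics_from_counts(c: ConfusionCounts) -> BinaryMetrics:
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    acc = (c.tp + c.tn) / c.n if c.n else float("nan")
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)
    return BinaryMetrics(counts=c, sensitivity=sens, specificity=spec,
                         accuracy=acc, mcc=float(mcc))


def confusion_metrics(calls, labels) -> BinaryMetrics:
    """Sensitivity, specificity, accuracy and MCC of binary calls."""
    return metrics_from_counts(confusion_counts(calls, labels))


@dataclass
class ROCCurve:
    """ROC points (FP-rate, TP-rate) with their thresholds, and the AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(probabilities, labels) -> ROCCurve:
    """ROC by sweeping the threshold over the unique predicted probabilities.

    At each threshold p, residues with probability >= p are called binding.
    The AUC is the trapezoidal area under the resulting step curve (equal to
    the tie-corrected rank-sum statistic). Requires both classes present.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probabilities.shape != labels.shape:
        raise ValueError("probabilities and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined: only one label class present")
    fpr, tpr, thr = roc_curve(labels, probabilities, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def write_roc_tsv(curve: ROCCurve, path) -> None:
    """Export ROC points as TSV (threshold, fpr, tpr) for plotting."""
    with open(path, "w") as fh:
        fh.write(f"# auc: {curve.auc:.6f}\n")
        fh.write("threshold\tfpr\ttpr\n")
        for thr, fpr, tpr in zip(curve.thresholds, curve.fpr, curve.tpr):
            fh.write(f"{thr:.6g}\t{fpr:.6f}\t{tpr:.6f}\n")


@dataclass
class PairedComparison:
    metric: str
    n_pairs: int
    n_dropped: int
    statistic: Optional[float]
    p_value: Optional[float]
    shapiro_p_a: Optional[float]
    shapiro_p_b: Optional[float]
    skipped: bool = False


@dataclass
class PerSequenceStats:
    """Per-chain MCC/AUC for two methods plus paired significance tests."""

    per_chain: Dict[str, dict] = field(default_factory=dict)
    comparisons: Dict[str, PairedComparison] = field(default_factory=dict)


def _shapiro_p(x: np.ndarray) -> Optional[float]:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return None
    return float(stats.shapiro(x).pvalue)


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Identical vectors (all zero differences) return (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b)
    return float(res.statistic), float(res.pvalue)


def per_sequence_compare(tracks_a: Sequence[PredictionTrack],
                         tracks_b: Sequence[PredictionTrack],
                         labels: Dict[str, np.ndarray],
                         min_pairs: int = 6) -> PerSequenceStats:
    """Compare two methods chain by chain on MCC and AUC.

    Per-chain MCC and AUC are computed for each method; chains where a metric
    is undefined for either method (single-class chains for AUC) are dropped
    pairwise with a logged count. Differences are tested with a two-sided
    paired Wilcoxon signed-rank test; Shapiro-Wilk p-values for each metric
    vector are reported alongside. Fewer than ``min_pairs`` valid pairs skips
    the test with a warning.
    """
    by_id_a = {t.chain_id: t for t in tracks_a}
    by_id_b = {t.chain_id: t for t in tracks_b}
    common = [c for c in by_id_a if c in by_id_b and c in labels]
    if set(by_id_a) != set(by_id_b):
        logger.warning("methods cover different chains; using the %d common",
                       len(common))

    out = PerSequenceStats()
    for cid in common:
        y = np.asarray(labels[cid], dtype=int)
        row = {}
        for tag, t in (("a", by_id_a[cid]), ("b", by_id_b[cid])):
            row[f"mcc_{tag}"] = confusion_metrics(t.calls, y).mcc
            try:
                row[f"auc_{tag}"] = roc_auc(t.probabilities, y).auc
            except ValueError:
                row[f"auc_{tag}"] = None
        out.per_chain[cid] = row

    for metric in ("mcc", "auc"):
        va, vb = [], []
        dropped = 0
        for cid in common:
            row = out.per_chain[cid]
            xa, xb = row[f"{metric}_a"], row[f"{metric}_b"]
            if xa is None or xb is None:
                dropped += 1
                continue
            va.append(xa)
            vb.append(xb)
        va, vb = np.asarray(va), np.asarray(vb)
        if dropped:
            logger.info("%s: %d chains dropped pairwise (undefined metric)",
                        metric, dropped)
        if va.size < min_pairs:
            logger.warning("%s: only %d valid pairs (< %d); test skipped",
                           metric, va.size, min_pairs)
            out.comparisons[metric] = PairedComparison(
                metric=metric, n_pairs=int(va.size), n_dropped=dropped,
                statistic=None, p_value=None, shapiro_p_a=_shapiro_p(va),
                shapiro_p_b=_shapiro_p(vb), skipped=True)
            continue
        stat, p = paired_wilcoxon(va, vb)
        out.comparisons[metric] = PairedComparison(
            metric=metric, n_pairs=int(va.size), n_dropped=dropped,
            statistic=stat, p_value=p, shapiro_p_a=_shapiro_p(va),
            shapiro_p_b=_shapiro_p(vb))
    return out


def confidence_bins(probabilities, calls, labels,
                    width: float = 0.05) -> "np.ndarray":
    """Bin residues by predicted probability and report per-bin call accuracy.

    Uses half-open bins [0, w), [w, 2w), ..., with the top bin closed at 1.0.
    Returns a structured array with fields (lo, hi, fraction, accuracy, count);
    accuracy is NaN for empty bins.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if np.any(probabilities < 0) or np.any(probabilities > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    n_bins = int(round(1.0 / width))
    idx = np.minimum((probabilities / width).astype(int), n_bins - 1)
    out = np.zeros(n_bins, dtype=[("lo", float), ("hi", float),
                                  ("fraction", float), ("accuracy", float),
                                  ("count", int)])
    total = probabilities.size
    for b in range(n_bins):
        sel = idx == b
        cnt = int(sel.sum())
        acc = float((calls[sel] == labels[sel]).mean()) if cnt else float("nan")
        out[b] = (b * width, (b + 1) * width,
                  cnt / total if total else 0.0, acc, cnt)
    return out


def pooled_and_averaged_metrics(tracks: Sequence[PredictionTrack],
                                labels: Dict[str, np.ndarray]) -> dict:
    """Residue-pooled and per-chain-averaged summaries for one method."""
    all_calls, all_probs, all_labels = [], [], []
    per_chain_mcc, per_chain_auc = [], []
    for t in tracks:
        y = np.asarray(labels[t.chain_id], dtype=int)
        all_calls.append(t.calls)
        all_probs.append(t.probabilities)
        all_labels.append(y)
        per_chain_mcc.append(confusion_metrics(t.calls, y).mcc)
        try:
            per_chain_auc.append(roc_auc(t.probabilities, y).auc)
        except ValueError:
            pass
    calls = np.concatenate(all_calls)
    probs = np.concatenate(all_probs)
    y = np.concatenate(all_labels)
    pooled = metrics_from_counts(confusion_counts(calls, y))
    pooled_auc = roc_auc(probs, y).auc if len(np.unique(y)) == 2 else None
    return {
        "pooled": {"sens": pooled.sensitivity, "spec": pooled.specificity,
                   "acc": pooled.accuracy, "mcc": pooled.mcc,
                   "auc": pooled_auc},
        "per_chain_mean": {
            "mcc": float(np.mean(per_chain_mcc)) if per_chain_mcc else None,
            "auc": float(np.mean(per_chain_auc)) if per_chain_auc else None,
        },
        "n_chains": len(tracks),
        "n_residues": int(y.size),
    }
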