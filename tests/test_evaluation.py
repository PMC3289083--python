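"""Confusion measures, ROC/AUC, paired tests and confidence binning."""

import itertools

import numpy as np
import pytest
from scipy import stats

from atpsite.evaluation import (confidence_bins, confusion_metrics,
                                paired_wilcoxon, per_sequence_compare,
                                pooled_and_averaged_metrics, roc_auc)
from atpsite.io import PredictionTrack


class TestConfusionMetrics:
    def test_all_predicted_binding_gives_mcc_zero(self):
        labels = np.array([0, 1, 0, 1])
        m = confusion_metrics(np.ones(4, dtype=int), labels)
        assert m.mcc == 0.0
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        m = confusion_metrics(y, y)
        assert (m.mcc, m.sensitivity, m.specificity, m.accuracy) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_fixed_table(self):
        # TP=50, TN=100, FP=10, FN=20 checked against the closed formulas
        calls = np.array([1] * 50 + [0] * 100 + [1] * 10 + [0] * 20)
        labels = np.array([1] * 50 + [0] * 100 + [0] * 10 + [1] * 20)
        m = confusion_metrics(calls, labels)
        assert m.sensitivity == pytest.approx(50 / 70)
        assert m.specificity == pytest.approx(100 / 110)
        assert m.accuracy == pytest.approx(150 / 180)
        expected = (50 * 100 - 10 * 20) / np.sqrt(60 * 70 * 110 * 120)
        assert m.mcc == pytest.approx(expected)

    def test_random_tables_match_sklearn_oracle(self, rng):
        from sklearn.metrics import matthews_corrcoef
        for _ in range(200):
            n = int(rng.integers(4, 40))
            calls = rng.integers(0, 2, size=n)
            labels = rng.integers(0, 2, size=n)
            m = confusion_metrics(calls, labels)
            assert m.mcc == pytest.approx(
                matthews_corrcoef(labels, calls), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([1, 0]), np.array([1]))


class TestRocAuc:
    def test_perfect_ordering(self):
        curve = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]),
                        np.array([1, 1, 0, 0]))
        assert curve.auc == pytest.approx(1.0)

    def test_all_equal_probabilities(self):
        curve = roc_auc(np.full(10, 0.5),
                        np.array([1, 0] * 5))
        assert curve.auc == pytest.approx(0.5)

    def test_matches_rank_sum_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            p = np.round(rng.uniform(size=n), 2)  # force ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            u = stats.mannwhitneyu(p[y == 1], p[y == 0],
                                   alternative="two-sided").statistic
            expected = u / ((y == 1).sum() * (y == 0).sum())
            assert roc_auc(p, y).auc == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        p = rng.uniform(size=40)
        y = rng.integers(0, 2, size=40)
        a1 = roc_auc(p, y).auc
        a2 = roc_auc(p ** 3, y).auc  # strictly monotone on [0,1]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_curve_endpoints(self, rng):
        p = rng.uniform(size=30)
        y = rng.integers(0, 2, size=30)
        curve = roc_auc(p, y)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_label_flip_complements_auc(self, rng):
        p = rng.normal(size=50)  # continuous: no ties
        y = rng.integers(0, 2, size=50)
        a = roc_auc(p, y).auc
        b = roc_auc(p, 1 - y).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestPairedTests:
    def test_identical_vectors_give_p_one(self):
        stat, p = paired_wilcoxon(np.arange(8.0), np.arange(8.0))
        assert p == 1.0

    def test_enumeration_oracle_n6(self):
        # exact two-sided signed-rank p by enumerating all 2^6 sign flips
        d = np.array([1.0, -2.0, 3.0, 4.0, -5.0, 6.0])
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        w_min = min(w_obs, total - w_obs)
        count = 0
        for signs in itertools.product([0, 1], repeat=6):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if min(w, total - w) <= w_min:
                count += 1
        expected = count / 2 ** 6
        _, p = paired_wilcoxon(d, np.zeros(6))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_uniform_improvement_is_significant(self, rng):
        # method a strictly better on every chain, n = 10
        b = rng.uniform(size=10)
        a = b + rng.uniform(0.05, 0.2, size=10)
        _, p = paired_wilcoxon(a, b)
        assert p < 0.01


class TestPerSequenceCompare:
    def _tracks(self, labels, probs, thr=0.5, method="m"):
        out = []
        for cid, y in labels.items():
            p = probs[cid]
            out.append(PredictionTrack(
                chain_id=cid, residues="A" * len(y), probabilities=p,
                calls=(p >= thr).astype(int), threshold=thr, method=method))
        return out

    def test_better_method_detected(self, rng):
        labels, pa, pb = {}, {}, {}
        for i in range(10):
            cid = f"c{i}"
            y = rng.integers(0, 2, size=40)
            labels[cid] = y
            pa[cid] = np.clip(y + rng.normal(scale=0.1, size=40), 0, 1)
            pb[cid] = rng.uniform(size=40)
        stats_ = per_sequence_compare(self._tracks(labels, pa),
                                      self._tracks(labels, pb), labels)
        assert stats_.comparisons["auc"].p_value < 0.01
        assert stats_.comparisons["auc"].n_pairs == 10

    def test_single_class_chains_dropped_pairwise(self, rng):
        labels = {"c0": np.zeros(20, dtype=int),
                  "c1": rng.integers(0, 2, size=20),
                  "c2": rng.integers(0, 2, size=20)}
        labels["c1"][0] = 1 - labels["c1"][0] if labels["c1"].min() == \
            labels["c1"].max() else labels["c1"][0]
        probs = {c: rng.uniform(size=20) for c in labels}
        stats_ = per_sequence_compare(self._tracks(labels, probs),
                                      self._tracks(labels, probs), labels)
        assert stats_.comparisons["auc"].n_dropped >= 1
        assert stats_.comparisons["auc"].skipped  # < 6 valid pairs

    def test_too_few_pairs_skips_test(self, rng):
        labels = {f"c{i}": rng.integers(0, 2, size=10) for i in range(3)}
        probs = {c: rng.uniform(size=10) for c in labels}
        stats_ = per_sequence_compare(self._tracks(labels, probs),
                                      self._tracks(labels, probs), labels)
        assert stats_.comparisons["mcc"].skipped


class TestConfidenceBins:
    def test_probability_one_in_closed_top_bin(self):
        bins = confidence_bins(np.array([1.0]), np.array([1]), np.array([1]))
        assert bins[-1]["count"] == 1

    def test_all_in_one_bin(self):
        p = np.full(10, 0.42)
        bins = confidence_bins(p, np.zeros(10, dtype=int),
                               np.zeros(10, dtype=int))
        assert bins[8]["fraction"] == pytest.approx(1.0)
        assert sum(b["count"] for b in bins) == 10

    def test_top_bin_accuracy_for_constructed_set(self):
        p = np.array([0.97, 0.98, 0.99, 0.1, 0.2])
        calls = (p >= 0.5).astype(int)
        labels = np.array([1, 1, 1, 1, 0])
        bins = confidence_bins(p, calls, labels)
        assert bins[19]["accuracy"] == pytest.approx(1.0)

    def test_twenty_bins_with_default_width(self):
        bins = confidence_bins(np.array([0.0]), np.array([0]), np.array([0]))
        assert len(bins) == 20


def test_roc_tsv_round_trip(tmp_path, rng):
    from atpsite.evaluation import write_roc_tsv

    p = rng.uniform(size=40)
    y = rng.integers(0, 2, size=40)
    curve = roc_auc(p, y)
    out = tmp_path / "roc.tsv"
    write_roc_tsv(curve, out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("# auc:")
    assert float(lines[0].split(":")[1]) == pytest.approx(curve.auc, abs=1e-6)
    assert len(lines) == 2 + len(curve.fpr)


def test_pooled_equals_recomputation_on_pooled_residues(rng):
    tracks, labels = [], {}
    all_calls, all_labels = [], []
    for i in range(5):
        cid = f"c{i}"
        y = rng.integers(0, 2, size=30)
        p = rng.uniform(size=30)
        calls = (p >= 0.5).astype(int)
        labels[cid] = y
        tracks.append(PredictionTrack(chain_id=cid, residues="A" * 30,
                                      probabilities=p, calls=calls,
                                      threshold=0.5, method="m"))
        all_calls.append(calls)
        all_labels.append(y)
    rep = pooled_and_averaged_metrics(tracks, labels)
    direct = confusion_metrics(np.concatenate(all_calls),
                               np.concatenate(all_labels))
    assert rep["pooled"]["mcc"] == pytest.approx(direct.mcc)
    assert rep["pooled"]["acc"] == pytest.approx(direct.accuracy)
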