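"""End-to-end orchestration: encode, select, train, predict, evaluate.

``fit_predictor`` wires the feature encoder and classifier together on
training chains; ``evaluate_on`` scores a fitted predictor on held-out
chains. ``run_pipeline`` drives the same steps from a fixture directory and
writes artifacts plus a manifest with the resolved configuration, seeds and
output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as aio
from .annotation import LabeledChain
from .baselines import conservation_baseline, consensus
from .evaluation import pooled_and_averaged_metrics
from .features import ResidueFeatureEncoder
from .io import PredictionTrack, ProfileBundle
from .model import AtpSiteClassifier
from .simulate import SimulatedChain, load_fixture

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    window_size: int = 17
    cutoff: float = 3.9
    max_identity: float = 0.40
    colloc_p_cut: float = 1e-6
    colloc_max_offset: int = 5
    k_folds: int = 5
    kernel: str = "auto"
    max_candidates: Optional[int] = None
    threshold: Optional[float] = None
    seed: int = 0


@dataclass
class FittedPredictor:
    encoder: ResidueFeatureEncoder
    classifier: AtpSiteClassifier
    config: RunConfig

    def predict_tracks(self,
                       bundles: Sequence[ProfileBundle]) -> list[PredictionTrack]:
        X = self.encoder.transform(bundles)
        sequences = {b.chain_id: b.sequence.sequence for b in bundles}
        return self.classifier.predict_tracks(X, sequences)


def fit_predictor(train: Sequence[SimulatedChain] |
                  Sequence[tuple[LabeledChain, ProfileBundle]],
                  config: RunConfig = RunConfig()) -> FittedPredictor:
    """Fit encoder + classifier on labeled training chains."""
    labeled, bundles = _unzip(train)
    encoder = ResidueFeatureEncoder(window_size=config.window_size,
                                    colloc_max_offset=config.colloc_max_offset,
                                    colloc_p_cut=config.colloc_p_cut)
    encoder.fit(bundles, [c.labels for c in labeled])
    X = encoder.transform(bundles)
    y = np.concatenate([c.labels for c in labeled])
    clf = AtpSiteClassifier(kernel=config.kernel, k_folds=config.k_folds,
                            max_candidates=config.max_candidates,
                            threshold=config.threshold, seed=config.seed)
    clf.fit(X, y)
    return FittedPredictor(encoder=encoder, classifier=clf, config=config)


def _unzip(chains) -> tuple[list[LabeledChain], list[ProfileBundle]]:
    labeled, bundles = [], []
    for c in chains:
        if isinstance(c, SimulatedChain):
            labeled.append(c.labeled)
            bundles.append(c.bundle)
        else:
            lc, b = c
            labeled.append(lc)
            bundles.append(b)
    return labeled, bundles


def evaluate_on(predictor: FittedPredictor, test) -> dict:
    """Score a fitted predictor on held-out labeled chains."""
    labeled, bundles = _unzip(test)
    tracks = predictor.predict_tracks(bundles)
    labels = {c.chain_id: c.labels for c in labeled}
    return pooled_and_averaged_metrics(tracks, labels)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(fixture_dir, outdir, config: RunConfig = RunConfig(),
                 test_fixture_dir=None) -> dict:
    """Run the full pipeline from a fixture directory.

    Fits on the chains in ``fixture_dir``; if ``test_fixture_dir`` is given,
    also predicts and evaluates its chains and runs the conservation baseline
    and consensus there. Writes prediction TSVs, an evaluation JSON and a
    manifest; returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    train = load_fixture(fixture_dir)

    predictor = fit_predictor(train, config)
    clf = predictor.classifier
    report: dict = {
        "cv_auc": clf.cv_auc_,
        "threshold": clf.threshold_,
        "kernel": clf.kernel_,
        "params": {k: (v if isinstance(v, str) else float(v))
                   for k, v in clf.params_.items()},
        "n_selected_features": len(clf.selected_features_),
        "selected_features": clf.selected_features_,
        "n_collocation_pairs": len(predictor.encoder.pairs_),
    }

    written: list[Path] = []
    if test_fixture_dir is not None:
        test = load_fixture(test_fixture_dir)
        labels = {c.labeled.chain_id: c.labeled.labels for c in test}
        tracks = predictor.predict_tracks([c.bundle for c in test])
        report["heldout"] = pooled_and_averaged_metrics(tracks, labels)

        # conservation threshold is calibrated on the training chains only
        cons_train = conservation_baseline(
            [c.bundle.conservation for c in train
             if c.bundle.conservation is not None],
            calibration_labels={c.labeled.chain_id: c.labeled.labels
                                for c in train})
        thr = cons_train[0].threshold if cons_train else None
        cons_tracks = conservation_baseline(
            [c.bundle.conservation for c in test
             if c.bundle.conservation is not None],
            threshold=thr if thr is not None else float("inf"),
            sequences={c.labeled.chain_id: c.bundle.sequence.sequence
                       for c in test})
        report["conservation_baseline"] = pooled_and_averaged_metrics(
            cons_tracks, labels)

        by_id = {t.chain_id: t for t in cons_tracks}
        cons_by_chain = [by_id[t.chain_id] for t in tracks]
        combo = [consensus(a, b) for a, b in zip(tracks, cons_by_chain)]
        report["consensus"] = pooled_and_averaged_metrics(combo, labels)

        pred_dir = outdir / "predictions"
        pred_dir.mkdir(exist_ok=True)
        for t in tracks:
            p = pred_dir / f"{t.chain_id}.tsv"
            aio.write_predictions(t, p)
            written.append(p)

    report_path = outdir / "evaluation.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    written.append(report_path)

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"report": report, "manifest": manifest}
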