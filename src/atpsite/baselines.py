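"""Reference predictors and the inclusive-disjunction consensus.

Three baselines bracket the SVM predictor: annotation transfer from the best
local alignment against an annotated database, thresholding of external
per-residue conservation scores, and (via the main model with selection
restricted to PSSM columns) a profile-only ablation. The consensus combines
tracks with OR on the binary calls and max on the probabilities.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .annotation import LabeledChain
from .io import ConservationTrack, PredictionTrack, SequenceRecord
from .model import mcc_max_threshold

logger = logging.getLogger(__name__)


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_transfer(query: SequenceRecord,
                       annotated_db: Sequence[LabeledChain],
                       score_floor: float = 0.0) -> PredictionTrack:
    """Transfer binding labels from the best-aligned annotated template.

    The query is locally aligned (Smith-Waterman, BLOSUM62, gap open 11 /
    extend 1) against every database chain except itself; the best-scoring
    chain is the template (first in database order on ties). Query residues
    aligned to binding template residues are called 1; gap columns transfer
    nothing. With no alignment scoring above ``score_floor`` an all-zero
    track is returned with a ``no_hit`` flag.
    """
    db = [c for c in annotated_db if c.chain_id != query.id]
    if not db:
        raise ValueError("annotated database is empty (after removing the "
                         "query itself)")
    aligner = _local_aligner()
    best = None
    for chain in db:
        score = aligner.score(query.sequence, chain.record.sequence)
        if best is None or score > best[0]:
            best = (score, chain)

    L = len(query.sequence)
    calls = np.zeros(L, dtype=int)
    flags = {}
    if best is None or best[0] <= score_floor:
        logger.warning("%s: no alignment above the score floor; all-zero "
                       "track", query.id)
        flags["no_hit"] = True
        template = None
    else:
        score, template = best
        alignment = aligner.align(query.sequence,
                                  template.record.sequence)[0]
        for (q0, q1), (t0, t1) in zip(*alignment.aligned):
            span = template.labels[t0:t1]
            calls[q0:q1] = np.maximum(calls[q0:q1], span)
        flags["template"] = template.chain_id
        flags["score"] = float(score)

    return PredictionTrack(
        chain_id=query.id, residues=query.sequence,
        probabilities=calls.astype(float), calls=calls,
        threshold=None, method="alignment_transfer", flags=flags)


def normalize_conservation(track: ConservationTrack) -> np.ndarray:
    """Orient scores so higher = more likely binding and min-max scale to [0,1].

    Conservation scorers in the rate4site convention emit low scores for
    conserved residues, and conserved residues are the binding candidates, so
    those tracks are negated before scaling. Constant tracks map to all 0.5.
    """
    s = np.asarray(track.scores, dtype=float)
    if track.low_is_conserved:
        s = -s
    span = s.max() - s.min()
    if span == 0:
        return np.full_like(s, 0.5)
    return (s - s.min()) / span


def conservation_baseline(tracks: Sequence[ConservationTrack],
                          calibration_labels: Optional[Dict[str, np.ndarray]]
                          = None,
                          sequences: Optional[Dict[str, str]] = None,
                          threshold: Optional[float] = None
                          ) -> list[PredictionTrack]:
    """Binarize external conservation scores at an MCC-maximizing threshold.

    Scores are oriented and normalized per chain to [0, 1]; the threshold is
    found by exhaustive scan on the chains present in ``calibration_labels``
    (pooled residues) unless given explicitly. Constant tracks with no
    usable threshold yield all-zero calls with a warning.
    """
    normalized = {t.chain_id: normalize_conservation(t) for t in tracks}
    if threshold is None:
        if not calibration_labels:
            raise ValueError("either a threshold or calibration labels are "
                             "required")
        probs, labels = [], []
        for t in tracks:
            if t.chain_id in calibration_labels:
                probs.append(normalized[t.chain_id])
                labels.append(np.asarray(calibration_labels[t.chain_id],
                                         dtype=int))
        pooled_p = np.concatenate(probs)
        pooled_y = np.concatenate(labels)
        if len(np.unique(pooled_y)) < 2 or np.ptp(pooled_p) == 0:
            logger.warning("conservation threshold undefined; all-zero calls")
            threshold = np.inf
        else:
            threshold = mcc_max_threshold(pooled_p, pooled_y)

    out = []
    for t in tracks:
        p = normalized[t.chain_id]
        residues = (sequences or {}).get(t.chain_id, "X" * len(p))
        out.append(PredictionTrack(
            chain_id=t.chain_id, residues=residues, probabilities=p,
            calls=(p >= threshold).astype(int),
            threshold=None if np.isinf(threshold) else float(threshold),
            method="conservation"))
    return out


def consensus(*tracks: PredictionTrack) -> PredictionTrack:
    """Inclusive-disjunction consensus of prediction tracks on one chain.

    The binary call is the OR of the component calls; the probability is the
    component maximum (binary-only components contribute their 0/1 calls).
    Commutative, associative and idempotent.
    """
    if len(tracks) < 2:
        raise ValueError("consensus needs at least two tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if t.chain_id != first.chain_id or len(t) != len(first):
            raise ValueError(
                f"chain mismatch: {t.chain_id}({len(t)}) vs "
                f"{first.chain_id}({len(first)})")
    calls = np.zeros(len(first), dtype=int)
    probs = np.zeros(len(first))
    for t in tracks:
        calls = np.maximum(calls, t.calls)
        probs = np.maximum(probs, t.probabilities)
    return PredictionTrack(
        chain_id=first.chain_id, residues=first.residues,
        probabilities=probs, calls=calls, threshold=None,
        method="consensus(" + "+".join(t.method or "?" for t in tracks) + ")")
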