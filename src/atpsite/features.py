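"""Per-residue feature encoding over a sliding sequence window.

Each residue is described by a fixed-order vector assembled from nine feature
groups computed over a window of 17 residues centered on it:

* ``pssm``   — 180 values: normalized PSSM log-odds 1/(1+2^-x), compressed by
  symmetric averaging g_z = (f_{i+z} + f_{i-z})/2 for z = 0..8 (9 x 20);
* ``ss``     — 51 values: predicted helix/strand/coil probabilities at each of
  the 17 window positions;
* ``rsa``    — 17 values: predicted relative solvent accessibility;
* ``dih``    — 34 values: predicted phi/psi dihedrals scaled to [-1, 1];
* ``aagrp``  — 36 values: four physicochemical group indicator tracks
  (hydrophobic, negatively charged, positively charged, carboxamide),
  compressed by the same symmetric averaging (9 x 4);
* ``term``   — 1 value: indicator of the first/last three sequence positions;
* ``seg``    — 6 values: helix/strand/coil segment indicators for the 8
  residues flanking each side of the window;
* ``consA/B/C`` — 17 values each: per-position conservation scores (Shannon
  entropy; relative entropy to background; Jensen-Shannon divergence to
  background) over the window;
* ``colloc`` — one binary column per collocated amino-acid pair that survives
  a Fisher-exact association screen on training data.

Window positions that fall outside the chain are padded with neutral values
(0.5 for normalized PSSM, coil for secondary structure, 0 for indicators, RSA
and scaled dihedrals, the no-conservation point for the conservation scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AA20, AA_INDEX, ProfileBundle

logger = logging.getLogger(__name__)

#: Physicochemical amino-acid groups (ordered).
AA_GROUPS = (
    ("hydrophobic", frozenset("ACILMV")),
    ("negative", frozenset("DE")),
    ("positive", frozenset("HKR")),
    ("amide", frozenset("NQ")),
)

#: Robinson-Robinson amino-acid background frequencies, canonical AA20 order.
BACKGROUND_FREQS = np.array([
    0.07805,  # A
    0.01925,  # C
    0.05364,  # D
    0.06295,  # E
    0.03856,  # F
    0.07377,  # G
    0.02199,  # H
    0.05142,  # I
    0.05744,  # K
    0.09019,  # L
    0.02243,  # M
    0.04487,  # N
    0.05203,  # P
    0.04264,  # Q
    0.05129,  # R
    0.07120,  # S
    0.05841,  # T
    0.06441,  # V
    0.01330,  # W
    0.03216,  # Y
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: an odd window of ``size`` residues.

    Offsets k run over -radius..radius; symmetric offsets z over 0..radius.
    """

    size: int = 17

    def __post_init__(self):
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 1")

    @property
    def radius(self) -> int:
        return (self.size - 1) // 2

    @property
    def offsets(self) -> range:
        return range(-self.radius, self.radius + 1)

    @property
    def sym_offsets(self) -> range:
        return range(0, self.radius + 1)


@dataclass(frozen=True)
class CollocationPair:
    """An ordered (center, partner) AA pair at a signed sequence offset."""

    center: str
    partner: str
    offset: int
    table: tuple[int, int, int, int] = (0, 0, 0, 0)  # (a, b, c, d)
    p_value: float = 1.0

    @property
    def name(self) -> str:
        return f"colloc.{self.center}{self.offset:+d}{self.partner}"


def normalize_pssm_value(x):
    """Normalize raw PSSM log-odds to (0, 1) with the logistic 1/(1+2^-x)."""
    return 1.0 / (1.0 + np.exp2(-np.asarray(x, dtype=float)))


def _shifted(track: np.ndarray, shift: int, pad) -> np.ndarray:
    """Return t[i + shift] for every i, padding out-of-chain positions.

    ``track`` may be (L,) or (L, d); ``pad`` a scalar or length-d vector.
    """
    track = np.asarray(track, dtype=float)
    out = np.empty_like(track)
    out[...] = pad
    L = track.shape[0]
    if shift >= 0:
        if L > shift:
            out[:L - shift] = track[shift:]
    elif L > -shift:
        out[-shift:] = track[:L + shift]
    return out


def _window_block(track: np.ndarray, spec: WindowSpec, pad) -> np.ndarray:
    """Stack raw window values: (L, size * d), k-major ordering."""
    cols = [_shifted(track, k, pad) for k in spec.offsets]
    cols = [c[:, None] if c.ndim == 1 else c for c in cols]
    return np.hstack(cols)


def _sym_avg_block(track: np.ndarray, spec: WindowSpec, pad) -> np.ndarray:
    """Symmetric averaging g_z = (f_{i+z} + f_{i-z}) / 2, z-major (L, 9*d)."""
    cols = []
    for z in spec.sym_offsets:
        g = 0.5 * (_shifted(track, z, pad) + _shifted(track, -z, pad))
        cols.append(g[:, None] if g.ndim == 1 else g)
    return np.hstack(cols)


# ---------------------------------------------------------------------------
# Per-group encoders (whole-chain, vectorized; single-residue views are rows)
# ---------------------------------------------------------------------------

def pssm_window_features(normalized: np.ndarray,
                         spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Symmetric-averaged normalized PSSM features, (L, 9*20) for size 17."""
    normalized = np.asarray(normalized, dtype=float)
    if normalized.ndim != 2 or normalized.shape[1] != 20:
        raise ValueError("normalized profile must be L x 20")
    return _sym_avg_block(normalized, spec, 0.5)


def ss3_window_features(ss3: np.ndarray,
                        spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Raw windowed secondary-structure probabilities, (L, 17*3)."""
    return _window_block(np.asarray(ss3, dtype=float), spec,
                         np.array([0.0, 0.0, 1.0]))


def rsa_window_features(rsa: np.ndarray,
                        spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Raw windowed RSA fractions, (L, 17)."""
    return _window_block(np.asarray(rsa, dtype=float), spec, 0.0)


def dihedral_window_features(phi: np.ndarray, psi: np.ndarray,
                             spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Windowed phi/psi dihedrals scaled by 1/180, (L, 17*2)."""
    angles = np.stack([np.asarray(phi, dtype=float) / 180.0,
                       np.asarray(psi, dtype=float) / 180.0], axis=1)
    return _window_block(angles, spec, 0.0)


def aagroup_indicator_tracks(sequence: str) -> np.ndarray:
    """(L, 4) binary membership of each residue in the four AA groups."""
    L = len(sequence)
    out = np.zeros((L, len(AA_GROUPS)))
    for j, (_, members) in enumerate(AA_GROUPS):
        out[:, j] = [1.0 if c in members else 0.0 for c in sequence]
    return out


def aagroup_window_features(sequence: str,
                            spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Symmetric-averaged AA-group indicators, (L, 9*4)."""
    return _sym_avg_block(aagroup_indicator_tracks(sequence), spec, 0.0)


def terminal_indicator(length: int, n_terminal: int = 3) -> np.ndarray:
    """(L,) indicator of the first and last ``n_terminal`` residues."""
    out = np.zeros(length)
    out[:n_terminal] = 1.0
    out[max(0, length - n_terminal):] = 1.0
    return out


def _max_run(states: np.ndarray, symbol: str) -> int:
    best = run = 0
    for s in states:
        run = run + 1 if s == symbol else 0
        best = max(best, run)
    return best


def segment_indicators(states: Sequence[str], spec: WindowSpec = WindowSpec(),
                       flank: int = 8, helix_run: int = 4,
                       strand_run: int = 3) -> np.ndarray:
    """Secondary-structure segment indicators for the window flanks, (L, 6).

    For each side, the ``flank`` residues immediately outside the window are
    inspected: the helix (strand) indicator is 1 if they contain a run of at
    least 4 (3) consecutive helix (strand) states; the coil indicator is 1
    when both are 0. Out-of-chain positions count as coil. Columns are
    (left H, left E, left C, right H, right E, right C).
    """
    states = np.asarray(list(states))
    L = len(states)
    r = spec.radius
    out = np.zeros((L, 6))
    padded = np.concatenate([np.full(r + flank, "C"), states,
                             np.full(r + flank, "C")])
    for i in range(L):
        c = i + r + flank  # index of residue i in padded
        left = padded[c - r - flank:c - r]
        right = padded[c + r + 1:c + r + 1 + flank]
        for side, seg in ((0, left), (3, right)):
            h = 1.0 if _max_run(seg, "H") >= helix_run else 0.0
            e = 1.0 if _max_run(seg, "E") >= strand_run else 0.0
            out[i, side:side + 3] = (h, e, 1.0 if h == 0.0 and e == 0.0 else 0.0)
    return out


def conservation_scores(frequencies: np.ndarray,
                        background: np.ndarray = BACKGROUND_FREQS,
                        tol: float = 1e-3) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray]:
    """Per-position conservation scores A, B, C from AA frequency vectors.

    A is the Shannon entropy -sum q log2 q; B the relative entropy (KL
    divergence, base 2) of q against the background; C the Jensen-Shannon
    divergence between q and the background. Frequency rows not summing to 1
    within ``tol`` are renormalized with a warning.
    """
    q = np.asarray(frequencies, dtype=float)
    if q.ndim == 1:
        q = q[None, :]
    sums = q.sum(axis=1)
    off = np.abs(sums - 1.0) > tol
    if off.any():
        logger.warning("%d frequency rows do not sum to 1; renormalizing",
                       int(off.sum()))
    q = q / sums[:, None]
    b = np.asarray(background, dtype=float)
    b = b / b.sum()

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(q > 0, q * np.log2(q), 0.0)
        A = -plogp.sum(axis=1)
        B = np.where(q > 0, q * np.log2(q / b), 0.0).sum(axis=1)
        m = 0.5 * (q + b)
        kl_qm = np.where(q > 0, q * np.log2(q / m), 0.0).sum(axis=1)
        kl_bm = (b * np.log2(b / m)).sum(axis=1)
        C = 0.5 * kl_qm + 0.5 * kl_bm
    return A, B, C


#: Neutral window-padding values for the conservation tracks: entropy of the
#: uniform distribution (= no conservation) for A, the background point (0
#: divergence) for B and C.
CONS_PADS = (float(np.log2(20.0)), 0.0, 0.0)


# ---------------------------------------------------------------------------
# Collocated AA pairs
# ---------------------------------------------------------------------------

def collocation_offsets(max_offset: int = 5) -> list[int]:
    return [d for d in range(-max_offset, max_offset + 1) if d != 0]


def screen_collocations(sequences: Sequence[str],
                        labels: Sequence[np.ndarray],
                        max_offset: int = 5,
                        p_cut: float = 1e-6) -> list[CollocationPair]:
    """Screen all (center AA, partner AA, offset) pairs for label association.

    Enumerates the 20 x 20 x 2*max_offset candidate combinations (4000 for the
    default offset range of 5 on each side). For each, a 2x2 contingency table
    of pair presence against the residue's binding label is built over all
    training residues and tested with a two-sided Fisher exact test; pairs
    with p < ``p_cut`` survive, ordered by (p, center, partner, offset).

    Must be fed training chains only.
    """
    if len(sequences) == 0:
        raise ValueError("empty training set")
    offsets = collocation_offsets(max_offset)
    # presence counts per (offset, center, partner) split by label
    pos_counts = {d: np.zeros((20, 20), dtype=np.int64) for d in offsets}
    neg_counts = {d: np.zeros((20, 20), dtype=np.int64) for d in offsets}
    n_pos = 0
    n_tot = 0
    for seq, lab in zip(sequences, labels):
        lab = np.asarray(lab, dtype=int)
        if len(seq) != len(lab):
            raise ValueError("sequence/label length mismatch")
        codes = np.array([AA_INDEX.get(c, -1) for c in seq])
        n_tot += len(seq)
        n_pos += int(lab.sum())
        for d in offsets:
            if d > 0:
                ci = np.arange(0, len(seq) - d)
            else:
                ci = np.arange(-d, len(seq))
            pi = ci + d
            ok = (codes[ci] >= 0) & (codes[pi] >= 0)
            ci, pi = ci[ok], pi[ok]
            for counts, mask in ((pos_counts, lab[ci] == 1),
                                 (neg_counts, lab[ci] == 0)):
                np.add.at(counts[d], (codes[ci[mask]], codes[pi[mask]]), 1)

    survivors: list[CollocationPair] = []
    for d in offsets:
        for ic in range(20):
            for ip in range(20):
                a = int(pos_counts[d][ic, ip])   # pair present, binding
                b = int(neg_counts[d][ic, ip])   # pair present, non-binding
                c = n_pos - a                    # pair absent, binding
                dd = (n_tot - n_pos) - b         # pair absent, non-binding
                if a + b == 0:
                    continue
                _, p = stats.fisher_exact([[a, b], [c, dd]],
                                          alternative="two-sided")
                if p < p_cut:
                    survivors.append(CollocationPair(
                        center=AA20[ic], partner=AA20[ip], offset=d,
                        table=(a, b, c, dd), p_value=float(p)))
    survivors.sort(key=lambda cp: (cp.p_value, cp.center, cp.partner,
                                   cp.offset))
    return survivors


def collocation_features(sequence: str,
                         pairs: Sequence[CollocationPair]) -> np.ndarray:
    """(L, n_pairs) binary presence of each screened pair at each residue."""
    L = len(sequence)
    out = np.zeros((L, len(pairs)))
    for j, pair in enumerate(pairs):
        for i in range(L):
            k = i + pair.offset
            if 0 <= k < L and sequence[i] == pair.center \
                    and sequence[k] == pair.partner:
                out[i, j] = 1.0
    return out


class CollocationScreen(BaseEstimator):
    """Estimator wrapper around the Fisher-exact collocation screen.

    Fit on training sequences and labels; exposes the surviving pairs as
    ``pairs_`` and transforms sequences into binary pair-presence columns.
    """

    def __init__(self, max_offset: int = 5, p_cut: float = 1e-6):
        self.max_offset = max_offset
        self.p_cut = p_cut

    def fit(self, sequences: Sequence[str], labels: Sequence[np.ndarray]):
        self.pairs_ = screen_collocations(sequences, labels,
                                          max_offset=self.max_offset,
                                          p_cut=self.p_cut)
        return self

    def transform(self, sequences: Sequence[str]) -> np.ndarray:
        return np.vstack([collocation_features(s, self.pairs_)
                          for s in sequences])


# ---------------------------------------------------------------------------
# Whole-chain assembly
# ---------------------------------------------------------------------------

def feature_column_names(spec: WindowSpec,
                         pairs: Sequence[CollocationPair]) -> list[str]:
    names: list[str] = []
    for z in spec.sym_offsets:
        names += [f"pssm.z{z}.{a}" for a in AA20]
    for k in spec.offsets:
        names += [f"ss.k{k:+d}.{s}" for s in "HEC"]
    names += [f"rsa.k{k:+d}" for k in spec.offsets]
    for k in spec.offsets:
        names += [f"dih.k{k:+d}.{ang}" for ang in ("phi", "psi")]
    for z in spec.sym_offsets:
        names += [f"aagrp.z{z}.{g}" for g, _ in AA_GROUPS]
    names.append("term")
    names += [f"seg.{side}.{s}" for side in ("left", "right") for s in "HEC"]
    for tag in ("consA", "consB", "consC"):
        names += [f"{tag}.k{k:+d}" for k in spec.offsets]
    names += [p.name for p in pairs]
    return names


def encode_chain(bundle: ProfileBundle,
                 pairs: Sequence[CollocationPair] = (),
                 spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Encode every residue of one chain as a feature row.

    Returns a DataFrame indexed by (chain_id, 0-based position) whose column
    order and per-group counts are fixed: 180 pssm + 51 ss + 17 rsa + 34 dih
    + 36 aagrp + 1 term + 6 seg + 3 x 17 conservation + one column per
    screened collocation pair (for the default window of 17).
    """
    seq = bundle.sequence.sequence
    tracks = bundle.tracks
    if tracks is None:
        raise ValueError(f"{bundle.chain_id}: missing structure tracks")
    if bundle.pssm is None:
        raise ValueError(f"{bundle.chain_id}: missing PSSM profile")

    f_norm = normalize_pssm_value(bundle.pssm.logodds)
    blocks = [pssm_window_features(f_norm, spec),
              ss3_window_features(tracks.ss3, spec),
              rsa_window_features(tracks.rsa, spec),
              dihedral_window_features(tracks.phi, tracks.psi, spec),
              aagroup_window_features(seq, spec),
              terminal_indicator(len(seq))[:, None]]
    states = np.array(list("HEC"))[np.argmax(tracks.ss3, axis=1)]
    blocks.append(segment_indicators(states, spec))
    A, B, C = conservation_scores(bundle.pssm.frequencies)
    for track, pad in zip((A, B, C), CONS_PADS):
        blocks.append(_window_block(track, spec, pad))
    blocks.append(collocation_features(seq, pairs))

    X = np.hstack(blocks)
    index = pd.MultiIndex.from_arrays(
        [[bundle.chain_id] * len(seq), np.arange(len(seq))],
        names=["chain", "position"])
    return pd.DataFrame(X, index=index,
                        columns=feature_column_names(spec, pairs))


def encode_dataset(bundles: Iterable[ProfileBundle],
                   pairs: Sequence[CollocationPair] = (),
                   spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Concatenate :func:`encode_chain` over many chains."""
    frames = [encode_chain(b, pairs, spec) for b in bundles]
    if not frames:
        raise ValueError("no chains to encode")
    return pd.concat(frames, axis=0)


class ResidueFeatureEncoder(BaseEstimator, TransformerMixin):
    """Transform ProfileBundles into the full per-residue feature matrix.

    ``fit`` screens collocated AA pairs on the supplied (training) chains;
    ``transform`` encodes any chains into a DataFrame with the fitted column
    set. With ``use_collocations=False`` the encoder is stateless apart from
    recording the column names.

    Parameters
    ----------
    window_size : odd int, default 17
    colloc_max_offset : int, default 5
    colloc_p_cut : float, default 1e-6
    use_collocations : bool, default True
    """

    def __init__(self, window_size: int = 17, colloc_max_offset: int = 5,
                 colloc_p_cut: float = 1e-6, use_collocations: bool = True):
        self.window_size = window_size
        self.colloc_max_offset = colloc_max_offset
        self.colloc_p_cut = colloc_p_cut
        self.use_collocations = use_collocations

    def _spec(self) -> WindowSpec:
        return WindowSpec(self.window_size)

    def fit(self, bundles: Sequence[ProfileBundle],
            labels: Optional[Sequence[np.ndarray]] = None):
        if self.use_collocations:
            if labels is None:
                raise ValueError("labels are required to screen collocations")
            self.pairs_ = screen_collocations(
                [b.sequence.sequence for b in bundles], labels,
                max_offset=self.colloc_max_offset, p_cut=self.colloc_p_cut)
        else:
            self.pairs_ = []
        self.feature_names_ = feature_column_names(self._spec(), self.pairs_)
        return self

    def transform(self, bundles: Sequence[ProfileBundle]) -> pd.DataFrame:
        if not hasattr(self, "pairs_"):
            raise ValueError("encoder is not fitted")
        return encode_dataset(bundles, self.pairs_, self._spec())

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
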