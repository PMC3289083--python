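"""Readers and writers for the external file formats the toolkit consumes.

All per-residue inputs (PSI-BLAST ASCII PSSM, PSIPRED ss2, columnar RSA/dihedral
and conservation files) are validated against the chain sequence: row counts must
equal the sequence length and row letters must match the sequence. Coordinates in
files are 1-based; everything in memory is 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical in-memory amino-acid column order (alphabetical one-letter codes).
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}

#: Column order used by PSI-BLAST ASCII matrices.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

ALPHABET = set(AA20) | {"X"}


class ParseError(ValueError):
    """A structured error raised when an input file fails validation."""

    def __init__(self, message: str, path: Optional[str] = None,
                 where: Optional[str] = None):
        self.path = str(path) if path is not None else None
        self.where = where
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if where is not None:
            prefix += f"{where}: "
        super().__init__(prefix + message)


@dataclass
class SequenceRecord:
    """A protein chain: identifier plus sequence over the 20 AAs and X."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ParseError("empty sequence", where=self.id)
        bad = sorted(set(self.sequence) - ALPHABET)
        if bad:
            raise ParseError(f"illegal characters {bad} in sequence",
                             where=self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMProfile:
    """Per-residue evolutionary profile from a PSI-BLAST ASCII matrix.

    ``logodds`` holds the raw log-odds scores x (L x 20, canonical :data:`AA20`
    column order); ``frequencies`` the weighted observed frequency block as
    fractions summing to ~1 per row.
    """

    chain_id: str
    logodds: np.ndarray
    frequencies: np.ndarray
    letters: str

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        L = len(self.letters)
        if self.logodds.shape != (L, 20) or self.frequencies.shape != (L, 20):
            raise ParseError("PSSM blocks must be L x 20 matching the sequence",
                             where=self.chain_id)

    def __len__(self) -> int:
        return len(self.letters)


@dataclass
class StructTracks:
    """Predicted secondary structure, solvent accessibility and dihedrals.

    ``ss3`` is L x 3 with columns (helix, strand, coil) probabilities; ``rsa``
    is the relative solvent accessibility fraction in [0, 1]; ``phi``/``psi``
    are backbone dihedrals in degrees in [-180, 180].
    """

    chain_id: str
    ss3: np.ndarray
    rsa: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.ss3 = np.asarray(self.ss3, dtype=float)
        self.rsa = np.asarray(self.rsa, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        L = self.ss3.shape[0]
        if self.ss3.shape != (L, 3):
            raise ParseError("ss3 must be L x 3", where=self.chain_id)
        for name, track in (("rsa", self.rsa), ("phi", self.phi),
                            ("psi", self.psi)):
            if track.shape != (L,):
                raise ParseError(f"{name} length {track.shape} != {L}",
                                 where=self.chain_id)
        if np.any(self.ss3 < 0) or np.any(self.ss3 > 1):
            raise ParseError("ss3 probabilities outside [0,1]",
                             where=self.chain_id)

    def __len__(self) -> int:
        return self.ss3.shape[0]


@dataclass
class ConservationTrack:
    """Per-residue conservation scores from an external scorer.

    ``low_is_conserved`` records the orientation (rate4site-style scores are
    low for conserved residues) so downstream consumers can invert once.
    """

    chain_id: str
    scores: np.ndarray
    low_is_conserved: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class ProfileBundle:
    """All per-residue input tracks for one chain."""

    sequence: SequenceRecord
    pssm: PSSMProfile
    tracks: StructTracks
    conservation: Optional[ConservationTrack] = None

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name, obj in (("pssm", self.pssm), ("tracks", self.tracks),
                          ("conservation", self.conservation)):
            if obj is not None and len(obj) != L:
                raise ParseError(
                    f"{name} length {len(obj)} != sequence length {L}",
                    where=self.sequence.id)

    @property
    def chain_id(self) -> str:
        return self.sequence.id


@dataclass
class PredictionTrack:
    """Per-residue probabilities and binarized calls for one chain.

    Calls follow the >= convention: ``call = probability >= threshold``.
    Purely binary predictors (alignment transfer) carry their calls as the
    probabilities.
    """

    chain_id: str
    residues: str
    probabilities: np.ndarray
    calls: np.ndarray
    threshold: Optional[float] = None
    method: str = ""
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.calls = np.asarray(self.calls, dtype=int)
        L = len(self.residues)
        if self.probabilities.shape != (L,) or self.calls.shape != (L,):
            raise ValueError(f"track lengths differ from chain length {L}")
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be binary")

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; letters outside the 20 standard amino acids are
    mapped to ``X`` with a warning. Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r}", path=path,
                             where=f"record {i + 1}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        nonstd = sorted(set(seq) - ALPHABET)
        if nonstd:
            logger.warning("%s: record %s: mapping non-standard letters %s to X",
                           path, rec.id, nonstd)
            seq = "".join(c if c in ALPHABET else "X" for c in seq)
        if not seq:
            raise ParseError("empty sequence", path=path, where=rec.id)
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ParseError("no FASTA records found", path=path)
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def _check_letter(file_letter: str, seq_letter: str, pos0: int, path, what: str):
    if seq_letter == "X" or file_letter == "X":
        return
    if file_letter != seq_letter:
        raise ParseError(
            f"residue letter {file_letter!r} does not match sequence letter "
            f"{seq_letter!r}", path=path, where=f"{what} position {pos0 + 1}")


def read_pssm(path, sequence: str) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII position-specific scoring matrix.

    Both the 40-column dialect (log-odds + weighted observed percentages) and
    the 20-column log-odds-only dialect are accepted. When the frequency block
    is absent, per-position frequencies are derived from the log-odds via the
    logistic transform 1/(1+2^-x) and renormalization (logged as degraded
    mode). Columns are reordered to the canonical alphabetical order.
    """
    path = Path(path)
    sequence = sequence.upper()
    lines = path.read_text().splitlines()

    header_order: Optional[str] = None
    rows: list[tuple[int, str, list[float], Optional[list[float]]]] = []
    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if not toks:
            continue
        if header_order is None and all(t in ALPHABET and len(t) == 1
                                        for t in toks) and len(toks) in (20, 40):
            header_order = "".join(toks[:20])
            continue
        if header_order is None:
            continue  # preamble text
        if not toks[0].lstrip("-").isdigit():
            continue  # trailing footer (K/lambda lines etc.)
        pos = int(toks[0])
        letter = toks[1].upper()
        if len(toks) < 22:
            raise ParseError("malformed PSSM row (fewer than 20 score columns)",
                             path=path, where=f"row {pos} (line {lineno})")
        try:
            scores = [float(t) for t in toks[2:22]]
        except ValueError as exc:
            raise ParseError(f"non-numeric score: {exc}", path=path,
                             where=f"row {pos} (line {lineno})") from None
        freqs = None
        if len(toks) >= 42:
            freqs = [float(t) / 100.0 for t in toks[22:42]]
        rows.append((pos, letter, scores, freqs))

    if header_order is None or not rows:
        raise ParseError("no PSSM matrix found", path=path)
    if len(rows) != len(sequence):
        raise ParseError(
            f"PSSM has {len(rows)} rows but sequence has {len(sequence)} "
            "residues", path=path)

    perm = [header_order.index(a) for a in AA20]
    L = len(rows)
    logodds = np.empty((L, 20))
    freqmat = np.full((L, 20), np.nan)
    letters = []
    have_freqs = True
    for i, (pos, letter, scores, freqs) in enumerate(rows):
        _check_letter(letter, sequence[i], i, path, "PSSM")
        letters.append(sequence[i])
        logodds[i] = np.asarray(scores)[perm]
        if freqs is None:
            have_freqs = False
        else:
            freqmat[i] = np.asarray(freqs)[perm]

    if not have_freqs:
        logger.warning("%s: no frequency block; deriving frequencies from "
                       "log-odds (degraded mode)", path)
        freqmat = 1.0 / (1.0 + np.exp2(-logodds))
        freqmat /= freqmat.sum(axis=1, keepdims=True)
    else:
        sums = freqmat.sum(axis=1)
        # rows of all-zero frequencies occur in real files at X positions
        zero = sums <= 0
        if zero.any():
            freqmat[zero] = 1.0 / 20.0
            sums = freqmat.sum(axis=1)
        freqmat /= sums[:, None]

    return PSSMProfile(chain_id=path.stem, logodds=logodds,
                       frequencies=freqmat, letters="".join(letters))


def write_pssm(path, sequence: str, logodds: np.ndarray,
               frequencies: Optional[np.ndarray] = None) -> None:
    """Write a PSI-BLAST-style ASCII matrix (40-column dialect).

    Log-odds are written as integers and frequencies as integer percentages,
    as produced by PSI-BLAST itself.
    """
    logodds = np.asarray(logodds)
    if frequencies is None:
        frequencies = 1.0 / (1.0 + np.exp2(-logodds))
        frequencies = frequencies / frequencies.sum(axis=1, keepdims=True)
    perm = [AA20.index(a) for a in PSIBLAST_ORDER]
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down, information per position, "
                 "and relative weight of gapless real matches to pseudocounts\n")
        head = "    " + "  ".join(PSIBLAST_ORDER) + "   " + \
               "  ".join(PSIBLAST_ORDER)
        fh.write("           " + head.strip() + "\n")
        for i, letter in enumerate(sequence):
            lo = " ".join(f"{int(round(v)):3d}" for v in logodds[i][perm])
            fr = " ".join(f"{int(round(v * 100)):3d}"
                          for v in frequencies[i][perm])
            fh.write(f"{i + 1:5d} {letter} {lo}  {fr}  0.00 0.00\n")


# ---------------------------------------------------------------------------
# PSIPRED ss2 and columnar tracks
# ---------------------------------------------------------------------------

def read_ss2(path, sequence: str) -> np.ndarray:
    """Read a PSIPRED vertical-format (.ss2) file.

    Returns an L x 3 array of (helix, strand, coil) probabilities. The file
    stores columns in (coil, helix, strand) order.
    """
    path = Path(path)
    sequence = sequence.upper()
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        toks = line.split()
        if not toks or toks[0].startswith("#"):
            continue
        if not toks[0].isdigit():
            continue
        if len(toks) < 6:
            raise ParseError("malformed ss2 row", path=path,
                             where=f"line {lineno}")
        pos, letter = int(toks[0]), toks[1].upper()
        c, h, e = (float(t) for t in toks[3:6])
        rows.append((pos, letter, h, e, c))
    if len(rows) != len(sequence):
        raise ParseError(f"ss2 has {len(rows)} rows but sequence has "
                         f"{len(sequence)} residues", path=path)
    ss3 = np.empty((len(rows), 3))
    for i, (pos, letter, h, e, c) in enumerate(rows):
        _check_letter(letter, sequence[i], i, path, "ss2")
        ss3[i] = (h, e, c)
    if np.any(ss3 < 0) or np.any(ss3 > 1):
        raise ParseError("ss2 probabilities outside [0,1]", path=path)
    return ss3


def write_ss2(path, sequence: str, ss3: np.ndarray) -> None:
    """Write (helix, strand, coil) probabilities in PSIPRED vertical format."""
    ss3 = np.asarray(ss3)
    states = np.array(list("HEC"))[np.argmax(ss3, axis=1)]
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (synthetic)\n\n")
        for i, letter in enumerate(sequence):
            h, e, c = ss3[i]
            fh.write(f"{i + 1:4d} {letter} {states[i]}  "
                     f"{c:6.3f} {h:6.3f} {e:6.3f}\n")


def read_rsa_dihedrals(path, sequence: str) -> tuple[np.ndarray, np.ndarray,
                                                     np.ndarray]:
    """Read a columnar file of position, letter, RSA, phi, psi.

    RSA values outside [0, 1] are clamped with a warning; dihedrals outside
    [-180, 180] are an error.
    """
    path = Path(path)
    sequence = sequence.upper()
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        toks = line.split()
        if not toks or toks[0].startswith("#"):
            continue
        if len(toks) < 5:
            raise ParseError("expected 5 columns (pos letter rsa phi psi)",
                             path=path, where=f"line {lineno}")
        rows.append((int(toks[0]), toks[1].upper(), float(toks[2]),
                     float(toks[3]), float(toks[4])))
    if len(rows) != len(sequence):
        raise ParseError(f"{len(rows)} rows but sequence has {len(sequence)} "
                         "residues", path=path)
    rsa = np.empty(len(rows))
    phi = np.empty(len(rows))
    psi = np.empty(len(rows))
    for i, (pos, letter, r, f_, p) in enumerate(rows):
        _check_letter(letter, sequence[i], i, path, "rsa/dihedral")
        if r < 0.0 or r > 1.0:
            logger.warning("%s: RSA %.3f at position %d clamped to [0,1]",
                           path, r, i + 1)
            r = min(max(r, 0.0), 1.0)
        if not (-180.0 <= f_ <= 180.0) or not (-180.0 <= p <= 180.0):
            raise ParseError(f"dihedral outside [-180,180] at position {i + 1}",
                             path=path)
        rsa[i], phi[i], psi[i] = r, f_, p
    return rsa, phi, psi


def write_rsa_dihedrals(path, sequence: str, rsa, phi, psi) -> None:
    with open(path, "w") as fh:
        fh.write("# pos res rsa phi psi\n")
        for i, letter in enumerate(sequence):
            fh.write(f"{i + 1:4d} {letter} {rsa[i]:7.4f} "
                     f"{phi[i]:9.3f} {psi[i]:9.3f}\n")


def read_struct_tracks(ss2_path, rsa_path, sequence: str,
                       chain_id: str = "") -> StructTracks:
    """Combine a PSIPRED ss2 file and an RSA/dihedral file into StructTracks."""
    ss3 = read_ss2(ss2_path, sequence)
    rsa, phi, psi = read_rsa_dihedrals(rsa_path, sequence)
    return StructTracks(chain_id=chain_id or Path(ss2_path).stem, ss3=ss3,
                        rsa=rsa, phi=phi, psi=psi)


def read_conservation(path, sequence: str,
                      low_is_conserved: bool = True) -> ConservationTrack:
    """Read a columnar conservation-score file (pos, letter, score).

    A ``# low_is_conserved: true/false`` header directive overrides the
    argument; rate4site-style scorers emit low scores for conserved residues.
    """
    path = Path(path)
    sequence = sequence.upper()
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        toks = line.split()
        if not toks:
            continue
        if toks[0].startswith("#"):
            joined = " ".join(toks).lower()
            if "low_is_conserved" in joined:
                low_is_conserved = "true" in joined or "1" in joined.split(":")[-1]
            continue
        if len(toks) < 3:
            raise ParseError("expected 3 columns (pos letter score)",
                             path=path, where=f"line {lineno}")
        rows.append((int(toks[0]), toks[1].upper(), float(toks[2])))
    if len(rows) != len(sequence):
        raise ParseError(f"{len(rows)} rows but sequence has {len(sequence)} "
                         "residues", path=path)
    scores = np.empty(len(rows))
    for i, (pos, letter, s) in enumerate(rows):
        _check_letter(letter, sequence[i], i, path, "conservation")
        scores[i] = s
    return ConservationTrack(chain_id=path.stem, scores=scores,
                             low_is_conserved=low_is_conserved)


def write_conservation(path, sequence: str, scores,
                       low_is_conserved: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# low_is_conserved: {str(low_is_conserved).lower()}\n")
        for i, letter in enumerate(sequence):
            fh.write(f"{i + 1:4d} {letter} {scores[i]:10.5f}\n")


# ---------------------------------------------------------------------------
# Prediction tracks
# ---------------------------------------------------------------------------

def write_predictions(track: PredictionTrack, path) -> None:
    """Write a prediction track as TSV: position, residue, probability, call."""
    with open(path, "w") as fh:
        thr = "NA" if track.threshold is None else f"{track.threshold:.6f}"
        fh.write(f"# chain: {track.chain_id}\n")
        fh.write(f"# method: {track.method}\n")
        fh.write(f"# threshold: {thr}\n")
        fh.write("position\tresidue\tprobability\tcall\n")
        for i, letter in enumerate(track.residues):
            fh.write(f"{i + 1}\t{letter}\t{track.probabilities[i]:.6f}\t"
                     f"{track.calls[i]}\n")


def read_predictions(path) -> PredictionTrack:
    path = Path(path)
    chain_id, method, threshold = path.stem, "", None
    letters: list[str] = []
    probs: list[float] = []
    calls: list[int] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            key, val = key.strip(), val.strip()
            if key == "chain":
                chain_id = val
            elif key == "method":
                method = val
            elif key == "threshold":
                threshold = None if val == "NA" else float(val)
            continue
        toks = line.split("\t")
        if not toks or toks[0] == "position" or not toks[0].strip():
            continue
        if len(toks) < 4:
            raise ParseError("expected 4 tab-separated columns", path=path,
                             where=f"line {lineno}")
        letters.append(toks[1])
        probs.append(float(toks[2]))
        calls.append(int(toks[3]))
    if not letters:
        raise ParseError("no prediction rows", path=path)
    return PredictionTrack(chain_id=chain_id, residues="".join(letters),
                           probabilities=np.asarray(probs),
                           calls=np.asarray(calls), threshold=threshold,
                           method=method)
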