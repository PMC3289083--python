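"""Synthetic fixtures with planted signal for every stage of the pipeline.

The generator emulates the statistical structure of the real inputs: chains of
a few hundred residues in which ~4% of positions bind the ligand, clustered
into contiguous segments; PSSM log-odds whose designated columns are shifted
upward at binding positions (evolutionary conservation of the site, the
strongest real signal source); a collocated center/partner sequence motif
enriched at binding sites; uninformative predicted secondary-structure, RSA
and dihedral tracks; a conservation-score track (profile entropy plus noise,
explicitly lowered at binding positions, low = conserved) so the
conservation baseline has a realistic signal to find; and toy PDB complexes
that place a ligand within or beyond the annotation distance of chosen
residues.

With ``pssm_delta = 0``, ``motif = None`` and ``conservation_delta = 0`` the
generator is an exact null: no input carries label information.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as aio
from .annotation import LabeledChain
from .features import BACKGROUND_FREQS, conservation_scores
from .io import (ConservationTrack, PSSMProfile, ProfileBundle,
                 SequenceRecord, StructTracks, AA20)

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Generator settings; the defaults are the reference study conditions.

    ``positive_fraction`` targets the ~4% binding-residue rate of real
    ligand-bound chains; binding positions form contiguous segments of
    ``segment_len_range`` residues. ``pssm_delta`` is the effect size: the
    shift added to the log-odds of ``signal_columns`` at binding positions.
    ``motif`` plants a (center, partner, offset) collocated pair at binding
    residues with probability ``motif_prob`` (and at non-binding residues
    with ``motif_background``). ``conservation_delta`` lowers the emulated
    external conservation score at binding positions (low = conserved).
    """

    n_chains: int = 60
    length_mean: int = 300
    length_sd: int = 30
    min_length: int = 80
    positive_fraction: float = 0.04
    segment_len_range: tuple[int, int] = (4, 11)
    pssm_delta: float = 2.0
    signal_columns: tuple[str, ...] = ("G", "K", "T")
    pssm_noise_sd: float = 2.0
    motif: Optional[tuple[str, str, int]] = ("G", "K", 3)
    motif_prob: float = 0.5
    motif_background: float = 0.01
    conservation_delta: float = 0.4
    conservation_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.segment_len_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid segment length range")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must be in (0, 1)")


def _plant_segments(L: int, n_pos: int, seg_range: tuple[int, int],
                    rng: np.random.Generator) -> np.ndarray:
    """Binary labels with ``n_pos`` positives in contiguous segments."""
    lo, hi = seg_range
    if n_pos > L:
        raise ValueError("more positives requested than chain length")
    lengths: list[int] = []
    remaining = n_pos
    while remaining > 0:
        ln = int(rng.integers(lo, hi + 1))
        ln = min(ln, remaining)
        lengths.append(ln)
        remaining -= ln
    labels = np.zeros(L, dtype=int)
    # place segments left to right with random gaps; require >= 1 residue gap
    total = sum(lengths)
    slack = L - total - (len(lengths) - 1)
    if slack < 0:
        raise ValueError("segments do not fit in the chain")
    cuts = np.sort(rng.integers(0, slack + 1, size=len(lengths)))
    pos = 0
    prev_cut = 0
    for ln, cut in zip(lengths, cuts):
        pos += cut - prev_cut
        prev_cut = cut
        labels[pos:pos + ln] = 1
        pos += ln + 1
    return labels


def _random_sequence(L: int, rng: np.random.Generator) -> list[str]:
    codes = rng.choice(20, size=L, p=BACKGROUND_FREQS)
    return [AA20[c] for c in codes]


@dataclass
class SimulatedChain:
    labeled: LabeledChain
    bundle: ProfileBundle


def simulate_chain(config: SimConfig, chain_id: str,
                   rng: np.random.Generator) -> SimulatedChain:
    L = max(config.min_length,
            int(round(rng.normal(config.length_mean, config.length_sd))))
    n_pos = max(1, int(round(config.positive_fraction * L)))
    labels = _plant_segments(L, n_pos, config.segment_len_range, rng)

    seq = _random_sequence(L, rng)
    if config.motif is not None:
        center, partner, offset = config.motif
        for i in range(L):
            prob = config.motif_prob if labels[i] else config.motif_background
            if 0 <= i + offset < L and rng.random() < prob:
                seq[i] = center
                seq[i + offset] = partner
    sequence = "".join(seq)

    logodds = np.round(rng.normal(0.0, config.pssm_noise_sd, size=(L, 20)))
    if config.pssm_delta:
        cols = [AA20.index(a) for a in config.signal_columns]
        for c in cols:
            logodds[labels == 1, c] += config.pssm_delta
    logodds = np.clip(logodds, -12, 12)
    freqs = 1.0 / (1.0 + np.exp2(-logodds))
    freqs = freqs / freqs.sum(axis=1, keepdims=True)

    ss3 = rng.dirichlet(alpha=(1.0, 1.0, 1.5), size=L)
    rsa = rng.uniform(0.0, 1.0, size=L)
    phi = rng.uniform(-180.0, 180.0, size=L)
    psi = rng.uniform(-180.0, 180.0, size=L)

    # conservation track: profile entropy plus noise, lowered by an explicit
    # effect at binding positions (low = conserved, as a real scorer reports)
    A, _, _ = conservation_scores(freqs)
    cons = (A - config.conservation_delta * labels
            + rng.normal(0.0, config.conservation_noise_sd, size=L))

    record = SequenceRecord(chain_id, sequence)
    bundle = ProfileBundle(
        sequence=record,
        pssm=PSSMProfile(chain_id=chain_id, logodds=logodds,
                         frequencies=freqs, letters=sequence),
        tracks=StructTracks(chain_id=chain_id, ss3=ss3, rsa=rsa,
                            phi=phi, psi=psi),
        conservation=ConservationTrack(chain_id=chain_id, scores=cons,
                                       low_is_conserved=True))
    return SimulatedChain(
        labeled=LabeledChain(record=record, labels=labels, source="synthetic"),
        bundle=bundle)


def simulate_dataset(config: SimConfig) -> list[SimulatedChain]:
    """Generate ``config.n_chains`` chains with planted signal (seeded)."""
    rng = np.random.default_rng(config.seed)
    return [simulate_chain(config, f"syn{i:03d}", rng)
            for i in range(config.n_chains)]


def write_fixture(chains: Sequence[SimulatedChain], outdir,
                  config: Optional[SimConfig] = None) -> None:
    """Write a dataset in the external file dialects plus a manifest.

    Emits chains.fasta, labels.tsv, and per-chain .pssm/.ss2/.rsa/.cons files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aio.write_fasta([c.bundle.sequence for c in chains],
                    outdir / "chains.fasta")
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("chain\tlabels\n")
        for c in chains:
            fh.write(f"{c.labeled.chain_id}\t"
                     f"{''.join(map(str, c.labeled.labels))}\n")
    for c in chains:
        cid = c.labeled.chain_id
        b = c.bundle
        aio.write_pssm(outdir / f"{cid}.pssm", b.sequence.sequence,
                       b.pssm.logodds, b.pssm.frequencies)
        aio.write_ss2(outdir / f"{cid}.ss2", b.sequence.sequence,
                      b.tracks.ss3)
        aio.write_rsa_dihedrals(outdir / f"{cid}.rsa", b.sequence.sequence,
                                b.tracks.rsa, b.tracks.phi, b.tracks.psi)
        aio.write_conservation(outdir / f"{cid}.cons", b.sequence.sequence,
                               b.conservation.scores,
                               b.conservation.low_is_conserved)
    manifest = {"n_chains": len(chains),
                "chains": [c.labeled.chain_id for c in chains]}
    if config is not None:
        manifest["config"] = asdict(config)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_fixture(outdir) -> list[SimulatedChain]:
    """Read a fixture directory back into labeled chains and bundles."""
    outdir = Path(outdir)
    records = aio.read_fasta(outdir / "chains.fasta")
    labels = {}
    for line in (outdir / "labels.tsv").read_text().splitlines()[1:]:
        cid, lab = line.split("\t")
        labels[cid] = np.array([int(c) for c in lab])
    chains = []
    for rec in records:
        seq = rec.sequence
        pssm = aio.read_pssm(outdir / f"{rec.id}.pssm", seq)
        pssm.chain_id = rec.id
        tracks = aio.read_struct_tracks(outdir / f"{rec.id}.ss2",
                                        outdir / f"{rec.id}.rsa", seq,
                                        chain_id=rec.id)
        cons = aio.read_conservation(outdir / f"{rec.id}.cons", seq)
        cons.chain_id = rec.id
        bundle = ProfileBundle(sequence=rec, pssm=pssm, tracks=tracks,
                               conservation=cons)
        chains.append(SimulatedChain(
            labeled=LabeledChain(record=rec, labels=labels[rec.id],
                                 source="synthetic"),
            bundle=bundle))
    return chains


# ---------------------------------------------------------------------------
# Toy complexes for the annotation rule
# ---------------------------------------------------------------------------

def simulate_complex(chain: SequenceRecord, labeled_positions: Sequence[int],
                     path, cutoff: float = 3.9,
                     ligand_name: str = "ATP",
                     boundary_positions: Sequence[int] = (),
                     hydrogen_decoy_positions: Sequence[int] = ()) -> None:
    """Write a toy PDB complex that re-annotates to the requested labels.

    Residues are laid out as single C-alpha atoms 4.0 A apart along x. For
    every 0-based position in ``labeled_positions`` a heavy ligand atom is
    placed at distance ``cutoff - 0.1``; all other residues are at least
    ``cutoff + 1.0`` from every heavy ligand atom. ``boundary_positions`` get
    a ligand atom at exactly ``cutoff`` (and so must NOT be labeled under the
    strict-< rule); ``hydrogen_decoy_positions`` get a ligand *hydrogen*
    within the cutoff, which must be ignored.
    """
    L = len(chain.sequence)
    spacing = 4.0
    for p in list(labeled_positions) + list(boundary_positions) + \
            list(hydrogen_decoy_positions):
        if not 0 <= p < L:
            raise ValueError(f"position {p} outside chain of length {L}")
    near = cutoff - 0.1
    if np.hypot(spacing, near) < cutoff + 1.0:
        raise ValueError("geometry infeasible: neighboring residues would "
                         "fall within cutoff + 1.0 of the ligand")

    three = {v: k for k, v in
             {"ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
              "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
              "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
              "SER": "S", "THR": "T", "VAL": "V", "TRP": "W",
              "TYR": "Y"}.items()}
    lines = []
    serial = 1
    for i, aa in enumerate(chain.sequence):
        resname = three.get(aa, "UNK")
        x = i * spacing
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:<3s} A{i + 1:4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'C':>2s}")
        serial += 1
    atom_idx = 1
    for p in labeled_positions:
        x = p * spacing
        lines.append(
            f"HETATM{serial:5d}  C{atom_idx:<2d} {ligand_name:<3s} B 500    "
            f"{x:8.3f}{near:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'C':>2s}")
        serial += 1
        atom_idx += 1
    for p in boundary_positions:
        x = p * spacing
        lines.append(
            f"HETATM{serial:5d}  C{atom_idx:<2d} {ligand_name:<3s} B 500    "
            f"{x:8.3f}{cutoff:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'C':>2s}")
        serial += 1
        atom_idx += 1
    for p in hydrogen_decoy_positions:
        x = p * spacing
        lines.append(
            f"HETATM{serial:5d}  H{atom_idx:<2d} {ligand_name:<3s} B 500    "
            f"{x:8.3f}{near:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'H':>2s}")
        serial += 1
        atom_idx += 1
    if not labeled_positions and not boundary_positions \
            and not hydrogen_decoy_positions:
        # the ligand must exist; park one atom far away
        lines.append(
            f"HETATM{serial:5d}  C1  {ligand_name:<3s} B 500    "
            f"{0.0:8.3f}{100.0:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'C':>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
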