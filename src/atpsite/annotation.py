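"""Structure-derived binding labels and sequence-redundancy reduction.

A residue is annotated as ATP-binding when at least one of its non-hydrogen
atoms lies strictly closer than a distance cutoff (default 3.9 A) to a
non-hydrogen atom of a bound ATP molecule, with all ATP copies in the file
considered against every chain. Redundancy between labeled chains is removed
by greedy identity clustering down to a maximum pairwise identity (default
40%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.PDBData import protein_letters_3to1_extended
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .io import ALPHABET, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class LabeledChain:
    """A chain with per-residue binary binding labels and its provenance."""

    record: SequenceRecord
    labels: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.record.sequence),):
            raise ValueError(
                f"{self.record.id}: label length {self.labels.shape} != "
                f"sequence length {len(self.record.sequence)}")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def chain_id(self) -> str:
        return self.record.id

    def __len__(self) -> int:
        return len(self.record.sequence)


def _is_hydrogen(atom) -> bool:
    element = (atom.element or "").strip().upper()
    if element:
        return element in ("H", "D")
    name = atom.get_name().strip().upper()
    return name.startswith("H") or (name[:1].isdigit() and
                                    name[1:2] == "H")


def _residue_letter(resname: str) -> str:
    letter = protein_letters_3to1_extended.get(resname.strip().upper(), "X")
    if len(letter) != 1 or letter not in ALPHABET:
        letter = "X"
    return letter


def _heavy_coords(residue) -> np.ndarray:
    coords = [a.get_coord() for a in residue.get_atoms()
              if not _is_hydrogen(a)]
    return np.asarray(coords, dtype=float)


def annotate_binding(structure_path, ligand_name: str = "ATP",
                     cutoff: float = 3.9,
                     structure_id: Optional[str] = None) -> list[LabeledChain]:
    """Label every chain of a protein-ligand complex.

    A residue gets label 1 iff the minimum distance between any of its
    non-hydrogen atoms and any non-hydrogen atom of any copy of the named
    het group is strictly below ``cutoff``. Hydrogens (and deuteriums) on
    both sides are excluded. Raises if the ligand is absent; chains with no
    resolved atoms are skipped with a warning.
    """
    path = Path(structure_path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(structure_id or path.stem, str(path))
    model = next(structure.get_models())

    ligand_coords = []
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag != " " and residue.get_resname().strip() == ligand_name:
                c = _heavy_coords(residue)
                if c.size:
                    ligand_coords.append(c)
    if not ligand_coords:
        raise ValueError(f"{path}: no het group {ligand_name!r} found")
    ligand_xyz = np.vstack(ligand_coords)

    out: list[LabeledChain] = []
    for chain in model:
        letters: list[str] = []
        labels: list[int] = []
        for residue in chain:
            hetflag = residue.id[0]
            resname = residue.get_resname().strip()
            if hetflag == "W" or resname == ligand_name:
                continue
            if hetflag != " " and resname not in protein_letters_3to1_extended:
                continue  # other het groups are not chain residues
            xyz = _heavy_coords(residue)
            if xyz.size == 0:
                continue
            letters.append(_residue_letter(resname))
            dmin = cdist(xyz, ligand_xyz).min()
            labels.append(1 if dmin < cutoff else 0)
        if not letters:
            logger.warning("%s: chain %s has no resolved residues; skipped",
                           path, chain.id)
            continue
        cid = f"{structure.id}_{chain.id}"
        out.append(LabeledChain(record=SequenceRecord(cid, "".join(letters)),
                                labels=np.asarray(labels),
                                source=structure.id))
    if not out:
        raise ValueError(f"{path}: no chains with resolved residues")
    return out


# ---------------------------------------------------------------------------
# Redundancy reduction
# ---------------------------------------------------------------------------

def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str,
                      aligner: Optional[PairwiseAligner] = None) -> float:
    """Global-alignment identity: exact matches / length of the shorter chain."""
    if aligner is None:
        aligner = _global_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        matches += sum(1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1])
                       if x == y)
    return matches / min(len(seq_a), len(seq_b))


def reduce_redundancy(chains: Sequence[LabeledChain],
                      max_identity: float = 0.40) -> list[LabeledChain]:
    """Greedy identity clustering; returns cluster representatives.

    Chains are visited longest first; a chain joins the first existing
    cluster whose representative it matches with identity > ``max_identity``,
    otherwise it founds a new cluster. Representatives are the founding
    (longest) members.
    """
    if not chains:
        raise ValueError("no chains to cluster")
    aligner = _global_aligner()
    ordered = sorted(chains, key=lambda c: (-len(c), c.chain_id))
    representatives: list[LabeledChain] = []
    for chain in ordered:
        for rep in representatives:
            if pairwise_identity(chain.record.sequence, rep.record.sequence,
                                 aligner) > max_identity:
                break
        else:
            representatives.append(chain)
    return representatives
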