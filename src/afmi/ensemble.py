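"""Weighted conformational ensembles of one-bead-per-residue chains.

Coordinates are stored in nm internally; multi-model PDB files are written in
Angstrom with one CA pseudo-atom per residue, so they can be inspected with any
standard structure viewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from Bio.SeqUtils import seq3, seq1

from .constants import ANGSTROM_PER_NM

__all__ = [
    "WeightedEnsemble",
    "write_ensemble_pdb",
    "read_ensemble_pdb",
]


@dataclass
class WeightedEnsemble:
    """A set of conformations (frames) with normalized statistical weights.

    Parameters
    ----------
    frames:
        Array of shape ``(n_frames, n_beads, 3)``, in nm.
    weights:
        Array of shape ``(n_frames,)``; normalized to unit sum on construction.
    source:
        Optional ``(n_frames, 2)`` integer array of (replica, frame) indices
        recording where each frame came from in a multi-replica run.
    """

    frames: np.ndarray
    weights: np.ndarray
    source: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_beads, 3)")
        if len(self.frames) == 0:
            raise ValueError("ensemble must contain at least one frame")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.frames),):
            raise ValueError("weights length must match number of frames")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        self.weights = w / total

    @classmethod
    def uniform(cls, frames: np.ndarray) -> "WeightedEnsemble":
        frames = np.asarray(frames, dtype=float)
        n = len(frames)
        return cls(frames, np.full(n, 1.0 / n))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]


def _chain_atom_array(sequence: str, coords_angstrom: np.ndarray) -> struc.AtomArray:
    n = len(sequence)
    atoms = struc.AtomArray(n)
    atoms.coord = coords_angstrom
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.array([seq3(aa).upper() for aa in sequence])
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    return atoms


def write_ensemble_pdb(
    path,
    ensemble: WeightedEnsemble,
    sequence: str,
    b_factor: np.ndarray | None = None,
) -> None:
    """Write an ensemble as a multi-model CA-trace PDB file.

    ``b_factor`` (per residue, e.g. a pLDDT score) is replicated across models.
    """
    if len(sequence) != ensemble.n_beads:
        raise ValueError("sequence length does not match bead count")
    n_frames = ensemble.n_frames
    template = _chain_atom_array(sequence, ensemble.frames[0] * ANGSTROM_PER_NM)
    stack = struc.AtomArrayStack(n_frames, len(sequence))
    for category in template.get_annotation_categories():
        stack.set_annotation(category, template.get_annotation(category))
    stack.coord = ensemble.frames * ANGSTROM_PER_NM
    if b_factor is not None:
        stack.set_annotation("b_factor", np.asarray(b_factor, dtype=float))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble_pdb(path) -> tuple[WeightedEnsemble, str, np.ndarray | None]:
    """Read a multi-model CA-trace PDB.

    Returns the ensemble (uniform weights, nm), the one-letter sequence, and
    the per-residue B-factor column of the first model (or ``None``).
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, extra_fields=["b_factor"])
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    ca = stack[:, stack.atom_name == "CA"]
    sequence = "".join(seq1(name.capitalize()) for name in ca.res_name[:])
    frames = ca.coord / ANGSTROM_PER_NM
    b = None
    try:
        b = np.asarray(ca.get_annotation("b_factor"), dtype=float)
    except ValueError:
        pass
    return WeightedEnsemble.uniform(frames), sequence, b
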