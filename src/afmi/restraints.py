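"""Selection of distance restraints from a distogram and confidence annotations.

The filtering protocol keeps a residue pair (i, j) as a restraint iff

1. the distogram tail mass p_ij(r >= last finite edge) <= ``tail_threshold``
   (default 0.02) — the predictor cannot place distances beyond its grid;
2. the (symmetrized) predicted aligned error PAE(i, j) is below a cutoff
   chosen per protein: 10 A for hydrophilic chains (mean Kyte-Doolittle
   hydropathy < -1.4) that contain at least one 5-residue stretch with
   pLDDT > 75, otherwise 5 A;
3. neither residue lies in a *structured segment* (a maximal run of >= 2
   consecutive residues with pLDDT above the segment cutoff) — those regions
   are instead held near the predicted structure by an RMSD wall, because the
   one-bead model cannot maintain secondary structure on its own;
4. the sequence separation |i - j| is at least ``min_separation`` (default 3;
   shorter-range geometry is the force field's job).

Kept pairs carry the distogram mean and spread (Angstrom) as restraint target
and scale.  pLDDT values are normalized internally to a 0-100 scale, so a
file using 0-1 confidences is accepted transparently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .distogram import Distogram, all_pair_stats

__all__ = [
    "ResidueAnnotations",
    "RestraintSet",
    "detect_structured_segments",
    "choose_pae_cutoff",
    "select_restraints",
    "read_pae_json",
    "read_plddt_table",
    "write_restraints",
    "read_restraints",
]


def _normalize_plddt(plddt: np.ndarray) -> np.ndarray:
    """Bring pLDDT onto the 0-100 scale (accepts 0-1 input)."""
    plddt = np.asarray(plddt, dtype=float)
    if plddt.size == 0:
        raise ValueError("empty pLDDT score list")
    if plddt.max() <= 1.0:
        plddt = plddt * 100.0
    if plddt.min() < 0 or plddt.max() > 100:
        raise ValueError("pLDDT values outside [0, 100] after normalization")
    return plddt


@dataclass
class ResidueAnnotations:
    """Per-residue confidence (pLDDT), pairwise error (PAE) and hydropathy."""

    plddt: np.ndarray  # (N,), 0-100
    pae: np.ndarray  # (N, N), Angstrom, >= 0
    kd_scores: np.ndarray  # (N,), Kyte-Doolittle hydropathy

    def __post_init__(self) -> None:
        self.plddt = _normalize_plddt(self.plddt)
        self.pae = np.asarray(self.pae, dtype=float)
        self.kd_scores = np.asarray(self.kd_scores, dtype=float)
        n = len(self.plddt)
        if self.pae.shape != (n, n):
            raise ValueError("PAE matrix shape inconsistent with pLDDT length")
        if np.any(self.pae < 0):
            raise ValueError("PAE must be non-negative")
        if len(self.kd_scores) != n:
            raise ValueError("hydropathy length inconsistent with pLDDT length")

    @classmethod
    def from_sequence(
        cls, sequence: str, plddt: np.ndarray, pae: np.ndarray
    ) -> "ResidueAnnotations":
        kd = np.array([KYTE_DOOLITTLE[aa] for aa in sequence])
        return cls(plddt=np.asarray(plddt), pae=np.asarray(pae), kd_scores=kd)


@dataclass
class RestraintSet:
    """Selected pairs with targets/spreads plus the structured segments.

    ``provenance`` counts, for each filter in order (tail, pae, segment,
    separation), the pairs it removed; each excluded pair is counted once,
    under the first filter that rejected it.
    """

    i: np.ndarray  # (M,) 0-based indices, i < j
    j: np.ndarray
    target: np.ndarray  # (M,) Angstrom
    sd: np.ndarray  # (M,) Angstrom
    structured_segments: list[tuple[int, int]] = field(default_factory=list)
    selection_mode: float = 5.0  # PAE cutoff used, Angstrom
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.target = np.asarray(self.target, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)

    def __len__(self) -> int:
        return len(self.i)

    @property
    def n_restraints(self) -> int:
        return len(self.i)


def detect_structured_segments(
    plddt: np.ndarray, cutoff: float = 75.0, min_len: int = 2
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive residues with pLDDT > cutoff.

    Returns half-open 0-based ranges ``(start, stop)`` of length >= min_len.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    plddt = _normalize_plddt(plddt)
    above = plddt > cutoff
    segments: list[tuple[int, int]] = []
    start = None
    for idx, flag in enumerate(above):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            if idx - start >= min_len:
                segments.append((start, idx))
            start = None
    if start is not None and len(above) - start >= min_len:
        segments.append((start, len(above)))
    return segments


def choose_pae_cutoff(
    sequence: str,
    plddt: np.ndarray,
    kd_threshold: float = -1.4,
    stretch_len: int = 5,
    stretch_cutoff: float = 75.0,
) -> float:
    """Per-protein PAE cutoff: 10 A or 5 A.

    The looser 10 A cutoff applies to hydrophilic chains (mean Kyte-Doolittle
    score below ``kd_threshold``, i.e. disorder-prone) that nonetheless show a
    confidently predicted stretch of >= ``stretch_len`` residues with
    pLDDT > ``stretch_cutoff``; every other protein gets the strict 5 A cutoff.
    """
    plddt = _normalize_plddt(plddt)
    if len(plddt) != len(sequence):
        raise ValueError("pLDDT length inconsistent with sequence")
    mean_kd = float(np.mean([KYTE_DOOLITTLE[aa] for aa in sequence]))
    has_stretch = any(
        stop - start >= stretch_len
        for start, stop in detect_structured_segments(
            plddt, cutoff=stretch_cutoff, min_len=stretch_len
        )
    )
    return 10.0 if (mean_kd < kd_threshold and has_stretch) else 5.0


def select_restraints(
    d: Distogram,
    ann: ResidueAnnotations,
    tail_threshold: float = 0.02,
    min_separation: int = 3,
    kd_threshold: float = -1.4,
    stretch_len: int = 5,
    stretch_cutoff: float = 75.0,
    segment_cutoff: float = 75.0,
    segment_min_len: int = 2,
) -> RestraintSet:
    """Apply the full filtering protocol and return the restraint set.

    The kept set is independent of pair enumeration order; the filter order
    (tail -> PAE -> segment -> separation) only fixes provenance bookkeeping.
    """
    n = d.n_residues
    if len(ann.plddt) != n:
        raise ValueError("annotations refer to a different sequence length")
    mean, sd, tail = all_pair_stats(d)
    # hydropathy from the annotations (authoritative for the branch rule)
    mean_kd = float(ann.kd_scores.mean())
    has_stretch = any(
        stop - start >= stretch_len
        for start, stop in detect_structured_segments(
            ann.plddt, cutoff=stretch_cutoff, min_len=stretch_len
        )
    )
    pae_cutoff = 10.0 if (mean_kd < kd_threshold and has_stretch) else 5.0
    segments = detect_structured_segments(
        ann.plddt, cutoff=segment_cutoff, min_len=segment_min_len
    )
    in_segment = np.zeros(n, dtype=bool)
    for start, stop in segments:
        in_segment[start:stop] = True

    iu, ju = np.triu_indices(n, k=1)
    pae_sym = np.maximum(ann.pae, ann.pae.T)  # conservative symmetrization

    pass_tail = tail[iu, ju] <= tail_threshold
    pass_pae = pae_sym[iu, ju] < pae_cutoff
    pass_segment = ~(in_segment[iu] | in_segment[ju])
    pass_sep = (ju - iu) >= min_separation

    keep = pass_tail & pass_pae & pass_segment & pass_sep
    # provenance: first failing filter in fixed order
    fail_tail = ~pass_tail
    fail_pae = pass_tail & ~pass_pae
    fail_segment = pass_tail & pass_pae & ~pass_segment
    fail_sep = pass_tail & pass_pae & pass_segment & ~pass_sep
    provenance = {
        "tail": int(fail_tail.sum()),
        "pae": int(fail_pae.sum()),
        "segment": int(fail_segment.sum()),
        "separation": int(fail_sep.sum()),
        "kept": int(keep.sum()),
        "total_pairs": len(iu),
    }
    if keep.sum() == 0:
        warnings.warn("restraint selection kept no pairs", stacklevel=2)
    return RestraintSet(
        i=iu[keep],
        j=ju[keep],
        target=mean[iu, ju][keep],
        sd=sd[iu, ju][keep],
        structured_segments=segments,
        selection_mode=pae_cutoff,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_pae_json(path) -> np.ndarray:
    """Read a PAE matrix from database-style JSON.

    Accepts ``{"predicted_aligned_error": [[...]]}`` at top level or wrapped
    in a single-element list.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        doc = doc[0]
    if "predicted_aligned_error" not in doc:
        raise ValueError("missing 'predicted_aligned_error' field in PAE JSON")
    pae = np.asarray(doc["predicted_aligned_error"], dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError("PAE matrix must be square")
    return pae


def read_plddt_table(path) -> np.ndarray:
    """Read per-residue pLDDT from a two-column text table (index, score)."""
    table = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    if table.shape[1] < 2:
        raise ValueError("pLDDT table must have two columns (index, score)")
    return table.iloc[:, 1].to_numpy(dtype=float)


def write_restraints(prefix, rs: RestraintSet) -> None:
    """Write a restraint set as TSV (i, j, target_A, sd_A) + JSON sidecar."""
    df = pd.DataFrame(
        {"i": rs.i, "j": rs.j, "target_A": rs.target, "sd_A": rs.sd}
    )
    df.to_csv(f"{prefix}.tsv", sep="\t", index=False)
    sidecar = {
        "structured_segments": [list(seg) for seg in rs.structured_segments],
        "selection_mode_pae_A": rs.selection_mode,
        "provenance": rs.provenance,
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_restraints(prefix) -> RestraintSet:
    df = pd.read_csv(f"{prefix}.tsv", sep="\t")
    with open(f"{prefix}.json") as fh:
        sidecar = json.load(fh)
    return RestraintSet(
        i=df["i"].to_numpy(),
        j=df["j"].to_numpy(),
        target=df["target_A"].to_numpy(),
        sd=df["sd_A"].to_numpy(),
        structured_segments=[tuple(s) for s in sidecar["structured_segments"]],
        selection_mode=sidecar["selection_mode_pae_A"],
        provenance=sidecar["provenance"],
    )
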