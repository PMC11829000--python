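"""Distograms: per-residue-pair discrete distributions over binned distances.

A structure-prediction network emits, for every residue pair (i, j), the
probability :math:`p^b_{ij}` that their (Cbeta-based) distance falls into bin
*b* of a fixed grid.  The default grid has 64 equal-width bins covering
2.15625-21.84375 Angstrom; the last bin absorbs all longer distances, so its
occupancy (the *tail mass*) flags pairs whose true distance is off-grid.

The expected distance and its spread for a pair follow from the first two
moments of the binned distribution,

.. math::

    \\hat d_{ij} = \\sum_b d^b\\, p^b_{ij}, \\qquad
    \\sigma_{ij} = \\sqrt{\\sum_b (d^b - \\hat d_{ij})^2\\, p^b_{ij}},

with :math:`d^b` the central value of bin *b* (midpoint of its edges,
including the last finite bin).

Distances are Angstrom throughout this module; conversion to nm happens once
at the restraint boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM_PER_NM
from .ensemble import WeightedEnsemble

__all__ = [
    "DEFAULT_FIRST_EDGE",
    "DEFAULT_LAST_EDGE",
    "DEFAULT_N_BINS",
    "default_bin_edges",
    "bin_centers",
    "Distogram",
    "PairStats",
    "pair_stats",
    "read_distogram",
    "write_distogram",
    "distogram_from_ensemble",
]

DEFAULT_FIRST_EDGE = 2.15625  # Angstrom
DEFAULT_LAST_EDGE = 21.84375  # Angstrom
DEFAULT_N_BINS = 64

#: Probability-sum tolerance for *stored* distograms (strict).
_SUM_TOL_STRICT = 1e-6
#: Probability-sum tolerance accepted on read before renormalization.
_SUM_TOL_READ = 1e-3


def default_bin_edges() -> np.ndarray:
    """The canonical 65-edge grid (64 equal-width bins)."""
    return np.linspace(DEFAULT_FIRST_EDGE, DEFAULT_LAST_EDGE, DEFAULT_N_BINS + 1)


def bin_centers(bin_edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(bin_edges, dtype=float)
    return 0.5 * (edges[:-1] + edges[1:])


class DistogramError(ValueError):
    pass


@dataclass
class Distogram:
    """Validated symmetric pair-distance distribution container.

    Attributes
    ----------
    sequence:
        One-letter amino-acid sequence of length N.
    bin_edges:
        Strictly increasing distance-bin edges in Angstrom (``n_bins + 1``).
    probs:
        Array ``(N, N, n_bins)``, symmetric in the first two axes; the
        diagonal is zero and is never interpreted.
    """

    sequence: str
    bin_edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        n = len(self.sequence)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) < 3:
            raise DistogramError("bin_edges must be a 1-D array of >= 3 edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise DistogramError("bin_edges must be strictly increasing")
        n_bins = len(self.bin_edges) - 1
        if self.probs.shape != (n, n, n_bins):
            raise DistogramError(
                f"probs shape {self.probs.shape} inconsistent with sequence "
                f"length {n} and {n_bins} bins"
            )
        if np.any(self.probs < 0):
            raise DistogramError("negative bin probability")
        if not np.allclose(self.probs, self.probs.transpose(1, 0, 2)):
            raise DistogramError("probs must be symmetric under i<->j")
        offdiag = ~np.eye(n, dtype=bool)
        sums = self.probs.sum(axis=2)[offdiag]
        if np.any(np.abs(sums - 1.0) > _SUM_TOL_STRICT):
            raise DistogramError("unnormalized distogram (pair sums differ from 1)")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def centers(self) -> np.ndarray:
        return bin_centers(self.bin_edges)


@dataclass(frozen=True)
class PairStats:
    """First two moments of one pair's binned distance distribution."""

    i: int
    j: int
    mean: float  # Angstrom
    sd: float  # Angstrom
    tail_mass: float  # probability in the last bin


def pair_stats(d: Distogram, i: int, j: int) -> PairStats:
    """Expected distance, spread and tail mass for pair (i, j)."""
    n = d.n_residues
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"pair ({i}, {j}) out of range for {n} residues")
    if i == j:
        raise ValueError("pair_stats undefined for i == j")
    p = d.probs[i, j]
    c = d.centers
    mean = float(np.dot(c, p))
    var = float(np.dot((c - mean) ** 2, p))
    sd = float(np.sqrt(max(var, 0.0)))
    return PairStats(i=i, j=j, mean=mean, sd=sd, tail_mass=float(p[-1]))


def all_pair_stats(d: Distogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized moments for all pairs.

    Returns ``(mean, sd, tail_mass)``, each of shape ``(N, N)``; diagonal
    entries are zero and meaningless.
    """
    c = d.centers
    mean = d.probs @ c
    var = (d.probs * (c[None, None, :] - mean[..., None]) ** 2).sum(axis=2)
    sd = np.sqrt(np.maximum(var, 0.0))
    tail = d.probs[..., -1]
    np.fill_diagonal(mean, 0.0)
    np.fill_diagonal(sd, 0.0)
    np.fill_diagonal(tail, 0.0)
    return mean, sd, tail


# ---------------------------------------------------------------------------
# Exchange format (JSON): {"sequence": ..., "bin_edges_angstrom": [...],
#   "pairs": [{"i": int, "j": int, "p": [n_bins floats]}, ...]}, i < j only.
# ---------------------------------------------------------------------------


def write_distogram(path, d: Distogram) -> None:
    n = d.n_residues
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append({"i": i, "j": j, "p": d.probs[i, j].tolist()})
    doc = {
        "sequence": d.sequence,
        "bin_edges_angstrom": d.bin_edges.tolist(),
        "pairs": pairs,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_distogram(path) -> Distogram:
    """Read and validate a distogram in the JSON exchange format.

    Pair probabilities whose sum deviates from 1 by at most 1e-3 are
    renormalized; larger deviations are an error.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("sequence", "bin_edges_angstrom", "pairs"):
        if key not in doc:
            raise DistogramError(f"missing field '{key}' in distogram file")
    sequence = doc["sequence"]
    edges = np.asarray(doc["bin_edges_angstrom"], dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise DistogramError("bin_edges must be strictly increasing")
    n = len(sequence)
    n_bins = len(edges) - 1
    probs = np.zeros((n, n, n_bins))
    seen = np.zeros((n, n), dtype=bool)
    for entry in doc["pairs"]:
        i, j, p = int(entry["i"]), int(entry["j"]), np.asarray(entry["p"], float)
        if not (0 <= i < j < n):
            raise DistogramError(f"pair indices ({i}, {j}) out of range or not i<j")
        if len(p) != n_bins:
            raise DistogramError(f"pair ({i}, {j}) has {len(p)} bins, expected {n_bins}")
        if np.any(p < 0):
            raise DistogramError(f"negative probability for pair ({i}, {j})")
        s = p.sum()
        if abs(s - 1.0) > _SUM_TOL_READ:
            raise DistogramError(
                f"unnormalized distogram: pair ({i}, {j}) sums to {s:.6g}"
            )
        if abs(s - 1.0) > 1e-12:  # keep exact files bit-identical
            p = p / s
        probs[i, j] = probs[j, i] = p
        seen[i, j] = True
    expected = n * (n - 1) // 2
    if seen.sum() != expected:
        raise DistogramError(
            f"pair count {int(seen.sum())} inconsistent with sequence length "
            f"{n} (expected {expected})"
        )
    return Distogram(sequence=sequence, bin_edges=edges, probs=probs)


def distogram_from_ensemble(
    ensemble: WeightedEnsemble,
    sequence: str,
    bin_edges: np.ndarray | None = None,
) -> Distogram:
    """Back-calculate a distogram from a weighted ensemble.

    For every pair, the bead-bead distances across frames are histogrammed on
    the grid with the frame weights; distances at or beyond the last edge
    accumulate in the last bin (emulating the predictor's overflow bin).
    """
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, float)
    n = ensemble.n_beads
    if len(sequence) != n:
        raise ValueError("sequence length does not match ensemble bead count")
    n_bins = len(edges) - 1
    iu, ju = np.triu_indices(n, k=1)
    # (n_frames, n_pairs) distances in Angstrom
    diff = ensemble.frames[:, iu] - ensemble.frames[:, ju]
    dist = np.linalg.norm(diff, axis=2) * ANGSTROM_PER_NM
    width = np.diff(edges)
    if np.allclose(width, width[0]):
        idx = np.floor((dist - edges[0]) / width[0]).astype(int)
    else:
        idx = np.searchsorted(edges, dist, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    probs = np.zeros((n, n, n_bins))
    w = ensemble.weights
    for k in range(len(iu)):
        hist = np.bincount(idx[:, k], weights=w, minlength=n_bins)
        probs[iu[k], ju[k]] = probs[ju[k], iu[k]] = hist
    if np.any(dist < edges[0]):
        warnings.warn(
            "distances below the first bin edge were clamped into the first bin",
            stacklevel=2,
        )
    return Distogram(sequence=sequence, bin_edges=edges, probs=probs)
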