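"""Ensemble observables and validation statistics.

The headline validation observable is the pairwise distance distribution
P(r) — the normalized histogram of all inter-residue distances over all
conformations — which is directly comparable with a small-angle-scattering
derived distribution.  Agreement between a target P(r) and a model Q(r) is
scored with the Kullback-Leibler divergence

    D_KL(P || Q) = sum_i P(r_i) log[ P(r_i) / Q(r_i) ]   (natural log, nats),

with empty Q bins regularized by a small redistributed pseudo-mass so that a
model missing a populated bin gives a large but finite penalty.

Chain compaction is summarized by the scaling exponent nu of internal
distances, <R_ij^2>^(1/2) ~ b |i-j|^nu: nu = 0.5 is the Flory random-coil
value, smaller is compact, ~0.6 is an excluded-volume coil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distogram import Distogram, all_pair_stats
from .ensemble import WeightedEnsemble
from .constants import ANGSTROM_PER_NM

__all__ = [
    "PairDistanceDistribution",
    "pair_distance_distribution",
    "distogram_distance_distribution",
    "kl_divergence",
    "radius_of_gyration",
    "ScalingFit",
    "scaling_exponent",
]


@dataclass
class PairDistanceDistribution:
    """Normalized histogram P(r) on a distance grid (Angstrom)."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    density: np.ndarray  # (n_bins,), sums to 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("negative density")
        total = self.density.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            if total <= 0:
                raise ValueError("empty distribution")
            self.density = self.density / total

    @property
    def r_grid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mean(self) -> float:
        return float(np.dot(self.r_grid, self.density))


def pair_distance_distribution(
    source: WeightedEnsemble,
    bin_width: float = 1.0,
    min_separation: int = 1,
    r_max: float | None = None,
) -> PairDistanceDistribution:
    """P(r) over all pairs |i-j| >= min_separation and all frames (Angstrom)."""
    n = source.n_beads
    iu, ju = np.triu_indices(n, k=min_separation)
    diff = source.frames[:, iu] - source.frames[:, ju]
    dist = np.linalg.norm(diff, axis=2) * ANGSTROM_PER_NM
    top = r_max if r_max is not None else float(dist.max()) + bin_width
    if not np.isfinite(top) or top / bin_width > 1e5:
        raise ValueError(
            "distance range implausibly large; the source trajectory has "
            "likely diverged"
        )
    edges = np.arange(0.0, top + bin_width, bin_width)
    w = np.broadcast_to(source.weights[:, None], dist.shape).ravel()
    hist, _ = np.histogram(np.clip(dist.ravel(), 0, edges[-1] - 1e-9), bins=edges, weights=w)
    return PairDistanceDistribution(bin_edges=edges, density=hist / hist.sum())


def distogram_distance_distribution(
    d: Distogram, bin_width: float = 1.0, min_separation: int = 1
) -> PairDistanceDistribution:
    """P(r) built from per-pair distogram mean distances (grid-truncated)."""
    mean, _, _ = all_pair_stats(d)
    iu, ju = np.triu_indices(d.n_residues, k=min_separation)
    vals = mean[iu, ju]
    edges = np.arange(0.0, d.bin_edges[-1] + bin_width, bin_width)
    hist, _ = np.histogram(vals, bins=edges)
    return PairDistanceDistribution(bin_edges=edges, density=hist / hist.sum())


def _rebin(dist: PairDistanceDistribution, edges: np.ndarray) -> np.ndarray:
    """Assign each source bin's mass to the target bin holding its center."""
    idx = np.searchsorted(edges, dist.r_grid, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    out = np.zeros(len(edges) - 1)
    np.add.at(out, idx, dist.density)
    return out


def kl_divergence(
    p: PairDistanceDistribution,
    q: PairDistanceDistribution,
    epsilon: float = 1e-8,
) -> float:
    """Kullback-Leibler divergence D_KL(P || Q) in nats.

    Distributions on different grids are re-binned to the coarser grid over
    the union of their ranges first.  Bins with P_i = 0 contribute zero; Q is
    regularized by redistributing pseudo-mass ``epsilon`` uniformly before
    taking the ratio.  Asymmetric in (P, Q) by construction.
    """
    same_grid = len(p.bin_edges) == len(q.bin_edges) and np.allclose(
        p.bin_edges, q.bin_edges
    )
    if same_grid:
        pd, qd = p.density, q.density
    else:
        width = max(p.bin_width, q.bin_width)
        lo = min(p.bin_edges[0], q.bin_edges[0])
        hi = max(p.bin_edges[-1], q.bin_edges[-1])
        edges = np.arange(lo, hi + width, width)
        if len(edges) < 2:
            raise ValueError("incompatible grids after re-binning")
        pd, qd = _rebin(p, edges), _rebin(q, edges)
    n = len(qd)
    q_reg = (qd + epsilon / n) / (1.0 + epsilon)
    mask = pd > 0
    return float(np.sum(pd[mask] * np.log(pd[mask] / q_reg[mask])))


def radius_of_gyration(
    frames: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float, np.ndarray]:
    """Mass-uniform Rg: weighted mean, standard error, per-frame series (A)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    com = frames.mean(axis=1, keepdims=True)
    rg = np.sqrt(((frames - com) ** 2).sum(axis=2).mean(axis=1)) * ANGSTROM_PER_NM
    if weights is None:
        weights = np.full(len(rg), 1.0 / len(rg))
    w = np.asarray(weights, float)
    w = w / w.sum()
    mean = float(np.dot(w, rg))
    var = float(np.dot(w, (rg - mean) ** 2))
    ess = w.sum() ** 2 / (w**2).sum()
    sem = float(np.sqrt(var / max(ess, 1.0)))
    return mean, sem, rg


@dataclass(frozen=True)
class ScalingFit:
    """Power-law fit <R_ij^2>^(1/2) = prefactor * |i-j|^nu."""

    nu: float
    prefactor: float  # Angstrom
    fit_range: tuple[int, int]  # sequence separations used (inclusive)
    residual: float  # RMS residual of the log-log fit


def fit_power_law(separations: np.ndarray, rms_distances: np.ndarray) -> ScalingFit:
    """Least-squares log-log fit of rms internal distances vs separation."""
    seps = np.asarray(separations, dtype=float)
    rms = np.asarray(rms_distances, dtype=float)
    if len(seps) < 3:
        raise ValueError("fit range must contain at least 3 separations")
    coeffs, res = np.polyfit(np.log(seps), np.log(rms), 1, full=True)[:2]
    nu, log_b = float(coeffs[0]), float(coeffs[1])
    rms_resid = float(np.sqrt(res[0] / len(seps))) if len(res) else 0.0
    return ScalingFit(
        nu=nu,
        prefactor=float(np.exp(log_b)),
        fit_range=(int(seps[0]), int(seps[-1])),
        residual=rms_resid,
    )


def scaling_exponent(
    ensemble: WeightedEnsemble,
    min_sep: int = 5,
    max_sep: int | None = None,
) -> ScalingFit:
    """Fit the internal-distance scaling exponent nu on a weighted ensemble.

    Root-mean-square internal distances are averaged over all pairs at each
    sequence separation s in [min_sep, N/2] (by default) and fit by least
    squares in log-log space.
    """
    n = ensemble.n_beads
    if n < 10:
        raise ValueError("chain too short for a scaling fit")
    max_sep = max_sep or n // 2
    seps = np.arange(min_sep, max_sep + 1)
    w = ensemble.weights
    rms = np.empty(len(seps), dtype=float)
    for k, s in enumerate(seps):
        i = np.arange(n - s)
        diff = ensemble.frames[:, i + s] - ensemble.frames[:, i]
        sq = (diff**2).sum(axis=2)  # (F, n-s) nm^2
        rms[k] = np.sqrt(np.dot(w, sq.mean(axis=1))) * ANGSTROM_PER_NM
    return fit_power_law(seps, rms)
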