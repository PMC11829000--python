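"""Recovering unbiased ensembles from metadynamics runs.

A biased trajectory visiting frame f under (final) bias V_f is unbiased by
Torrie-Valleau weights w_f ~ exp(+V_f / kB T); weighted resampling then turns
the concatenated replica trajectory into a final, uniformly weighted
structural ensemble.  Convergence is diagnosed by free-energy profiles along
the biased CVs over trajectory blocks of increasing coverage, after removing
the first 10% of each replica's trajectory as equilibration.
"""

from __future__ import annotations

import warnings

import numpy as np

from .constants import KB
from .ensemble import WeightedEnsemble

__all__ = [
    "WeightedEnsemble",
    "torrie_valleau_weights",
    "resample_ensemble",
    "effective_sample_size",
    "convergence_profiles",
]


def torrie_valleau_weights(per_frame_bias: np.ndarray, temperature: float) -> np.ndarray:
    """Normalized weights w_f ~ exp(+V_f/kBT), overflow-safe via max shift.

    Invariant under adding a constant to all biases.
    """
    bias = np.asarray(per_frame_bias, dtype=float)
    if bias.size == 0:
        raise ValueError("empty bias series")
    if not np.all(np.isfinite(bias)):
        raise ValueError("non-finite bias values")
    kT = KB * temperature
    shifted = (bias - bias.max()) / kT
    w = np.exp(shifted)
    return w / w.sum()


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2 (>= 1)."""
    w = np.asarray(weights, dtype=float)
    ess = float(w.sum() ** 2 / (w**2).sum())
    if ess < 0.05 * len(w):
        warnings.warn(
            f"effective sample size {ess:.1f} below 5% of {len(w)} frames",
            stacklevel=2,
        )
    return ess


def resample_ensemble(
    frames: np.ndarray,
    weights: np.ndarray,
    n_out: int,
    seed: int = 0,
    scheme: str = "multinomial",
) -> WeightedEnsemble:
    """Resample frames by weight into a uniformly weighted ensemble.

    ``scheme``: "multinomial" (default) or "systematic" (lower variance).
    Deterministic per seed.
    """
    if n_out <= 0:
        raise ValueError("n_out must be positive")
    frames = np.asarray(frames, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    if scheme == "multinomial":
        idx = rng.choice(len(frames), size=n_out, p=w)
    elif scheme == "systematic":
        positions = (rng.uniform() + np.arange(n_out)) / n_out
        idx = np.searchsorted(np.cumsum(w), positions)
    else:
        raise ValueError(f"unknown resampling scheme '{scheme}'")
    source = np.column_stack([np.zeros(n_out, dtype=int), idx])
    return WeightedEnsemble(
        frames=frames[idx], weights=np.full(n_out, 1.0 / n_out), source=source
    )


def convergence_profiles(
    cv_series: list[np.ndarray],
    weights: list[np.ndarray],
    temperature: float,
    n_blocks: int = 5,
    equilibration_fraction: float = 0.1,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted free-energy profiles over blocks of increasing coverage.

    ``cv_series``/``weights`` hold one 1-D array per replica (one biased CV).
    Block b uses the first (b+1)/n_blocks of each replica's post-equilibration
    frames; each block's profile is F(s) = -kBT log(weighted histogram),
    aligned at its minimum.  Returns (bin_centers, profiles) with profiles of
    shape (n_blocks, n_bins); empty bins are NaN.
    """
    if n_blocks < 2:
        raise ValueError("need at least two blocks")
    kT = KB * temperature
    trimmed_cv, trimmed_w = [], []
    for s, w in zip(cv_series, weights):
        s, w = np.asarray(s, float), np.asarray(w, float)
        start = int(np.floor(equilibration_fraction * len(s)))
        trimmed_cv.append(s[start:])
        trimmed_w.append(w[start:])
        if len(s) - start < n_blocks:
            raise ValueError("too few frames per block after equilibration")
    if bin_edges is None:
        all_s = np.concatenate(trimmed_cv)
        bin_edges = np.linspace(all_s.min(), all_s.max(), n_bins + 1)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    profiles = np.full((n_blocks, len(centers)), np.nan)
    for b in range(n_blocks):
        frac = (b + 1) / n_blocks
        s_b = np.concatenate([s[: int(np.ceil(frac * len(s)))] for s in trimmed_cv])
        w_b = np.concatenate([w[: int(np.ceil(frac * len(w)))] for w in trimmed_w])
        hist, _ = np.histogram(s_b, bins=bin_edges, weights=w_b)
        with np.errstate(divide="ignore"):
            f = -kT * np.log(hist / hist.sum())
        f[~np.isfinite(f)] = np.nan
        profiles[b] = f - np.nanmin(f)
    return centers, profiles
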