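import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from afmi.distogram import Distogram, default_bin_edges
from afmi.ensemble import WeightedEnsemble


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_distogram(n_residues: int, rng: np.random.Generator) -> Distogram:
    """Random valid distogram on the default grid."""
    edges = default_bin_edges()
    n_bins = len(edges) - 1
    probs = np.zeros((n_residues, n_residues, n_bins))
    iu, ju = np.triu_indices(n_residues, k=1)
    raw = rng.gamma(0.5, size=(len(iu), n_bins))
    raw /= raw.sum(axis=1, keepdims=True)
    probs[iu, ju] = raw
    probs[ju, iu] = raw
    sequence = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_residues))
    return Distogram(sequence=sequence, bin_edges=edges, probs=probs)


@pytest.fixture
def small_distogram(rng):
    return random_distogram(6, rng)


@pytest.fixture
def coil_ensemble(rng):
    """Freely jointed chain ensemble: 30 beads, bond 3.8 A, 500 frames (nm)."""
    n, frames = 30, 500
    steps = rng.normal(size=(frames, n - 1, 3))
    steps *= 0.38 / np.linalg.norm(steps, axis=2, keepdims=True)
    coords = np.concatenate(
        [np.zeros((frames, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    return WeightedEnsemble.uniform(coords)
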