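"""Distogram container, moments, exchange format and back-calculation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afmi.distogram import (
    DEFAULT_LAST_EDGE,
    Distogram,
    DistogramError,
    bin_centers,
    default_bin_edges,
    distogram_from_ensemble,
    pair_stats,
    read_distogram,
    write_distogram,
)
from afmi.ensemble import WeightedEnsemble

from conftest import random_distogram


def make_two_residue(probs_pair):
    edges = default_bin_edges()
    probs = np.zeros((2, 2, 64))
    probs[0, 1] = probs[1, 0] = probs_pair
    return Distogram(sequence="GS", bin_edges=edges, probs=probs)


class TestGrid:
    def test_default_grid_width(self):
        edges = default_bin_edges()
        widths = np.diff(edges)
        assert len(edges) == 65
        assert np.allclose(widths, 0.3076171875)
        assert edges[0] == 2.15625 and edges[-1] == 21.84375

    def test_centers_are_midpoints(self):
        edges = default_bin_edges()
        c = bin_centers(edges)
        assert c[0] == pytest.approx(2.31005859375, abs=1e-12)


class TestPairStats:
    def test_single_bin_mass(self):
        p = np.zeros(64)
        p[0] = 1.0
        st_ = pair_stats(make_two_residue(p), 0, 1)
        assert st_.mean == pytest.approx(2.31005859375, abs=1e-12)
        assert st_.sd == 0.0

    def test_two_bin_split(self):
        p = np.zeros(64)
        p[0] = p[1] = 0.5
        st_ = pair_stats(make_two_residue(p), 0, 1)
        assert st_.mean == pytest.approx(2.4638671875, abs=1e-12)
        assert st_.sd == pytest.approx(0.15380859375, abs=1e-12)

    def test_uniform_mean_is_grid_midpoint(self):
        p = np.full(64, 1.0 / 64)
        st_ = pair_stats(make_two_residue(p), 0, 1)
        assert st_.mean == pytest.approx(12.0, abs=1e-12)

    def test_tail_mass_is_last_bin(self):
        p = np.zeros(64)
        p[-1] = 0.3
        p[0] = 0.7
        assert pair_stats(make_two_residue(p), 0, 1).tail_mass == pytest.approx(0.3)

    def test_diagonal_and_range_errors(self, small_distogram):
        with pytest.raises(ValueError):
            pair_stats(small_distogram, 2, 2)
        with pytest.raises(IndexError):
            pair_stats(small_distogram, 0, 99)

    def test_moments_match_bruteforce(self, rng):
        """Vectorized moments vs explicit weighted-moment summation."""
        d = random_distogram(5, rng)
        c = bin_centers(d.bin_edges)
        for i in range(5):
            for j in range(i + 1, 5):
                s = pair_stats(d, i, j)
                mean = sum(c[b] * d.probs[i, j, b] for b in range(64))
                var = sum((c[b] - mean) ** 2 * d.probs[i, j, b] for b in range(64))
                assert s.mean == pytest.approx(mean, abs=1e-12)
                assert s.sd == pytest.approx(np.sqrt(var), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_sd_zero_iff_single_bin(self, seed):
        rng = np.random.default_rng(seed)
        p = np.zeros(64)
        k = rng.integers(64)
        if rng.random() < 0.5:
            p[k] = 1.0
            expect_zero = True
        else:
            k2 = (k + 1 + rng.integers(62)) % 64
            p[k], p[k2] = 0.6, 0.4
            expect_zero = False
        s = pair_stats(make_two_residue(p), 0, 1)
        assert (s.sd == 0.0) == expect_zero


class TestExchangeFormat:
    def test_round_trip_identity(self, small_distogram, tmp_path):
        path = tmp_path / "d.json"
        write_distogram(path, small_distogram)
        d2 = read_distogram(path)
        assert d2.sequence == small_distogram.sequence
        np.testing.assert_array_equal(d2.bin_edges, small_distogram.bin_edges)
        np.testing.assert_array_equal(d2.probs, small_distogram.probs)

    def test_unnormalized_pair_rejected(self, small_distogram, tmp_path):
        path = tmp_path / "d.json"
        write_distogram(path, small_distogram)
        doc = json.loads(path.read_text())
        doc["pairs"][0]["p"] = (np.array(doc["pairs"][0]["p"]) * 0.5).tolist()
        path.write_text(json.dumps(doc))
        with pytest.raises(DistogramError, match="unnormalized"):
            read_distogram(path)

    def test_small_deviation_renormalized(self, small_distogram, tmp_path):
        path = tmp_path / "d.json"
        write_distogram(path, small_distogram)
        doc = json.loads(path.read_text())
        doc["pairs"][0]["p"] = (np.array(doc["pairs"][0]["p"]) * 1.0005).tolist()
        path.write_text(json.dumps(doc))
        d2 = read_distogram(path)
        assert np.isclose(d2.probs[0, 1].sum(), 1.0, atol=1e-9)

    @pytest.mark.parametrize("field", ["sequence", "bin_edges_angstrom", "pairs"])
    def test_missing_field_rejected(self, small_distogram, tmp_path, field):
        path = tmp_path / "d.json"
        write_distogram(path, small_distogram)
        doc = json.loads(path.read_text())
        del doc[field]
        path.write_text(json.dumps(doc))
        with pytest.raises(DistogramError, match="missing"):
            read_distogram(path)

    def test_missing_pair_rejected(self, small_distogram, tmp_path):
        path = tmp_path / "d.json"
        write_distogram(path, small_distogram)
        doc = json.loads(path.read_text())
        doc["pairs"] = doc["pairs"][:-1]
        path.write_text(json.dumps(doc))
        with pytest.raises(DistogramError, match="pair count"):
            read_distogram(path)

    def test_non_monotone_edges_rejected(self, small_distogram, tmp_path):
        path = tmp_path / "d.json"
        write_distogram(path, small_distogram)
        doc = json.loads(path.read_text())
        doc["bin_edges_angstrom"][3] = doc["bin_edges_angstrom"][0]
        path.write_text(json.dumps(doc))
        with pytest.raises(DistogramError, match="increasing"):
            read_distogram(path)


class TestFromEnsemble:
    def test_fixed_pair_at_bin_center_is_delta(self):
        c = bin_centers(default_bin_edges())[10] / 10.0  # nm
        frames = np.array([[[0.0, 0, 0], [c, 0, 0]]])
        d = distogram_from_ensemble(WeightedEnsemble.uniform(frames), "GS")
        assert d.probs[0, 1, 10] == 1.0

    def test_beyond_grid_accumulates_in_tail(self):
        frames = np.array([[[0.0, 0, 0], [5.0, 0, 0]]])  # 50 A
        d = distogram_from_ensemble(WeightedEnsemble.uniform(frames), "GS")
        assert d.probs[0, 1, -1] == 1.0
        assert pair_stats(d, 0, 1).tail_mass == 1.0

    def test_mean_recovered_within_half_bin(self, coil_ensemble):
        """Ensemble -> distogram -> moments recovers direct averaging for
        pairs with no tail mass."""
        seq = "G" * coil_ensemble.n_beads
        d = distogram_from_ensemble(coil_ensemble, seq)
        width = d.bin_edges[1] - d.bin_edges[0]
        dist = np.linalg.norm(
            coil_ensemble.frames[:, :, None] - coil_ensemble.frames[:, None, :],
            axis=3,
        ) * 10.0
        direct = dist.mean(axis=0)
        checked = 0
        for i in range(0, 30, 5):
            for j in range(i + 1, 30, 7):
                s = pair_stats(d, i, j)
                if s.tail_mass == 0:
                    assert abs(s.mean - direct[i, j]) < 0.5 * width
                    checked += 1
        assert checked > 5


class TestInvariants:
    def test_negative_probability_rejected(self):
        p = np.zeros(64)
        p[0], p[1] = 1.5, -0.5
        with pytest.raises(DistogramError):
            make_two_residue(p)

    def test_asymmetric_rejected(self):
        edges = default_bin_edges()
        probs = np.zeros((2, 2, 64))
        probs[0, 1, 0] = 1.0
        probs[1, 0, 1] = 1.0
        with pytest.raises(DistogramError, match="symmetric"):
            Distogram(sequence="GS", bin_edges=edges, probs=probs)
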