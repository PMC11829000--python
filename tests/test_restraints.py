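"""Restraint selection filters: structured segments, PAE branch, provenance."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afmi.distogram import Distogram, default_bin_edges
from afmi.restraints import (
    ResidueAnnotations,
    choose_pae_cutoff,
    detect_structured_segments,
    read_pae_json,
    read_plddt_table,
    read_restraints,
    select_restraints,
    write_restraints,
)


def distogram_with_tails(n, tail_by_pair=None, seed=0):
    """Distogram with all mass in bin 20 except prescribed tail masses."""
    edges = default_bin_edges()
    probs = np.zeros((n, n, 64))
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        tail = 0.0 if tail_by_pair is None else tail_by_pair.get((i, j), 0.0)
        p = np.zeros(64)
        p[20] = 1.0 - tail
        p[-1] = tail
        probs[i, j] = probs[j, i] = p
    seq = "S" * n
    return Distogram(sequence=seq, bin_edges=edges, probs=probs)


def annotations(n, plddt=None, pae=None, sequence=None):
    plddt = np.full(n, 40.0) if plddt is None else np.asarray(plddt, float)
    pae = np.full((n, n), 2.0) if pae is None else np.asarray(pae, float)
    sequence = sequence or "S" * n
    return ResidueAnnotations.from_sequence(sequence, plddt, pae)


class TestStructuredSegments:
    def test_short_run_dropped(self):
        assert detect_structured_segments([80, 80, 60, 80], 75, 2) == [(0, 2)]

    def test_all_below_cutoff(self):
        assert detect_structured_segments([10, 50, 75], 75, 2) == []

    def test_single_maximal_run(self):
        assert detect_structured_segments([80] * 10, 75, 2) == [(0, 10)]

    def test_zero_to_one_scale_normalized(self):
        # confidences given on a 0-1 scale are read as percentages
        assert detect_structured_segments([0.8, 0.8, 0.6, 0.8], 75, 2) == [(0, 2)]

    def test_run_at_end_kept(self):
        assert detect_structured_segments([10, 80, 80, 80], 75, 2) == [(1, 4)]


class TestPaeCutoffBranch:
    def test_hydrophilic_with_stretch_gets_10(self):
        # poly-Q/N is strongly hydrophilic (KD -3.5)
        plddt = [80] * 6 + [40] * 14
        assert choose_pae_cutoff("Q" * 20, plddt) == 10.0

    def test_hydrophilic_without_stretch_gets_5(self):
        plddt = [80] * 4 + [40] * 16
        assert choose_pae_cutoff("Q" * 20, plddt) == 5.0

    def test_hydrophobic_always_gets_5(self):
        # poly-I: KD +4.5, fails the hydrophilicity conjunct
        assert choose_pae_cutoff("I" * 20, [80] * 20) == 5.0


class TestSelectRestraints:
    def test_tail_threshold(self):
        d = distogram_with_tails(6, {(0, 3): 0.03, (1, 4): 0.01})
        rs = select_restraints(d, annotations(6), min_separation=3)
        kept = set(zip(rs.i.tolist(), rs.j.tolist()))
        assert (1, 4) in kept and (0, 3) not in kept
        assert rs.provenance["tail"] >= 1

    def test_pae_cutoff_applied(self):
        d = distogram_with_tails(8)
        pae = np.full((8, 8), 2.0)
        pae[0, 4] = pae[4, 0] = 4.0
        pae[1, 5] = pae[5, 1] = 7.0
        pae[2, 6] = pae[6, 2] = 12.0
        # hydrophilic with a confident stretch -> cutoff 10
        plddt = [80] * 6 + [40] * 2
        ann = annotations(8, plddt=plddt, pae=pae, sequence="Q" * 8)
        rs = select_restraints(
            d, ann, min_separation=3, segment_cutoff=101.0
        )  # disable segment filter to isolate PAE behaviour
        assert rs.selection_mode == 10.0
        kept = set(zip(rs.i.tolist(), rs.j.tolist()))
        assert (0, 4) in kept and (1, 5) in kept and (2, 6) not in kept

    def test_segment_exclusion_beats_perfect_pae(self):
        d = distogram_with_tails(8)
        plddt = [90, 90, 90, 40, 40, 40, 40, 40]  # segment [0,3)
        ann = annotations(8, plddt=plddt)
        rs = select_restraints(d, ann, min_separation=3)
        assert rs.structured_segments == [(0, 3)]
        assert not any(i < 3 for i in rs.i)

    def test_min_separation(self):
        d = distogram_with_tails(6)
        rs = select_restraints(d, annotations(6), min_separation=3)
        assert np.all(rs.j - rs.i >= 3)

    def test_all_confident_chain_gives_empty_set(self):
        """Fully confident prediction: whole chain structured, no distance
        restraints (the folded-protein degenerate case)."""
        d = distogram_with_tails(10)
        ann = annotations(10, plddt=[100] * 10)
        with pytest.warns(UserWarning, match="no pairs"):
            rs = select_restraints(d, ann)
        assert len(rs) == 0
        assert rs.structured_segments == [(0, 10)]

    def test_provenance_counts_partition_pairs(self):
        d = distogram_with_tails(8, {(0, 4): 0.5})
        pae = np.full((8, 8), 2.0)
        pae[1, 5] = pae[5, 1] = 30.0
        ann = annotations(8, pae=pae)
        rs = select_restraints(d, ann)
        p = rs.provenance
        total = p["tail"] + p["pae"] + p["segment"] + p["separation"] + p["kept"]
        assert total == p["total_pairs"] == 28

    def test_targets_within_grid(self):
        d = distogram_with_tails(6)
        rs = select_restraints(d, annotations(6))
        assert np.all(rs.target <= d.bin_edges[-1])
        assert np.all(rs.sd >= 0)

    @given(st.floats(0.0, 0.1), st.floats(0.0, 0.1))
    @settings(max_examples=20, deadline=None)
    def test_tail_filter_monotone(self, t1, t2):
        """Raising the tail threshold never removes a kept pair."""
        lo, hi = sorted([t1, t2])
        d = distogram_with_tails(
            6, {(0, 3): 0.05, (1, 4): 0.02, (2, 5): 0.08}
        )
        ann = annotations(6)
        kept_lo = set(
            zip(*(select_restraints(d, ann, tail_threshold=lo).i,
                  select_restraints(d, ann, tail_threshold=lo).j))
        )
        kept_hi = set(
            zip(*(select_restraints(d, ann, tail_threshold=hi).i,
                  select_restraints(d, ann, tail_threshold=hi).j))
        )
        assert kept_lo <= kept_hi

    def test_pae_symmetrized_conservatively(self):
        d = distogram_with_tails(6)
        pae = np.full((6, 6), 2.0)
        pae[0, 3] = 2.0
        pae[3, 0] = 9.0  # asymmetric entry; max wins -> above cutoff 5
        ann = annotations(6, pae=pae)
        rs = select_restraints(d, ann)
        assert (0, 3) not in set(zip(rs.i.tolist(), rs.j.tolist()))


class TestIO:
    def test_restraints_round_trip(self, tmp_path):
        d = distogram_with_tails(6)
        rs = select_restraints(d, annotations(6))
        write_restraints(tmp_path / "r", rs)
        rs2 = read_restraints(tmp_path / "r")
        np.testing.assert_array_equal(rs.i, rs2.i)
        np.testing.assert_allclose(rs.target, rs2.target)
        assert rs2.provenance == rs.provenance

    def test_pae_json(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text(json.dumps({"predicted_aligned_error": [[0, 1], [1, 0]]}))
        np.testing.assert_array_equal(read_pae_json(path), [[0, 1], [1, 0]])

    def test_plddt_table(self, tmp_path):
        path = tmp_path / "plddt.tsv"
        path.write_text("0 81.5\n1 42.0\n")
        np.testing.assert_allclose(read_plddt_table(path), [81.5, 42.0])
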