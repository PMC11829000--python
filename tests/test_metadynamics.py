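"""Parallel-bias well-tempered metadynamics: bias algebra and CV mechanics."""

import numpy as np
import pytest

from afmi.constants import KB
from afmi.metadynamics import (
    BiasState,
    CVSpec,
    InterBeadDistanceCV,
    RadiusOfGyrationCV,
    SegmentComDistanceCV,
    deposit_hill,
    evaluate_bias_forces,
    make_cv,
    recompute_final_bias,
)

T = 300.0
KT = KB * T


def one_cv_bias(**kw):
    spec = CVSpec(
        kind="inter_bead_distance",
        grid_min=0.0,
        grid_max=4.0,
        grid_spacing=0.002,
        gaussian_width=0.1,
        parameters={"i": 0, "j": 1},
    )
    return BiasState(specs=[spec], **kw)


def two_cv_bias():
    specs = [
        CVSpec("radius_of_gyration", 0.0, 4.0, 0.002, 0.1),
        CVSpec("inter_bead_distance", 0.0, 4.0, 0.002, 0.1, {"i": 0, "j": 1}),
    ]
    return BiasState(specs=specs)


class TestCVs:
    @pytest.mark.parametrize(
        "cv",
        [
            RadiusOfGyrationCV(),
            InterBeadDistanceCV(0, 4),
            SegmentComDistanceCV(np.arange(3), np.arange(3, 6)),
        ],
        ids=["rg", "distance", "com_distance"],
    )
    def test_gradients_match_central_differences(self, cv, rng):
        coords = rng.normal(size=(6, 3))
        s, grad = cv.value_and_grad(coords)
        h = 1e-6
        for _ in range(8):
            i, c = rng.integers(6), rng.integers(3)
            cp, cm = coords.copy(), coords.copy()
            cp[i, c] += h
            cm[i, c] -= h
            num = (cv.value_and_grad(cp)[0] - cv.value_and_grad(cm)[0]) / (2 * h)
            assert num == pytest.approx(grad[i, c], abs=1e-6)

    def test_rg_value(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        s, _ = RadiusOfGyrationCV().value_and_grad(coords)
        assert s == pytest.approx(1.0)

    def test_make_cv_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown CV kind"):
            make_cv(CVSpec("torsion", 0, 1, 0.1, 0.1))


class TestBias:
    def test_zero_bias_gauge(self):
        bias = two_cv_bias()
        v, forces = evaluate_bias_forces(
            np.array([1.0, 1.0]), np.zeros((2, 5, 3)), bias, T
        )
        assert v == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(forces, 0.0)

    def test_first_hill_height_nominal(self):
        bias = one_cv_bias(height=0.7)
        deposit_hill(bias, np.array([1.5]), T)
        v, _ = bias.bias_at(0, 1.5)
        assert v == pytest.approx(0.7, rel=1e-6)

    def test_well_tempered_heights_decrease(self):
        bias = one_cv_bias()
        heights = []
        for _ in range(5):
            deposit_hill(bias, np.array([2.0]), T)
            heights.append(bias.hills[0][-1][2])
        assert all(a > b for a, b in zip(heights, heights[1:]))

    def test_single_cv_reduces_to_well_tempered(self):
        """With one CV the conditional weight is 1, so deposited heights are
        exactly h0 exp(-V/((gamma-1) kT))."""
        bias = one_cv_bias(height=0.5, bias_factor=10.0)
        s = np.array([1.0])
        deposit_hill(bias, s, T)
        v_before, _ = bias.bias_at(0, 1.0)
        deposit_hill(bias, s, T)
        h2 = bias.hills[0][-1][2]
        assert h2 == pytest.approx(0.5 * np.exp(-v_before / (9.0 * KT)), rel=1e-9)

    def test_softmin_dominated_by_deep_bias(self):
        """The combined bias tracks the per-CV minimum within kT log K."""
        bias = two_cv_bias()
        # grow bias only on CV 0
        for _ in range(40):
            deposit_hill(bias, np.array([1.0, 3.5]), T)
        v0 = bias.bias_at(0, 1.0)[0]
        v1 = bias.bias_at(1, 1.0)[0]
        v_pb, _ = evaluate_bias_forces(
            np.array([1.0, 1.0]), np.zeros((2, 4, 3)), bias, T
        )
        direct = -KT * np.log(0.5 * (np.exp(-v0 / KT) + np.exp(-v1 / KT)))
        assert v_pb == pytest.approx(direct, rel=1e-9)
        assert v_pb <= min(v0, v1) + KT * np.log(2) + 1e-9

    def test_bias_nonnegative_and_finite(self, rng):
        bias = two_cv_bias()
        for _ in range(30):
            deposit_hill(bias, rng.uniform(0.5, 3.5, size=2), T)
        for k in range(2):
            assert np.all(np.isfinite(bias.values[k]))
            assert np.all(bias.values[k] >= 0)

    def test_forces_match_central_differences(self, rng):
        spec = CVSpec("inter_bead_distance", 0.0, 4.0, 0.0005, 0.15, {"i": 0, "j": 1})
        bias = BiasState(specs=[spec])
        for _ in range(10):
            deposit_hill(bias, rng.uniform(0.8, 2.5, size=1), T)
        cv = InterBeadDistanceCV(0, 1)

        def energy(coords):
            s, g = cv.value_and_grad(coords)
            return evaluate_bias_forces(np.array([s]), g[None], bias, T)[0]

        coords = np.array([[0.0, 0, 0], [1.7, 0.3, -0.2]])
        s, g = cv.value_and_grad(coords)
        _, forces = evaluate_bias_forces(np.array([s]), g[None], bias, T)
        h = 1e-5
        for i, c in [(0, 0), (1, 1), (1, 2)]:
            cp, cm = coords.copy(), coords.copy()
            cp[i, c] += h
            cm[i, c] -= h
            num = -(energy(cp) - energy(cm)) / (2 * h)
            assert num == pytest.approx(forces[i, c], abs=1e-4)

    def test_out_of_grid_clamped_with_counter(self):
        bias = one_cv_bias()
        deposit_hill(bias, np.array([2.0]), T)
        before = bias.clamp_count
        bias.bias_at(0, 99.0)
        assert bias.clamp_count == before + 1


class TestFinalBias:
    def test_zero_hills_all_zero(self):
        bias = two_cv_bias()
        out = recompute_final_bias(np.random.default_rng(0).uniform(1, 3, (10, 2)), bias, T)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_bruteforce_gaussian_sum(self, rng):
        bias = one_cv_bias()
        centers = rng.uniform(0.5, 3.5, size=25)
        for c in centers:
            deposit_hill(bias, np.array([c]), T)
        frames = rng.uniform(0.6, 3.4, size=(50, 1))
        out = recompute_final_bias(frames, bias, T)
        # brute force: direct summation over stored hills
        brute = np.zeros(50)
        for c0, w, h in bias.hills[0]:
            brute += h * np.exp(-0.5 * ((frames[:, 0] - c0) / w) ** 2)
        np.testing.assert_allclose(out, brute, atol=1e-6)

    def test_grid_node_value_matches_interpolation(self, rng):
        bias = one_cv_bias()
        for _ in range(15):
            deposit_hill(bias, rng.uniform(0.5, 3.5, size=1), T)
        node = bias.grids[0][700]
        exact = recompute_final_bias(np.array([[node]]), bias, T)[0]
        interp, _ = bias.bias_at(0, float(node))
        assert exact == pytest.approx(interp, abs=1e-6)
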