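"""Bayesian restraint energy, error sampling, SEM estimation and RMSD wall."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from afmi.constants import ANGSTROM_PER_NM, KB
from afmi.metainference import (
    ErrorState,
    WallSpec,
    conditional_log_density,
    deviations,
    error_energy,
    gibbs_update_errors,
    kabsch_rmsd,
    restraint_energy_forces,
    rmsd_wall_energy_forces,
    sem_from_window,
)
from afmi.restraints import RestraintSet


def simple_restraints(targets, pairs=None):
    targets = np.atleast_1d(np.asarray(targets, float))
    pairs = pairs or [(0, k + 1) for k in range(len(targets))]
    i, j = np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])
    return RestraintSet(i=i, j=j, target=targets, sd=np.ones_like(targets))


def error_state(n_rep, n_d, sigma_b=1.0, sigma_sem=0.0):
    return ErrorState(
        sigma_b=np.full((n_rep, n_d), sigma_b),
        sigma_sem=np.full(n_d, sigma_sem),
    )


class TestRestraintEnergy:
    def test_zero_deviation_zero_energy(self):
        rs = simple_restraints([10.0])
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0]]])  # 10 A apart
        for mode in ("replica_average", "per_replica"):
            e, f = restraint_energy_forces(coords, rs, error_state(1, 1), 300.0, mode)
            assert e[0] == pytest.approx(0.0, abs=1e-12)
            np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_unit_deviation_half_kt(self):
        """|d - f| = 1 A with sigma_B = 1 A, sigma_SEM = 0 gives kBT/2."""
        rs = simple_restraints([11.0])
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0]]])
        e, _ = restraint_energy_forces(coords, rs, error_state(1, 1), 300.0)
        assert e[0] == pytest.approx(0.5 * KB * 300.0, rel=1e-12)

    @pytest.mark.parametrize("mode", ["replica_average", "per_replica"])
    def test_forces_match_central_differences(self, mode, rng):
        n_rep, n_beads = 3, 5
        rs = simple_restraints([8.0, 12.0, 6.0], pairs=[(0, 2), (1, 4), (2, 3)])
        errors = ErrorState(
            sigma_b=rng.uniform(0.5, 2.0, size=(n_rep, 3)),
            sigma_sem=rng.uniform(0.0, 0.5, size=3),
        )
        coords = rng.normal(scale=0.5, size=(n_rep, n_beads, 3))

        def energy(c):
            e, _ = restraint_energy_forces(c, rs, errors, 300.0, mode)
            return e.sum()

        _, forces = restraint_energy_forces(coords, rs, errors, 300.0, mode)
        h = 1e-6
        for _ in range(10):
            r, i, c = rng.integers(n_rep), rng.integers(n_beads), rng.integers(3)
            cp, cm = coords.copy(), coords.copy()
            cp[r, i, c] += h
            cm[r, i, c] -= h
            num = -(energy(cp) - energy(cm)) / (2 * h)
            assert num == pytest.approx(forces[r, i, c], abs=1e-4)

    def test_large_sigma_deactivates_restraint(self):
        rs = simple_restraints([20.0])
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0]]])
        _, f_tight = restraint_energy_forces(coords, rs, error_state(1, 1, 0.5), 300.0)
        _, f_loose = restraint_energy_forces(coords, rs, error_state(1, 1, 10.0), 300.0)
        assert np.abs(f_loose).max() < 1e-2 * np.abs(f_tight).max()


class TestErrorEnergy:
    def test_unity_sigma_zero_energy(self):
        e = error_energy(error_state(1, 1, 1.0, 0.0), 300.0, "as_printed")
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_as_printed_cancels_without_sem(self, rng):
        """With sigma_SEM = 0 the printed form reduces to
        sum(-log s + log s) = 0 for any sigma_B."""
        sb = rng.uniform(0.01, 9.0, size=(3, 7))
        errors = ErrorState(sigma_b=sb, sigma_sem=np.zeros(7))
        assert error_energy(errors, 300.0, "as_printed") == pytest.approx(0.0, abs=1e-9)

    def test_jeffreys_differs_by_prior_sign(self, rng):
        sb = rng.uniform(0.1, 5.0, size=(2, 4))
        sem = rng.uniform(0.1, 1.0, size=4)
        errors = ErrorState(sigma_b=sb, sigma_sem=sem)
        diff = error_energy(errors, 300.0, "jeffreys") - error_energy(
            errors, 300.0, "as_printed"
        )
        assert diff == pytest.approx(2 * KB * 300.0 * np.log(sb).sum(), rel=1e-9)

    def test_monotone_in_sigma_sem(self):
        e1 = error_energy(error_state(2, 3, 1.0, 0.5), 300.0)
        e2 = error_energy(error_state(2, 3, 1.0, 1.0), 300.0)
        assert e2 > e1


class TestGibbs:
    def test_out_of_bounds_proposals_rejected(self):
        errors = ErrorState(
            sigma_b=np.full((1, 1), 9.99), sigma_sem=np.zeros(1), move_width=0.5
        )
        rng = np.random.default_rng(0)
        for _ in range(200):
            gibbs_update_errors(errors, np.zeros((1, 1)), 300.0, rng)
        assert errors.sigma_b[0, 0] <= 10.0

    def test_zero_move_width_frozen(self):
        errors = ErrorState(
            sigma_b=np.full((2, 3), 1.0), sigma_sem=np.zeros(3), move_width=0.0
        )
        rng = np.random.default_rng(1)
        gibbs_update_errors(errors, np.ones((2, 3)), 300.0, rng)
        np.testing.assert_array_equal(errors.sigma_b, 1.0)

    def test_marginal_matches_quadrature(self):
        """Sampled sigma_B histogram vs quadrature of the full conditional
        (Jeffreys mode: concentrated conditional, adequate mixing)."""
        dev, sem = 1.0, 0.2
        errors = ErrorState(
            sigma_b=np.full((8, 16), 1.0), sigma_sem=np.full(16, sem)
        )
        rng = np.random.default_rng(12345)
        devs = np.full((8, 16), dev)
        samples = []
        n_sweeps = 20_000
        for sweep in range(n_sweeps):
            gibbs_update_errors(errors, devs, 300.0, rng, "jeffreys")
            if sweep > n_sweeps // 5 and sweep % 40 == 0:
                samples.append(errors.sigma_b.ravel().copy())
        samples = np.concatenate(samples)
        grid = np.linspace(1e-4, 10.0, 20001)
        logp = conditional_log_density(grid, dev, sem, "jeffreys")
        p = np.exp(logp - logp.max())
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(samples), grid) / len(samples)
        ks = np.abs(emp - cdf).max()
        assert ks < 0.05  # looser than the acceptance-level bound at 1e5 sweeps

    def test_deterministic_per_seed(self):
        outs = []
        for _ in range(2):
            errors = ErrorState(sigma_b=np.full((2, 3), 1.0), sigma_sem=np.zeros(3))
            rng = np.random.default_rng(99)
            for _ in range(100):
                gibbs_update_errors(errors, np.ones((2, 3)), 300.0, rng)
            outs.append(errors.sigma_b.copy())
        np.testing.assert_array_equal(outs[0], outs[1])


class TestSigmaSEM:
    def test_identical_replicas_zero(self):
        samples = np.tile(np.random.default_rng(0).normal(size=(50, 1, 4)), (1, 3, 1))
        np.testing.assert_allclose(sem_from_window(samples), 0.0, atol=1e-12)

    def test_iid_replicas_recover_variance(self, rng):
        """i.i.d. replica values with variance v give sigma_SEM^2 ~ v/N_R."""
        v, n_rep = 4.0, 6
        samples = rng.normal(scale=np.sqrt(v), size=(2000, n_rep, 2))
        sem = sem_from_window(samples)
        # instantaneous SEM averages std estimates; correct for the ~4% bias
        # of the ddof=1 std at n=6 (Gaussian c4 factor)
        c4 = np.sqrt(2 / (n_rep - 1)) * np.exp(
            np.log(math.gamma(n_rep / 2)) - np.log(math.gamma((n_rep - 1) / 2))
        )
        expected = np.sqrt(v / n_rep) * c4
        np.testing.assert_allclose(sem, expected, rtol=0.05)

    def test_single_replica_warns_zero(self):
        with pytest.warns(UserWarning, match="replicas"):
            sem = sem_from_window(np.zeros((10, 1, 3)))
        np.testing.assert_array_equal(sem, 0.0)


class TestRMSDWall:
    def make_wall(self, ref, threshold=0.1, kappa=1e4):
        return WallSpec(
            segments=[(0, len(ref))], reference=ref, threshold=threshold, kappa=kappa
        )

    def test_identity_zero(self, rng):
        ref = rng.normal(size=(6, 3))
        e, f = rmsd_wall_energy_forces(ref.copy(), self.make_wall(ref))
        assert e == 0.0
        np.testing.assert_allclose(f, 0.0)

    def test_rigid_rotation_invariant(self, rng):
        ref = rng.normal(size=(6, 3))
        rot = Rotation.random(random_state=1).as_matrix()
        moved = ref @ rot.T + [0.3, -0.2, 1.0]
        rmsd, _ = kabsch_rmsd(moved, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rmsd_matches_scipy_alignment(self, rng):
        ref = rng.normal(size=(8, 3))
        x = ref + rng.normal(scale=0.3, size=(8, 3))
        rmsd, _ = kabsch_rmsd(x, ref)
        xc, rc = x - x.mean(0), ref - ref.mean(0)
        rot, rssd = Rotation.align_vectors(xc, rc)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(x)), abs=1e-9)

    def test_wall_forces_match_central_differences(self, rng):
        ref = rng.normal(size=(7, 3))
        x = ref + rng.normal(scale=0.2, size=(7, 3))
        wall = self.make_wall(ref, threshold=0.05)
        e, f = rmsd_wall_energy_forces(x, wall)
        assert e > 0
        h = 1e-6
        for _ in range(8):
            i, c = rng.integers(7), rng.integers(3)
            xp, xm = x.copy(), x.copy()
            xp[i, c] += h
            xm[i, c] -= h
            ep, _ = rmsd_wall_energy_forces(xp, wall)
            em, _ = rmsd_wall_energy_forces(xm, wall)
            assert -(ep - em) / (2 * h) == pytest.approx(f[i, c], abs=1e-4)

    def test_short_segment_rejected(self, rng):
        ref = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="under-determined"):
            WallSpec(segments=[(0, 2)], reference=ref)


def test_replica_average_deviation_shared():
    rs = simple_restraints([10.0])
    coords = np.array(
        [[[0.0, 0, 0], [0.9, 0, 0]], [[0.0, 0, 0], [1.1, 0, 0]]]
    )  # distances 9 and 11 A -> replica mean 10 A = target
    dev = deviations(coords, rs, "replica_average")
    np.testing.assert_allclose(dev, 0.0, atol=1e-9)
    dev_pr = deviations(coords, rs, "per_replica")
    np.testing.assert_allclose(dev_pr[:, 0], [1.0, -1.0], atol=1e-9)
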