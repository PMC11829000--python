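"""Self-contained validation experiments with analytic oracles.

Each function runs one benchmark of a pipeline component against a result
known in closed form, at a problem size that finishes in seconds to minutes
on one CPU, and returns the measured quantities.  They are used both by the
test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .cg_model import Conditions, build_topology, energy_forces
from .constants import KB
from .ensemble import WeightedEnsemble
from .analysis import scaling_exponent
from .md_engine import initialize_replicas, run_replicas, self_avoiding_walk
from .metadynamics import CVSpec, PBMetaDHook
from .metainference import (
    ErrorState,
    WallSpec,
    conditional_log_density,
    gibbs_update_errors,
    restraint_energy_forces,
    rmsd_wall_energy_forces,
)
from .restraints import RestraintSet
from .reweighting import torrie_valleau_weights

__all__ = [
    "gibbs_ks_distance",
    "thermostat_variance_ratio",
    "force_consistency_max_error",
    "double_well_fes_rms",
    "reweighted_harmonic_variance",
    "flory_exponent_fjc",
]


def gibbs_ks_distance(
    seed: int = 0,
    n_sweeps: int = 100_000,
    deviation: float = 1.0,
    sigma_sem: float = 0.2,
    shape: tuple[int, int] = (8, 16),
    sigma_prior: str = "jeffreys",
) -> tuple[float, int]:
    """KS distance between sampled sigma_B marginal and its quadrature oracle.

    All (replica, datapoint) elements share one fixed deviation, so every
    element is an independent chain targeting the same 1-D full conditional;
    pooled post-burn-in samples are compared against the normalized
    conditional computed by quadrature.  The Jeffreys-prior conditional is
    used because it is concentrated, giving the uniform +/-0.1 A random walk
    adequate mixing on this budget; the sampler code path is identical for
    both prior conventions.  Returns (KS distance, pooled sample count).
    """
    errors = ErrorState(
        sigma_b=np.full(shape, 1.0), sigma_sem=np.full(shape[1], sigma_sem)
    )
    rng = np.random.default_rng([seed, 101])
    devs = np.full(shape, deviation)
    burn_in = n_sweeps // 5
    thin = 50
    samples = []
    for sweep in range(n_sweeps):
        gibbs_update_errors(errors, devs, 300.0, rng, sigma_prior)
        if sweep >= burn_in and sweep % thin == 0:
            samples.append(errors.sigma_b.ravel().copy())
    pooled = np.sort(np.concatenate(samples))
    lo, hi = errors.bounds
    grid = np.linspace(lo, hi, 40_001)
    logp = conditional_log_density(grid, deviation, sigma_sem, sigma_prior)
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    emp = np.searchsorted(pooled, grid, side="right") / len(pooled)
    return float(np.abs(emp - cdf).max()), len(pooled)


def thermostat_variance_ratio(
    seed: int = 0,
    n_steps: int = 100_000,
    k_spring: float = 50.0,
    temperature: float = 300.0,
    n_wells: int = 128,
) -> tuple[float, int]:
    """Positional variance of thermostatted oscillators over kBT/k.

    ``n_wells`` independent beads in identical harmonic wells are integrated
    with one Langevin thermostat; the pooled coordinate variance is compared
    with the equipartition value.  Returns (ratio, pooled sample count).
    """
    masses = np.full(n_wells, 50.0)

    def pot(x):
        return 0.5 * k_spring * float((x**2).sum()), -k_spring * x

    ens = initialize_replicas(
        np.zeros((n_wells, 3)), 1, masses, temperature, seed=seed
    )
    run_replicas(
        ens, pot, masses, n_steps, save_every=40, dt=0.005, friction=2.0,
        temperature=temperature,
    )
    xs = ens.trajectory.coords[len(ens.trajectory.steps) // 4:, 0]
    return float(xs.var() / (KB * temperature / k_spring)), xs.size


def force_consistency_max_error(seed: int = 0) -> tuple[float, int]:
    """Max |analytic - central-difference| force over every energy term.

    Covers the coarse-grained force field, the metainference data term in
    both forward-model modes, the RMSD wall and the metadynamics bias.
    Returns (max abs deviation in kJ/mol/nm, number of components probed).
    """
    rng = np.random.default_rng([seed, 7])
    h = 1e-6
    worst = 0.0
    checked = 0

    # 1) CG force field on a 10-bead coil
    top = build_topology("GSEDKQNPTA", Conditions())
    x = self_avoiding_walk(10, seed=seed)

    def probe(energy_fn, coords, forces, n_probe=12):
        nonlocal worst, checked
        for _ in range(n_probe):
            idx = tuple(rng.integers(s) for s in coords.shape)
            cp, cm = coords.copy(), coords.copy()
            cp[idx] += h
            cm[idx] -= h
            num = -(energy_fn(cp) - energy_fn(cm)) / (2 * h)
            worst = max(worst, abs(num - forces[idx]))
            checked += 1

    e, f = energy_forces(x, top)
    probe(lambda c: energy_forces(c, top)[0], x, f)

    # 2) metainference data term, both forward models
    rs = RestraintSet(
        i=np.array([0, 1, 2]),
        j=np.array([5, 7, 9]),
        target=np.array([9.0, 14.0, 11.0]),
        sd=np.array([1.0, 1.5, 0.8]),
    )
    errors = ErrorState(
        sigma_b=rng.uniform(0.5, 2.0, size=(3, 3)),
        sigma_sem=rng.uniform(0.1, 0.4, size=3),
    )
    coords = np.stack([self_avoiding_walk(10, seed=seed + k) for k in range(3)])
    for mode in ("replica_average", "per_replica"):
        _, forces = restraint_energy_forces(coords, rs, errors, 300.0, mode)
        probe(
            lambda c, m=mode: restraint_energy_forces(c, rs, errors, 300.0, m)[0].sum(),
            coords,
            forces,
        )

    # 3) RMSD wall
    ref = self_avoiding_walk(8, seed=seed + 11)
    xw = ref + rng.normal(scale=0.15, size=ref.shape)
    wall = WallSpec(segments=[(0, 8)], reference=ref, threshold=0.05, kappa=1e3)
    _, fw = rmsd_wall_energy_forces(xw, wall)
    probe(lambda c: rmsd_wall_energy_forces(c, wall)[0], xw, fw)

    # 4) metadynamics combined bias
    specs = [
        CVSpec("radius_of_gyration", 0.1, 3.0, 0.0005, 0.1),
        CVSpec("inter_bead_distance", 0.0, 4.0, 0.0005, 0.1, {"i": 0, "j": 9}),
    ]
    hook = PBMetaDHook(specs, 300.0, height=0.5, bias_factor=10.0, pace=1)
    xb = self_avoiding_walk(10, seed=seed + 3)
    for _ in range(8):
        hook.on_step_end(1, xb[None] + rng.normal(scale=0.05, size=(1, 10, 3)))
    _, fb = hook.energy_forces(0, xb[None])
    probe(lambda c: hook.energy_forces(0, c)[0][0], xb[None], fb[0][None], n_probe=10)

    return worst, checked


def _double_well(h_barrier: float, r0: float, half_sep: float):
    """Pair potential U(r) = h ((r-r0)^2/b^2 - 1)^2: minima at r0 +/- b."""

    def pot(x):
        d = x[0] - x[1]
        r = float(np.linalg.norm(d))
        u = (r - r0) ** 2 / half_sep**2 - 1.0
        e = h_barrier * u**2
        dEdr = 4.0 * h_barrier * u * (r - r0) / half_sep**2
        f = np.zeros_like(x)
        unit = d / r
        f[0] = -dEdr * unit
        f[1] = dEdr * unit
        return e, f

    return pot


def double_well_fes_rms(
    seed: int = 0,
    n_steps: int = 500_000,
    temperature: float = 300.0,
    barrier_kt: float = 3.0,
    r0: float = 1.0,
    half_sep: float = 0.25,
) -> tuple[float, int]:
    """RMS deviation (in kBT) of the metadynamics free-energy estimate.

    A bead pair in a quartic double-well pair potential is sampled with
    single-CV well-tempered metadynamics on the pair distance.  The bias
    estimate F = -(1 - 1/gamma)^{-1} V is compared with the analytic profile
    F(r) = U(r) - 2 kBT ln r (the Jacobian term accounts for the radial
    volume element), over the range within 6 kBT of the minimum.  Returns
    (RMS deviation / kBT, number of compared grid points).
    """
    kT = KB * temperature
    h_barrier = barrier_kt * kT
    pot = _double_well(h_barrier, r0, half_sep)
    masses = np.full(2, 50.0)
    spec = CVSpec(
        "inter_bead_distance",
        grid_min=max(0.05, r0 - 3 * half_sep),
        grid_max=r0 + 3 * half_sep,
        grid_spacing=0.002,
        gaussian_width=0.05,
        parameters={"i": 0, "j": 1},
    )
    hook = PBMetaDHook([spec], temperature, height=0.5, bias_factor=10.0, pace=250)
    x0 = np.array([[0.0, 0.0, 0.0], [r0 - half_sep, 0.0, 0.0]])
    ens = initialize_replicas(x0, 1, masses, temperature, seed=seed)
    run_replicas(
        ens, pot, masses, n_steps, hooks=[hook], save_every=1000,
        dt=0.005, friction=2.0, temperature=temperature,
    )
    gamma = hook.bias.bias_factor
    grid = hook.bias.grids[0]
    v = hook.bias.values[0]
    f_est = -v / (1.0 - 1.0 / gamma)
    f_ana = h_barrier * ((grid - r0) ** 2 / half_sep**2 - 1.0) ** 2 - 2.0 * kT * np.log(grid)
    mask = f_ana - f_ana.min() < 6.0 * kT
    diff = (f_est - f_ana)[mask]
    diff -= diff.mean()  # profiles defined up to a constant
    return float(np.sqrt((diff**2).mean()) / kT), int(mask.sum())


def reweighted_harmonic_variance(
    seed: int = 0,
    n_steps: int = 150_000,
    k_spring: float = 50.0,
    bias_slope: float = 8.0,
    temperature: float = 300.0,
    n_wells: int = 16,
) -> tuple[float, float, float, int]:
    """Torrie-Valleau reweighting of a statically biased harmonic well.

    Beads in harmonic wells are simulated under an additional linear bias
    potential V_b = -c x; reweighting each frame by exp(+V_b/kBT) must
    recover the unbiased positional variance kBT/k.  Returns
    (reweighted variance, analytic variance, standard error, n_frames).
    """
    kT = KB * temperature
    masses = np.full(n_wells, 50.0)

    class LinearBias:
        def energy_forces(self, step, coords_all):
            e = -bias_slope * coords_all[..., 0].sum(axis=(1,))
            f = np.zeros_like(coords_all)
            f[..., 0] = bias_slope
            return e, f

    def pot(x):
        return 0.5 * k_spring * float((x**2).sum()), -k_spring * x

    ens = initialize_replicas(
        np.zeros((n_wells, 3)), 1, masses, temperature, seed=seed
    )
    run_replicas(
        ens, pot, masses, n_steps, hooks=[LinearBias()], save_every=50,
        dt=0.005, friction=2.0, temperature=temperature,
    )
    traj = ens.trajectory
    n_skip = traj.n_frames // 5
    xs = traj.coords[n_skip:, 0, :, 0]  # biased coordinate only
    # per-frame bias actually applied: V_b = -c sum_i x_i; remove per bead
    var_w = []
    for w_idx in range(n_wells):
        x = xs[:, w_idx]
        # the applied bias potential at the frame is V_b(x) = -c x
        w = torrie_valleau_weights(-bias_slope * x, temperature)
        mean = np.dot(w, x)
        var_w.append(np.dot(w, (x - mean) ** 2))
    var = float(np.mean(var_w))
    expected = kT / k_spring
    # the wells are independent repeats: take the SE from their spread,
    # which folds in autocorrelation and weight heterogeneity
    se = float(np.std(var_w, ddof=1) / np.sqrt(n_wells))
    return var, expected, se, xs.shape[0]


def flory_exponent_fjc(
    seed: int = 0, n_beads: int = 50, n_frames: int = 4000, bond: float = 0.38
) -> tuple[float, int]:
    """Scaling exponent of a directly sampled freely jointed chain.

    Independent fixed-bond-length random walks have <R_ij^2> = b^2 |i-j|
    exactly, so the fitted exponent must equal the Flory random-coil value
    nu = 0.5 up to sampling error.  Returns (nu, n_frames).
    """
    rng = np.random.default_rng([seed, 55])
    steps = rng.normal(size=(n_frames, n_beads - 1, 3))
    steps *= bond / np.linalg.norm(steps, axis=2, keepdims=True)
    coords = np.concatenate(
        [np.zeros((n_frames, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    fit = scaling_exponent(WeightedEnsemble.uniform(coords))
    return float(fit.nu), n_frames
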