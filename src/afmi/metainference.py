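"""Bayesian (metainference) distance restraints with sampled error scales.

The restraint couples the simulated ensemble to target distances d_i through a
Gaussian likelihood whose variance combines two error scales per datapoint i:
sigma^SEM_i, the standard error from estimating the forward model with a
finite number of replicas, and sigma^B_{r,i}, a per-replica scale absorbing
random and systematic errors (force field, forward model, data).  The
restraint energy is

    E_rest = (kB T / 2) * sum_{r,i} [d_i - f_i(X)]^2 /
             (sigma^B_{r,i}^2 + sigma^SEM_i^2)

plus the error-dependent normalization/prior term

    E_sigma = kB T * sum_{r,i} [ -log sigma^B_{r,i}
              + 1/2 log(sigma^B_{r,i}^2 + sigma^SEM_i^2) ].

The first term of E_sigma as written corresponds to a prior p(sigma) ~ sigma;
the conventional Jeffreys prior p(sigma) ~ 1/sigma flips its sign, which makes
the conditional posterior of sigma^B peak near the actual deviation instead of
drifting toward the upper bound and thereby keeps restraints active.  Both
conventions are available through ``sigma_prior`` ("as_printed" | "jeffreys");
pipeline profiles use "jeffreys" (see the methods note).

The forward model f_i is either the replica-averaged pair distance (default:
the maximum-entropy reading for ensemble-averaged data) or the per-replica
distance ("per_replica").  sigma^B values are sampled by a Metropolis-within-
Gibbs sweep each MD step with a uniform proposal of half-width ``move_width``
(default 0.1 A) bounded to [0.0001, 10] A; sigma^SEM is refreshed every
``sem_window`` steps (default 200) by window-averaging the instantaneous
across-replica standard error of the forward model.

Structured segments are held near their reference coordinates by a one-sided
harmonic *RMSD wall*: energy (kappa/2)(RMSD - threshold)^2 whenever the
optimal-superposition RMSD of the segment exceeds the threshold.

Internally distances and sigmas are Angstrom; coordinates are nm, and the
A <-> nm conversion happens in the force chain rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_PER_NM, KB
from .restraints import RestraintSet

__all__ = [
    "ErrorState",
    "WallSpec",
    "restraint_energy_forces",
    "error_energy",
    "gibbs_update_errors",
    "sem_from_window",
    "kabsch_rmsd",
    "rmsd_wall_energy_forces",
    "MetainferenceHook",
    "RMSDWallHook",
]

SIGMA_BOUNDS = (1e-4, 10.0)  # Angstrom, the printed sampling range
MOVE_WIDTH = 0.1  # Angstrom, the printed Gibbs trial-move perturbation


@dataclass
class ErrorState:
    """Per-replica/per-datapoint sigma_B and per-datapoint sigma_SEM (A)."""

    sigma_b: np.ndarray  # (N_R, N_D)
    sigma_sem: np.ndarray  # (N_D,)
    bounds: tuple[float, float] = SIGMA_BOUNDS
    move_width: float = MOVE_WIDTH

    def __post_init__(self) -> None:
        self.sigma_b = np.asarray(self.sigma_b, dtype=float)
        self.sigma_sem = np.asarray(self.sigma_sem, dtype=float)
        lo, hi = self.bounds
        if np.any(self.sigma_b < lo) or np.any(self.sigma_b > hi):
            raise ValueError("sigma_b outside bounds")
        if np.any(self.sigma_sem < 0):
            raise ValueError("sigma_sem must be >= 0")
        if self.sigma_b.ndim != 2 or self.sigma_sem.shape != (self.sigma_b.shape[1],):
            raise ValueError("sigma_b must be (N_R, N_D), sigma_sem (N_D,)")

    @classmethod
    def from_restraints(
        cls,
        restraints: RestraintSet,
        n_replicas: int,
        bounds: tuple[float, float] = SIGMA_BOUNDS,
        move_width: float = MOVE_WIDTH,
    ) -> "ErrorState":
        """Initialize sigma_B from the distogram spread, clamped to bounds.

        sigma_SEM starts at spread/sqrt(N_R) — the best a-priori estimate of
        the replica-mean uncertainty before any on-the-fly window estimate
        exists; starting it at zero would let early restraint forces exceed
        the integrator's stability limit.  It is zero for a single replica.
        """
        lo, hi = bounds
        sigma0 = np.clip(restraints.sd, lo, hi)
        sem0 = sigma0 / np.sqrt(n_replicas) if n_replicas > 1 else np.zeros_like(sigma0)
        return cls(
            sigma_b=np.tile(sigma0, (n_replicas, 1)),
            sigma_sem=sem0,
            bounds=bounds,
            move_width=move_width,
        )

    @property
    def variance(self) -> np.ndarray:
        """(N_R, N_D) combined variance sigma_B^2 + sigma_SEM^2."""
        return self.sigma_b**2 + self.sigma_sem[None, :] ** 2


def _pair_distances(coords_all: np.ndarray, restraints: RestraintSet):
    """Distances (N_R, N_D) in Angstrom and unit vectors (N_R, N_D, 3)."""
    diff = coords_all[:, restraints.i] - coords_all[:, restraints.j]  # nm
    r = np.linalg.norm(diff, axis=2)
    unit = diff / np.maximum(r, 1e-12)[..., None]
    return r * ANGSTROM_PER_NM, unit


def restraint_energy_forces(
    coords_all: np.ndarray,
    restraints: RestraintSet,
    errors: ErrorState,
    temperature: float,
    forward_model: str = "replica_average",
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-data energy per replica and forces on all replicas.

    In ``replica_average`` mode the forward model is the across-replica mean
    distance, so every replica feels a share of the common deviation; in
    ``per_replica`` mode each replica is restrained to the target directly.
    """
    n_rep = coords_all.shape[0]
    if errors.sigma_b.shape != (n_rep, len(restraints)):
        raise ValueError("error state dimensioned inconsistently with replicas")
    kT = KB * temperature
    d_obs, unit = _pair_distances(coords_all, restraints)  # Angstrom
    var = errors.variance  # (R, D) A^2
    target = restraints.target[None, :]
    forces = np.zeros_like(coords_all)
    if forward_model == "replica_average":
        f = d_obs.mean(axis=0, keepdims=True)  # (1, D)
        dev = target - f  # (1, D)
        energy_terms = 0.5 * kT * dev**2 / var  # (R, D)
        # dE/df_i = -kT dev_i * sum_r 1/var_{r,i}; df_i/dx_r = unit_r / N_R (A/nm *10)
        dEdf = -kT * dev[0] * (1.0 / var).sum(axis=0)  # (D,)
        coeff = (dEdf / n_rep * ANGSTROM_PER_NM)[None, :, None] * unit
    elif forward_model == "per_replica":
        dev = target - d_obs  # (R, D)
        energy_terms = 0.5 * kT * dev**2 / var
        dEdd = -kT * dev / var  # (R, D)
        coeff = (dEdd * ANGSTROM_PER_NM)[..., None] * unit
    else:
        raise ValueError(f"unknown forward_model '{forward_model}'")
    np.add.at(forces, (slice(None), restraints.i), -coeff)
    np.add.at(forces, (slice(None), restraints.j), coeff)
    return energy_terms.sum(axis=1), forces


def deviations(
    coords_all: np.ndarray,
    restraints: RestraintSet,
    forward_model: str = "replica_average",
) -> np.ndarray:
    """Current (N_R, N_D) deviations d_i - f_i entering the Gibbs conditional."""
    d_obs, _ = _pair_distances(coords_all, restraints)
    if forward_model == "replica_average":
        f = d_obs.mean(axis=0, keepdims=True)
        return np.broadcast_to(restraints.target[None, :] - f, d_obs.shape).copy()
    return restraints.target[None, :] - d_obs


def _sigma_energy_terms(
    sigma_b: np.ndarray, sigma_sem: np.ndarray, sigma_prior: str
) -> np.ndarray:
    """Per-element E_sigma / kT."""
    var = sigma_b**2 + np.asarray(sigma_sem)[None, :] ** 2
    log_sigma = np.log(sigma_b)
    prior = -log_sigma if sigma_prior == "as_printed" else log_sigma
    if sigma_prior not in ("as_printed", "jeffreys"):
        raise ValueError(f"unknown sigma_prior '{sigma_prior}'")
    return prior + 0.5 * np.log(var)


def error_energy(
    errors: ErrorState, temperature: float, sigma_prior: str = "as_printed"
) -> float:
    """Error-normalization energy E_sigma (kJ/mol)."""
    kT = KB * temperature
    return float(
        kT * _sigma_energy_terms(errors.sigma_b, errors.sigma_sem, sigma_prior).sum()
    )


def conditional_log_density(
    sigma: np.ndarray,
    deviation: float,
    sigma_sem: float,
    sigma_prior: str = "as_printed",
) -> np.ndarray:
    """Unnormalized log full-conditional of one sigma_B (temperature cancels).

    Used by the Gibbs sampler's acceptance rule and by quadrature oracles.
    """
    sigma = np.asarray(sigma, dtype=float)
    var = sigma**2 + sigma_sem**2
    prior = -np.log(sigma) if sigma_prior == "as_printed" else np.log(sigma)
    return -(0.5 * deviation**2 / var + prior + 0.5 * np.log(var))


def gibbs_update_errors(
    errors: ErrorState,
    devs: np.ndarray,
    temperature: float,
    rng: np.random.Generator,
    sigma_prior: str = "as_printed",
) -> ErrorState:
    """One Metropolis-within-Gibbs sweep over all (replica, datapoint) sigmas.

    Uniform proposal sigma' = sigma +/- U(0, move_width); proposals outside the
    bounds are rejected outright, so no out-of-bounds value is ever stored.
    sigma_SEM is held fixed during the sweep.  In-place update; the (possibly
    shared) ErrorState is returned for convenience.
    """
    devs = np.asarray(devs, dtype=float)
    if devs.shape != errors.sigma_b.shape:
        raise ValueError("deviations dimensioned inconsistently with sigma_b")
    lo, hi = errors.bounds
    sigma = errors.sigma_b
    prop = sigma + rng.uniform(-errors.move_width, errors.move_width, size=sigma.shape)
    in_bounds = (prop >= lo) & (prop <= hi)
    sem = errors.sigma_sem[None, :]

    def logp(s):
        var = s**2 + sem**2
        prior = -np.log(s) if sigma_prior == "as_printed" else np.log(s)
        return -(0.5 * devs**2 / var + prior + 0.5 * np.log(var))

    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(in_bounds, logp(np.where(in_bounds, prop, 1.0)) - logp(sigma), -np.inf)
    accept = np.log(rng.uniform(size=sigma.shape)) < delta
    errors.sigma_b = np.where(accept & in_bounds, prop, sigma)
    return errors


def sem_from_window(samples: np.ndarray) -> np.ndarray:
    """sigma_SEM per datapoint from a window of forward-model values.

    ``samples`` has shape (window, N_R, N_D).  The instantaneous standard
    error of the replica mean, std_r(f)/sqrt(N_R), is averaged over the
    window.  With a single replica the estimate is zero (with a warning).
    """
    samples = np.asarray(samples, dtype=float)
    w, n_rep, _ = samples.shape
    if n_rep < 2:
        warnings.warn(
            "sigma_SEM requires >= 2 replicas; returning zeros", stacklevel=2
        )
        return np.zeros(samples.shape[2])
    inst = samples.std(axis=1, ddof=1) / np.sqrt(n_rep)  # (window, N_D)
    return inst.mean(axis=0)


# ---------------------------------------------------------------------------
# RMSD wall
# ---------------------------------------------------------------------------


@dataclass
class WallSpec:
    """Reference coordinates and wall parameters for structured segments."""

    segments: list[tuple[int, int]]  # half-open bead ranges
    reference: np.ndarray  # (N, 3) nm, full-chain reference
    threshold: float = 0.1  # nm
    kappa: float = 1e4  # kJ/mol/nm^2

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("wall threshold must be positive")
        for start, stop in self.segments:
            if stop - start < 3:
                raise ValueError(
                    "segment shorter than 3 beads: superposition under-determined"
                )


def kabsch_rmsd(x: np.ndarray, ref: np.ndarray) -> tuple[float, np.ndarray]:
    """Least RMSD after optimal superposition, and the fitted reference.

    Returns (rmsd, ref_fit) where ``ref_fit`` is the reference rotated and
    translated onto ``x``.
    """
    xc = x - x.mean(axis=0)
    yc = ref - ref.mean(axis=0)
    h = yc.T @ xc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    y_fit = yc @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((xc - y_fit) ** 2, axis=1))))
    return rmsd, y_fit + x.mean(axis=0)


def rmsd_wall_energy_forces(
    coords: np.ndarray, wall: WallSpec
) -> tuple[float, np.ndarray]:
    """One-sided harmonic wall on per-segment superposition RMSD.

    The gradient goes through the optimal superposition; rotation and
    translation derivatives vanish at the optimum (envelope theorem), leaving
    dRMSD/dx_k = (x_k - y_fit_k) / (n RMSD).
    """
    if not wall.segments:
        raise ValueError("wall requires at least one segment")
    energy = 0.0
    forces = np.zeros_like(coords)
    for start, stop in wall.segments:
        seg = coords[start:stop]
        ref = wall.reference[start:stop]
        rmsd, ref_fit = kabsch_rmsd(seg, ref)
        if rmsd > wall.threshold:
            excess = rmsd - wall.threshold
            energy += 0.5 * wall.kappa * excess**2
            n = stop - start
            grad = wall.kappa * excess * (seg - ref_fit) / (n * max(rmsd, 1e-12))
            forces[start:stop] -= grad
    return float(energy), forces


# ---------------------------------------------------------------------------
# Engine hooks
# ---------------------------------------------------------------------------


class MetainferenceHook:
    """Engine hook bundling restraint forces, Gibbs error moves and SEM updates."""

    def __init__(
        self,
        restraints: RestraintSet,
        n_replicas: int,
        temperature: float,
        forward_model: str = "replica_average",
        sigma_prior: str = "jeffreys",
        sem_window: int = 200,
        bounds: tuple[float, float] = SIGMA_BOUNDS,
        move_width: float = MOVE_WIDTH,
        seed: int = 0,
    ):
        self.restraints = restraints
        self.errors = ErrorState.from_restraints(
            restraints, n_replicas, bounds=bounds, move_width=move_width
        )
        self.temperature = temperature
        self.forward_model = forward_model
        self.sigma_prior = sigma_prior
        self.sem_window = sem_window
        self.rng = np.random.default_rng([seed, 9173])
        self._sem_buffer: list[np.ndarray] = []
        self._warmed_up = False

    def _warm_up(self, coords_all: np.ndarray, n_sweeps: int = 300) -> None:
        """Equilibrate sigma_B to the starting structure's deviations.

        Without this, a start far from the targets meets the (small) initial
        distogram spreads and the first restraint forces can exceed the
        integrator's stability limit; sampling the error conditional first
        is the Bayesian statement that the initial residuals are error, not
        signal.
        """
        devs = deviations(coords_all, self.restraints, self.forward_model)
        for _ in range(n_sweeps):
            gibbs_update_errors(
                self.errors, devs, self.temperature, self.rng, self.sigma_prior
            )
        self._warmed_up = True

    def energy_forces(self, step: int, coords_all: np.ndarray):
        if not self._warmed_up:
            self._warm_up(coords_all)
        e_data, forces = restraint_energy_forces(
            coords_all,
            self.restraints,
            self.errors,
            self.temperature,
            forward_model=self.forward_model,
        )
        e_sigma = error_energy(self.errors, self.temperature, self.sigma_prior)
        return e_data + e_sigma / len(e_data), forces

    def on_step_end(self, step: int, coords_all: np.ndarray) -> None:
        d_obs, _ = _pair_distances(coords_all, self.restraints)
        self._sem_buffer.append(d_obs)
        if len(self._sem_buffer) >= self.sem_window:
            if coords_all.shape[0] >= 2:
                self.errors.sigma_sem = sem_from_window(np.array(self._sem_buffer))
            self._sem_buffer.clear()
        devs = deviations(coords_all, self.restraints, self.forward_model)
        gibbs_update_errors(
            self.errors, devs, self.temperature, self.rng, self.sigma_prior
        )


class RMSDWallHook:
    """Engine hook applying the structured-segment RMSD wall per replica."""

    def __init__(self, wall: WallSpec):
        self.wall = wall

    def energy_forces(self, step: int, coords_all: np.ndarray):
        n_rep = coords_all.shape[0]
        energies = np.zeros(n_rep)
        forces = np.zeros_like(coords_all)
        for r in range(n_rep):
            energies[r], forces[r] = rmsd_wall_energy_forces(coords_all[r], self.wall)
        return energies, forces
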