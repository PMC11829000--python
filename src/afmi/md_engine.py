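"""Multi-replica NVT Langevin dynamics with energy/force hooks.

The integrator is the BAOAB splitting of Langevin dynamics (kick - drift -
Ornstein-Uhlenbeck - drift - kick), which gives accurate configurational
sampling at large time steps and reduces to velocity Verlet when the friction
is zero (NVE test mode).  Defaults follow the production protocol: 5 fs time
step and 0.01 ps^-1 friction.

Replicas advance in lockstep so that *hooks* — additional energy/force
contributors such as the metainference restraint or a metadynamics bias — can
see a consistent snapshot of all replica coordinates at every step.  A hook is
any object with

``energy_forces(step, coords_all) -> (energy_per_replica, forces_all)``

and optionally ``on_step_end(step, coords_all)`` (for Gibbs error moves, SEM
refreshes, hill deposition) and ``cv_values(coords_all)`` (recorded in the
trajectory).  Everything is deterministic given the seed in serial mode; the
replica id is folded into the per-replica noise stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import KB

__all__ = [
    "ReplicaState",
    "Trajectory",
    "ReplicaEnsemble",
    "minimize",
    "langevin_step",
    "run_replicas",
    "initialize_replicas",
    "instantaneous_temperature",
    "self_avoiding_walk",
]

Potential = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class ReplicaState:
    coords: np.ndarray  # (N, 3) nm
    velocities: np.ndarray  # (N, 3) nm/ps
    replica_id: int = 0
    rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        self.coords = np.array(self.coords, dtype=float)
        self.velocities = np.array(self.velocities, dtype=float)
        if self.coords.shape != self.velocities.shape:
            raise ValueError("coords/velocities shape mismatch")
        if not (np.all(np.isfinite(self.coords)) and np.all(np.isfinite(self.velocities))):
            raise ValueError("non-finite replica state")


@dataclass
class Trajectory:
    """Per-frame record of a multi-replica run."""

    coords: np.ndarray  # (n_frames, n_replicas, N, 3)
    steps: np.ndarray  # (n_frames,)
    potential_energy: np.ndarray  # (n_frames, n_replicas)
    kinetic_energy: np.ndarray  # (n_frames, n_replicas)
    hook_energies: dict[str, np.ndarray] = field(default_factory=dict)
    cvs: dict[str, np.ndarray] = field(default_factory=dict)  # (n_frames, n_replicas, n_cv)

    @property
    def n_frames(self) -> int:
        return len(self.steps)


@dataclass
class ReplicaEnsemble:
    replicas: list[ReplicaState]
    step: int = 0
    trajectory: Trajectory | None = None

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def coords_all(self) -> np.ndarray:
        return np.stack([r.coords for r in self.replicas])


def self_avoiding_walk(
    n_beads: int,
    bond_length: float = 0.38,
    min_dist: float = 0.40,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random chain at fixed bond length avoiding close contacts (nm)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.zeros((n_beads, 3))
    for k in range(1, n_beads):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= bond_length / np.linalg.norm(step)
            cand = coords[k - 1] + step
            if k < 2 or np.min(np.linalg.norm(coords[: k - 1] - cand, axis=1)) > min_dist:
                coords[k] = cand
                break
        else:  # fall back to a straight continuation
            coords[k] = coords[k - 1] + [bond_length, 0.0, 0.0]
    return coords


def confined_walk(
    n_beads: int,
    bond_length: float = 0.38,
    radius: float | None = None,
    min_dist: float = 0.35,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random chain at fixed bond length confined to a sphere (nm).

    Produces a compact, globule-like starting configuration; the default
    radius scales as the dense-packing radius of ``n_beads`` beads.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if radius is None:
        radius = 0.13 * n_beads ** (1.0 / 3.0) / 0.31 + 0.2  # ~dense packing
    coords = np.zeros((n_beads, 3))
    for k in range(1, n_beads):
        placed = False
        dmin = min_dist
        for attempt in range(400):
            if attempt and attempt % 100 == 0:
                dmin *= 0.9  # relax gradually; minimization cleans up
            step = rng.normal(size=3)
            step *= bond_length / np.linalg.norm(step)
            cand = coords[k - 1] + step
            if np.linalg.norm(cand) > radius:
                continue
            if k < 2 or np.min(np.linalg.norm(coords[: k - 1] - cand, axis=1)) > dmin:
                coords[k] = cand
                placed = True
                break
        if not placed:
            coords[k] = coords[k - 1] + step
    return coords


def initialize_replicas(
    coords0: np.ndarray,
    n_replicas: int,
    masses: np.ndarray,
    temperature: float,
    seed: int = 0,
    jitter: float = 0.0,
) -> ReplicaEnsemble:
    """Replicas at common coordinates with Maxwell-Boltzmann velocities.

    Each replica's RNG is seeded from ``(seed, replica_id)`` so identical seeds
    with different ids give independent noise streams.  ``jitter`` adds a small
    Gaussian displacement (nm) to decorrelate starting points.
    """
    masses = np.asarray(masses, dtype=float)
    replicas = []
    for rid in range(n_replicas):
        rng = np.random.default_rng([seed, rid])
        sigma_v = np.sqrt(KB * temperature / masses)[:, None]
        vel = rng.normal(size=(len(masses), 3)) * sigma_v
        x = np.array(coords0, dtype=float)
        if jitter > 0:
            x = x + rng.normal(scale=jitter, size=x.shape)
        replicas.append(ReplicaState(coords=x, velocities=vel, replica_id=rid, rng=rng))
    return ReplicaEnsemble(replicas=replicas)


def minimize(
    state: ReplicaState | np.ndarray,
    potential: Potential,
    max_steps: int = 100,
    initial_step: float = 1e-3,
    tol: float = 1e-8,
):
    """Steepest-descent minimization with a backtracking step size.

    Energy is non-increasing over accepted moves; at most ``max_steps`` moves
    are attempted (the production protocol uses a short 100-step
    minimization).  Returns the same type as its input.
    """
    is_state = isinstance(state, ReplicaState)
    x = np.array(state.coords if is_state else state, dtype=float)
    energy, forces = potential(x)
    if not np.isfinite(energy):
        raise ValueError("non-finite energy at minimization input")
    step = initial_step
    for _ in range(max_steps):
        fmax = np.abs(forces).max()
        if fmax < tol:
            break
        direction = forces / fmax  # displacement capped at `step` nm per bead
        accepted = False
        for _ in range(20):
            x_new = x + step * direction
            e_new, f_new = potential(x_new)
            if np.isfinite(e_new) and e_new <= energy:
                x, energy, forces = x_new, e_new, f_new
                step = min(step * 1.2, 0.05)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    if is_state:
        return ReplicaState(
            coords=x,
            velocities=state.velocities,
            replica_id=state.replica_id,
            rng=state.rng,
        )
    return x


class _BAOAB:
    """Precomputed BAOAB coefficients for fixed masses/dt/friction/T."""

    def __init__(self, masses: np.ndarray, dt: float, friction: float, temperature: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = dt
        self.masses = np.asarray(masses, dtype=float)[:, None]
        self.c1 = np.exp(-friction * dt)
        self.c2 = np.sqrt(max(0.0, 1.0 - self.c1**2))
        self.sigma_v = np.sqrt(KB * temperature / self.masses)

    def step(self, x, v, forces, rng, potential):
        half = 0.5 * self.dt
        v = v + half * forces / self.masses
        x = x + half * v
        if self.c2 > 0:
            v = self.c1 * v + self.c2 * self.sigma_v * rng.normal(size=v.shape)
        else:
            v = self.c1 * v
        x = x + half * v
        energy, forces = potential(x)
        if not np.all(np.isfinite(forces)):
            raise FloatingPointError("non-finite forces during integration")
        v = v + half * forces / self.masses
        return x, v, forces, energy


def langevin_step(
    state: ReplicaState,
    potential: Potential,
    masses: np.ndarray,
    dt: float = 0.005,
    friction: float = 0.01,
    temperature: float = 298.0,
) -> ReplicaState:
    """One BAOAB Langevin update of a single replica (deterministic per rng)."""
    integ = _BAOAB(masses, dt, friction, temperature)
    rng = state.rng or np.random.default_rng(0)
    _, forces = potential(state.coords)
    x, v, _, _ = integ.step(state.coords, state.velocities, forces, rng, potential)
    return ReplicaState(coords=x, velocities=v, replica_id=state.replica_id, rng=rng)


def instantaneous_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic temperature 2 KE / (3 N kB)."""
    ke = 0.5 * float((np.asarray(masses)[:, None] * velocities**2).sum())
    ndof = 3 * len(masses)
    return 2.0 * ke / (ndof * KB)


def run_replicas(
    ensemble: ReplicaEnsemble,
    potential: Potential,
    masses: np.ndarray,
    n_steps: int,
    hooks: Sequence = (),
    save_every: int = 1000,
    dt: float = 0.005,
    friction: float = 0.01,
    temperature: float = 298.0,
) -> ReplicaEnsemble:
    """Advance all replicas ``n_steps`` with hook contributions.

    Hooks are called synchronously once per step with the full (R, N, 3)
    coordinate snapshot.  Frames (including the initial one) are recorded
    every ``save_every`` steps together with per-hook energies and CV values.
    The run is reproducible per replica seed.
    """
    n_rep = ensemble.n_replicas
    masses = np.asarray(masses, dtype=float)
    integ = _BAOAB(masses, dt, friction, temperature)
    coords_all = ensemble.coords_all()
    vel_all = np.stack([r.velocities for r in ensemble.replicas])

    def total_forces(x_all: np.ndarray, step: int):
        e_pot = np.empty(n_rep)
        f_all = np.empty_like(x_all)
        for r in range(n_rep):
            e_pot[r], f_all[r] = potential(x_all[r])
        hook_e = {}
        for hook in hooks:
            try:
                eh, fh = hook.energy_forces(step, x_all)
            except Exception as exc:  # pragma: no cover - context for debugging
                raise RuntimeError(
                    f"hook {type(hook).__name__} failed at step {step}"
                ) from exc
            hook_e[type(hook).__name__] = np.asarray(eh, dtype=float)
            f_all = f_all + fh
        return e_pot, f_all, hook_e

    e_pot, f_all, hook_e = total_forces(coords_all, ensemble.step)

    frames, steps, epots, ekins = [], [], [], []
    hook_series: dict[str, list] = {}
    cv_series: dict[str, list] = {}

    def record(step):
        frames.append(coords_all.copy())
        steps.append(step)
        epots.append(e_pot.copy())
        ekins.append(
            [0.5 * float((masses[:, None] * vel_all[r] ** 2).sum()) for r in range(n_rep)]
        )
        for name, e in hook_e.items():
            hook_series.setdefault(name, []).append(np.array(e))
        for hook in hooks:
            if hasattr(hook, "cv_values"):
                cv_series.setdefault(type(hook).__name__, []).append(
                    np.asarray(hook.cv_values(coords_all), dtype=float)
                )

    record(ensemble.step)
    half = 0.5 * dt
    m = masses[:, None]
    for k in range(1, n_steps + 1):
        step = ensemble.step + k
        # B A O A (per replica; per-replica RNG preserves stream independence)
        vel_all += half * f_all / m
        coords_all += half * vel_all
        if integ.c2 > 0:
            for r in range(n_rep):
                vel_all[r] = integ.c1 * vel_all[r] + integ.c2 * integ.sigma_v * (
                    ensemble.replicas[r].rng.normal(size=vel_all[r].shape)
                )
        else:
            vel_all *= integ.c1
        coords_all += half * vel_all
        # B with fresh forces (cg potential + hooks)
        e_pot, f_all, hook_e = total_forces(coords_all, step)
        vel_all += half * f_all / m
        for hook in hooks:
            if hasattr(hook, "on_step_end"):
                hook.on_step_end(step, coords_all)
        if step % save_every == 0:
            record(step)

    for r in range(n_rep):
        ensemble.replicas[r].coords = coords_all[r]
        ensemble.replicas[r].velocities = vel_all[r]
    ensemble.step += n_steps
    ensemble.trajectory = Trajectory(
        coords=np.array(frames),
        steps=np.array(steps),
        potential_energy=np.array(epots),
        kinetic_energy=np.array(ekins),
        hook_energies={k: np.array(v) for k, v in hook_series.items()},
        cvs={k: np.array(v) for k, v in cv_series.items()},
    )
    return ensemble
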