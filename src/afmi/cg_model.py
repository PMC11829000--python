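"""One-bead-per-residue coarse-grained force field (CALVADOS-2 functional forms).

The chain energy is

.. math::

    E_{MD} = \\sum_{bonds} \\tfrac{k}{2}(r - r_0)^2
           + \\sum_{i<j} E^{AH}_{ij}(r)
           + \\sum_{i<j} \\frac{q_i q_j e^2}{4\\pi\\varepsilon_0
             \\varepsilon_r(T)\\, r} e^{-r/\\lambda_D},

where the short-range term is the Ashbaugh-Hatch "stickiness"-scaled
Lennard-Jones potential

.. math::

    E^{AH}_{ij}(r) = \\begin{cases}
      LJ(r; \\sigma_{ij}, \\epsilon) + (1 - \\lambda_{ij})\\epsilon
        & r \\le 2^{1/6}\\sigma_{ij} \\\\
      \\lambda_{ij}\\, LJ(r; \\sigma_{ij}, \\epsilon) & r > 2^{1/6}\\sigma_{ij}
    \\end{cases}

with arithmetic-mean combination rules for sigma and lambda.  Both nonbonded
terms are truncated and shifted to zero at their cutoffs (2.4 nm and 4.0 nm by
default) so the energy is continuous in the coordinates, which matters for
Langevin stability.  Bonded neighbours are excluded from the nonbonded sums.

Residue parameters (sigma, stickiness lambda, charge, mass) ship as a
versioned JSON data file; histidine charge and, optionally, the termini
charges are resolved at construction time from the pH via
Henderson-Hasselbalch.  Units: nm, kJ/mol, amu, elementary charges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .constants import COULOMB, KB

__all__ = [
    "Conditions",
    "ResidueParams",
    "Topology",
    "load_params_table",
    "build_topology",
    "energy_forces",
    "debye_parameters",
    "make_potential",
    "OverlapError",
]

#: Hard floor (nm) below which a nonbonded pair distance is considered an
#: unphysical overlap; energy evaluation then fails, advising minimization.
HARD_FLOOR_NM = 0.01


class OverlapError(ValueError):
    pass


def _build_nonbonded_kernel():
    """JIT-compiled pair kernel (numba), or None if numba is unavailable.

    Purely an acceleration of the numpy path below; both are exercised by the
    test suite and must agree to floating-point roundoff.
    """
    try:
        from numba import njit
    except ImportError:  # pragma: no cover
        return None

    @njit(cache=True, fastmath=False)
    def kernel(x, iu, ju, sig6, lam, qq, eps, rc_ah, ah_shift, rmin_sq,
               pref, inv_lam_d, rc_dh, dh_shift, floor_sq, forces):
        e_ah = 0.0
        e_dh = 0.0
        min_rsq = 1e30
        for p in range(len(iu)):
            i, j = iu[p], ju[p]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            rsq = dx * dx + dy * dy + dz * dz
            if rsq < min_rsq:
                min_rsq = rsq
            if rsq < floor_sq:
                rsq = floor_sq
            r = np.sqrt(rsq)
            dEdr = 0.0
            if r < rc_ah:
                sr6 = sig6[p] / (rsq * rsq * rsq)
                lj = 4.0 * eps * (sr6 * sr6 - sr6)
                dlj = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
                if rsq <= rmin_sq[p]:
                    e_ah += lj + (1.0 - lam[p]) * eps - ah_shift[p]
                    dEdr = dlj
                else:
                    e_ah += lam[p] * lj - ah_shift[p]
                    dEdr = lam[p] * dlj
            if qq[p] != 0.0 and r < rc_dh:
                edh = pref * qq[p] / r * np.exp(-r * inv_lam_d)
                e_dh += edh - dh_shift * qq[p]
                dEdr -= edh * (1.0 / r + inv_lam_d)
            c = -dEdr / r
            fx, fy, fz = c * dx, c * dy, c * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
        return e_ah, e_dh, min_rsq

    return kernel


_NONBONDED_KERNEL = _build_nonbonded_kernel()


@dataclass(frozen=True)
class ResidueParams:
    name: str
    sigma: float  # nm
    stickiness: float  # lambda, dimensionless
    charge: float  # e, at neutral pH before His/termini resolution
    mass: float  # amu


@dataclass(frozen=True)
class Conditions:
    """Solution conditions of a simulation."""

    temperature: float = 298.0  # K
    pH: float = 7.0
    ionic_strength: float = 0.15  # mol/L

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")

    @property
    def kT(self) -> float:
        return KB * self.temperature


def load_params_table(path=None) -> dict:
    """Load the residue-parameter table (the shipped file by default)."""
    if path is None:
        with resources.files("afmi.data").joinpath("calvados2.json").open() as fh:
            return json.load(fh)
    with open(path) as fh:
        return json.load(fh)


def water_permittivity(temperature: float) -> float:
    """Empirical relative permittivity of water as a function of T (K)."""
    t = temperature
    return 5321.0 / t + 233.76 - 0.9297 * t + 1.4178e-3 * t**2 - 8.292e-7 * t**3


def debye_parameters(conditions: Conditions) -> tuple[float, float]:
    """Debye screening length (nm) and Coulomb prefactor (kJ/mol nm e^-2).

    The screening length follows the standard closed form
    ``lambda_D = sqrt(eps0 epsr kB T / (2 NA e^2 I))`` with the
    temperature-dependent permittivity of water; at 0.15 M and 298 K it is
    about 0.79 nm.
    """
    if conditions.ionic_strength <= 0:
        raise ValueError(
            "ionic_strength must be positive for screened electrostatics; "
            "disable charges (e.g. charged_termini=False and a neutral "
            "sequence) for a no-electrostatics model"
        )
    eps_r = water_permittivity(conditions.temperature)
    bjerrum = COULOMB / (eps_r * KB * conditions.temperature)  # nm
    # ion number density in nm^-3 for a 1:1 electrolyte of molarity I
    rho = 0.6022140760 * conditions.ionic_strength
    kappa_sq = 8.0 * np.pi * bjerrum * rho
    return 1.0 / np.sqrt(kappa_sq), COULOMB / eps_r


@dataclass
class Topology:
    """Parameterized chain: per-bead parameters and interaction constants."""

    sequence: str
    sigma: np.ndarray  # (N,) nm
    stickiness: np.ndarray  # (N,)
    charge: np.ndarray  # (N,) e, pH-resolved
    mass: np.ndarray  # (N,) amu
    bond_k: float  # kJ/mol/nm^2
    bond_r0: float  # nm
    epsilon: float  # kJ/mol, AH energy scale
    cutoff_ah: float  # nm
    cutoff_dh: float  # nm
    debye_length: float  # nm
    coulomb_prefactor: float  # kJ/mol nm e^-2 (already includes eps_r)
    conditions: Conditions = field(default_factory=Conditions)

    @property
    def n_beads(self) -> int:
        return len(self.sequence)

    @property
    def bonds(self) -> np.ndarray:
        n = self.n_beads
        return np.column_stack([np.arange(n - 1), np.arange(1, n)])

    @property
    def pair_cache(self) -> dict:
        """Precomputed nonbonded pair lists and combined parameters."""
        cache = getattr(self, "_pair_cache", None)
        if cache is None:
            n = self.n_beads
            iu, ju = np.triu_indices(n, k=2)
            sig = 0.5 * (self.sigma[iu] + self.sigma[ju])
            lam = 0.5 * (self.stickiness[iu] + self.stickiness[ju])
            qq = self.charge[iu] * self.charge[ju]
            rc = self.cutoff_ah
            src6 = (sig / rc) ** 6
            cache = {
                "iu": iu,
                "ju": ju,
                "sig6": sig**6,
                "lam": lam,
                "qq": qq,
                "any_charge": bool(np.any(qq != 0.0)),
                "ah_shift": lam * 4.0 * self.epsilon * (src6**2 - src6),
                "rmin_sq": (2.0 ** (1.0 / 3.0)) * sig**2,
            }
            object.__setattr__(self, "_pair_cache", cache)
        return cache


def build_topology(
    sequence: str,
    conditions: Conditions | None = None,
    params_table: dict | None = None,
    charged_termini: bool = True,
) -> Topology:
    """Resolve a sequence into a parameterized topology at given conditions.

    Histidine charge comes from Henderson-Hasselbalch at the table's pKa;
    termini add +1/-1 e to the first/last bead when ``charged_termini``.
    """
    conditions = conditions or Conditions()
    table = params_table or load_params_table()
    residues = table["residues"]
    unknown = sorted(set(sequence) - set(residues))
    if unknown:
        raise KeyError(f"unknown residue code(s): {unknown}")
    n = len(sequence)
    sigma = np.array([residues[aa]["sigma_nm"] for aa in sequence])
    lam = np.array([residues[aa]["lambda"] for aa in sequence])
    charge = np.array([residues[aa]["charge"] for aa in sequence], dtype=float)
    mass = np.array([residues[aa]["mass_amu"] for aa in sequence])
    his_charge = 1.0 / (1.0 + 10.0 ** (conditions.pH - table["histidine_pka"]))
    for k, aa in enumerate(sequence):
        if aa == "H":
            charge[k] = his_charge
    if charged_termini and n >= 1:
        charge[0] += 1.0
        charge[-1] -= 1.0
    if conditions.ionic_strength > 0 and np.any(charge != 0):
        debye_len, prefactor = debye_parameters(conditions)
    else:
        debye_len, prefactor = np.inf, 0.0
    return Topology(
        sequence=sequence,
        sigma=sigma,
        stickiness=lam,
        charge=charge,
        mass=mass,
        bond_k=table["bond_k_kj_mol_nm2"],
        bond_r0=table["bond_r0_nm"],
        epsilon=table["epsilon_kj_mol"],
        cutoff_ah=table["cutoff_ah_nm"],
        cutoff_dh=table["cutoff_dh_nm"],
        debye_length=debye_len,
        coulomb_prefactor=prefactor,
        conditions=conditions,
    )


def energy_forces(
    coords: np.ndarray,
    topology: Topology,
    return_components: bool = False,
    overlap_floor: float | None = HARD_FLOOR_NM,
):
    """Potential energy (kJ/mol) and analytic forces (kJ/mol/nm).

    Nonbonded distances below ``overlap_floor`` raise :class:`OverlapError`
    advising a prior minimization; with ``overlap_floor=None`` distances are
    instead clamped at the hard floor (finite, very large energy), which is
    what the minimizer uses to escape overlaps.
    """
    x = np.asarray(coords, dtype=float)
    n = topology.n_beads
    if x.shape != (n, 3):
        raise ValueError(f"coords shape {x.shape} != ({n}, 3)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    if n < 2:
        raise ValueError("need at least two beads")

    forces = np.zeros_like(x)

    # bonds
    bvec = x[1:] - x[:-1]
    blen = np.linalg.norm(bvec, axis=1)
    blen_safe = np.maximum(blen, 1e-12)
    e_bond = 0.5 * topology.bond_k * ((blen - topology.bond_r0) ** 2).sum()
    fb = (topology.bond_k * (blen - topology.bond_r0) / blen_safe)[:, None] * bvec
    forces[:-1] += fb
    forces[1:] -= fb

    # nonbonded pairs: all i<j with j > i+1 (bonded neighbours excluded)
    cache = topology.pair_cache
    iu, ju = cache["iu"], cache["ju"]
    e_ah = 0.0
    e_dh = 0.0
    if len(iu) and _NONBONDED_KERNEL is not None:
        use_dh = topology.coulomb_prefactor != 0.0 and cache["any_charge"]
        qq = cache["qq"] if use_dh else np.zeros_like(cache["qq"])
        inv_lam_d = 0.0 if np.isinf(topology.debye_length) else 1.0 / topology.debye_length
        dh_shift = (
            topology.coulomb_prefactor
            / topology.cutoff_dh
            * np.exp(-topology.cutoff_dh * inv_lam_d)
            if use_dh
            else 0.0
        )
        e_ah, e_dh, min_rsq = _NONBONDED_KERNEL(
            x, iu, ju, cache["sig6"], cache["lam"], qq,
            topology.epsilon, topology.cutoff_ah, cache["ah_shift"],
            cache["rmin_sq"], topology.coulomb_prefactor, inv_lam_d,
            topology.cutoff_dh, dh_shift, HARD_FLOOR_NM**2, forces,
        )
        if overlap_floor is not None and min_rsq < overlap_floor**2:
            raise OverlapError(
                "bead overlap below the hard floor; run a short energy "
                "minimization before dynamics"
            )
    elif len(iu):
        rij = x[iu] - x[ju]
        r_sq = (rij * rij).sum(axis=1)
        if overlap_floor is not None and np.any(r_sq < overlap_floor**2):
            raise OverlapError(
                "bead overlap below the hard floor; run a short energy "
                "minimization before dynamics"
            )
        r_sq = np.maximum(r_sq, HARD_FLOOR_NM**2)
        r = np.sqrt(r_sq)

        # Ashbaugh-Hatch, truncated-shifted at the cutoff
        eps = topology.epsilon
        lam = cache["lam"]
        sr6 = cache["sig6"] / (r_sq * r_sq * r_sq)
        lj = 4.0 * eps * (sr6 * sr6 - sr6)
        dlj = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        inner = r_sq <= cache["rmin_sq"]
        e_pair = np.where(inner, lj + (1.0 - lam) * eps, lam * lj)
        dEdr = np.where(inner, dlj, lam * dlj)
        inside_ah = r < topology.cutoff_ah
        e_ah = float(((e_pair - cache["ah_shift"]) * inside_ah).sum())
        dEdr = dEdr * inside_ah

        if topology.coulomb_prefactor != 0.0 and cache["any_charge"]:
            rc = topology.cutoff_dh
            lam_d = topology.debye_length
            qq = cache["qq"]
            edh = topology.coulomb_prefactor * qq / r * np.exp(-r / lam_d)
            shift = topology.coulomb_prefactor * qq / rc * np.exp(-rc / lam_d)
            inside = r < rc
            e_dh = float(((edh - shift) * inside).sum())
            dEdr = dEdr - edh * (1.0 / r + 1.0 / lam_d) * inside

        coeff = -dEdr / r
        fpair = coeff[:, None] * rij
        for c in range(3):
            forces[:, c] += np.bincount(iu, weights=fpair[:, c], minlength=n)
            forces[:, c] -= np.bincount(ju, weights=fpair[:, c], minlength=n)

    energy = float(e_bond + e_ah + e_dh)
    if return_components:
        return energy, forces, {"bond": float(e_bond), "ah": e_ah, "dh": e_dh}
    return energy, forces


def make_potential(topology: Topology, overlap_floor: float | None = HARD_FLOOR_NM):
    """Closure ``coords -> (energy, forces)`` for the MD engine."""

    def potential(coords: np.ndarray) -> tuple[float, np.ndarray]:
        return energy_forces(coords, topology, overlap_floor=overlap_floor)

    return potential
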