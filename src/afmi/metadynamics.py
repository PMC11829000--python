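"""Parallel-bias well-tempered metadynamics on 1-D collective variables.

Each collective variable (CV) s_k carries its own one-dimensional bias V_k,
grown by Gaussian hills; the combined parallel bias acting on the system is
the softmin

    V_PB(s) = -kB T log[ (1/K) sum_k exp(-V_k(s_k) / kB T) ]

(the 1/K gauge makes V_PB = 0 when all per-CV biases are zero).  At each
deposition, CV k receives a hill of height

    h_k = h0 * exp(-V_k(s_k) / ((gamma - 1) kB T)) * w_k(s),

combining the well-tempered damping (bias factor gamma > 1) with the
conditional-probability weight w_k = exp(-V_k/kBT) / sum_j exp(-V_j/kBT) of
the parallel-bias scheme.  With a single CV the scheme reduces exactly to
well-tempered metadynamics, and the free-energy estimate along that CV is
F(s) = -(1 - 1/gamma)^{-1} V(s) + const.

Bias value grids are used during dynamics (piecewise-linear interpolation
with segment-slope forces); the complete hill history is kept so the final bias
can be re-evaluated exactly at every trajectory frame for reweighting.
By default the bias is shared across replicas (multiple-walker convention),
matching a protocol that concatenates replicas before reweighting.

CV units are nm; energies kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB

__all__ = [
    "CVSpec",
    "RadiusOfGyrationCV",
    "InterBeadDistanceCV",
    "SegmentComDistanceCV",
    "make_cv",
    "BiasState",
    "evaluate_bias_forces",
    "deposit_hill",
    "recompute_final_bias",
    "PBMetaDHook",
]


# ---------------------------------------------------------------------------
# Collective variables: value and gradient wrt bead coordinates
# ---------------------------------------------------------------------------


class RadiusOfGyrationCV:
    """Mass-uniform radius of gyration of a bead selection (nm)."""

    name = "rg"

    def __init__(self, indices: np.ndarray | None = None):
        self.indices = None if indices is None else np.asarray(indices, int)

    def value_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        idx = np.arange(len(coords)) if self.indices is None else self.indices
        x = coords[idx]
        com = x.mean(axis=0)
        dx = x - com
        s = float(np.sqrt((dx**2).sum() / len(x)))
        grad = np.zeros_like(coords)
        grad[idx] = dx / (len(x) * max(s, 1e-12))
        return s, grad


class InterBeadDistanceCV:
    """Distance between two beads, e.g. the chain ends (nm)."""

    name = "distance"

    def __init__(self, i: int, j: int):
        self.i, self.j = int(i), int(j)

    def value_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        d = coords[self.i] - coords[self.j]
        s = float(np.linalg.norm(d))
        grad = np.zeros_like(coords)
        u = d / max(s, 1e-12)
        grad[self.i] = u
        grad[self.j] = -u
        return s, grad


class SegmentComDistanceCV:
    """Distance between the centers of mass of two bead selections (nm)."""

    name = "com_distance"

    def __init__(self, sel_a: np.ndarray, sel_b: np.ndarray):
        self.sel_a = np.asarray(sel_a, int)
        self.sel_b = np.asarray(sel_b, int)

    def value_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        ca = coords[self.sel_a].mean(axis=0)
        cb = coords[self.sel_b].mean(axis=0)
        d = ca - cb
        s = float(np.linalg.norm(d))
        u = d / max(s, 1e-12)
        grad = np.zeros_like(coords)
        grad[self.sel_a] = u / len(self.sel_a)
        grad[self.sel_b] = -u / len(self.sel_b)
        return s, grad


@dataclass(frozen=True)
class CVSpec:
    """Declarative CV description used by configs.

    kind: ``radius_of_gyration`` | ``inter_bead_distance`` |
    ``segment_com_distance``; ``parameters`` holds the bead selections.
    """

    kind: str
    grid_min: float
    grid_max: float
    grid_spacing: float
    gaussian_width: float
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gaussian_width <= 0:
            raise ValueError("gaussian_width must be positive")
        if self.grid_max <= self.grid_min:
            raise ValueError("grid must cover a positive range")


def make_cv(spec: CVSpec):
    if spec.kind == "radius_of_gyration":
        return RadiusOfGyrationCV(spec.parameters.get("indices"))
    if spec.kind == "inter_bead_distance":
        return InterBeadDistanceCV(spec.parameters["i"], spec.parameters["j"])
    if spec.kind == "segment_com_distance":
        return SegmentComDistanceCV(spec.parameters["sel_a"], spec.parameters["sel_b"])
    raise ValueError(f"unknown CV kind '{spec.kind}'")


# ---------------------------------------------------------------------------
# Bias state
# ---------------------------------------------------------------------------


@dataclass
class BiasState:
    """Per-CV 1-D bias grids plus the complete hill history."""

    specs: list[CVSpec]
    height: float = 0.5  # kJ/mol, nominal hill height h0
    bias_factor: float = 10.0  # gamma, > 1
    pace: int = 500  # steps between depositions
    grids: list[np.ndarray] = field(default_factory=list)  # CV grid nodes
    values: list[np.ndarray] = field(default_factory=list)  # V_k at nodes
    hills: list[list[tuple[float, float, float]]] = field(default_factory=list)
    n_deposits: int = 0
    clamp_count: int = 0  # CV evaluations outside the grid

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if not self.grids:
            for spec in self.specs:
                g = np.arange(spec.grid_min, spec.grid_max + spec.grid_spacing / 2,
                              spec.grid_spacing)
                self.grids.append(g)
                self.values.append(np.zeros_like(g))
                self.hills.append([])

    @property
    def n_cvs(self) -> int:
        return len(self.specs)

    def bias_at(self, k: int, s: float) -> tuple[float, float]:
        """Interpolated (V_k, dV_k/ds) at CV value s, clamped to the grid.

        The bias is interpolated piecewise-linearly and the derivative is the
        exact slope of the active segment, so force and energy are mutually
        consistent to roundoff.
        """
        g = self.grids[k]
        v_grid = self.values[k]
        if s < g[0] or s > g[-1]:
            self.clamp_count += 1
            s = min(max(s, g[0]), g[-1])
        idx = min(int(np.searchsorted(g, s, side="right")) - 1, len(g) - 2)
        idx = max(idx, 0)
        frac = (s - g[idx]) / (g[idx + 1] - g[idx])
        v = (1.0 - frac) * v_grid[idx] + frac * v_grid[idx + 1]
        dv = (v_grid[idx + 1] - v_grid[idx]) / (g[idx + 1] - g[idx])
        return float(v), float(dv)


def _combined_bias(v_k: np.ndarray, kT: float) -> tuple[float, np.ndarray]:
    """Softmin V_PB (zero-bias gauge) and per-CV weights w_k."""
    a = -v_k / kT
    amax = a.max()
    expa = np.exp(a - amax)
    sum_expa = expa.sum()
    v_pb = -kT * (amax + np.log(sum_expa / len(v_k)))
    return float(v_pb), expa / sum_expa


def evaluate_bias_forces(
    cv_values: np.ndarray,
    cv_gradients: np.ndarray,
    bias: BiasState,
    temperature: float,
) -> tuple[float, np.ndarray]:
    """Combined parallel-bias potential and chain-rule forces for one replica.

    ``cv_values`` has shape (K,), ``cv_gradients`` (K, N, 3).
    """
    kT = KB * temperature
    v_k = np.empty(bias.n_cvs)
    dv_k = np.empty(bias.n_cvs)
    for k in range(bias.n_cvs):
        v_k[k], dv_k[k] = bias.bias_at(k, float(cv_values[k]))
    v_pb, w = _combined_bias(v_k, kT)
    # dV_PB/dx = sum_k w_k dV_k/ds_k * ds_k/dx
    forces = -np.einsum("k,kni->ni", w * dv_k, cv_gradients)
    return v_pb, forces


def deposit_hill(
    bias: BiasState, cv_values: np.ndarray, temperature: float
) -> BiasState:
    """Add one well-tempered, conditional-probability-weighted hill per CV."""
    kT = KB * temperature
    v_k = np.array([bias.bias_at(k, float(cv_values[k]))[0] for k in range(bias.n_cvs)])
    _, w = _combined_bias(v_k, kT)
    for k in range(bias.n_cvs):
        s0 = float(cv_values[k])
        width = bias.specs[k].gaussian_width
        h = bias.height * np.exp(-v_k[k] / ((bias.bias_factor - 1.0) * kT)) * w[k]
        g = bias.grids[k]
        arg = (g - s0) / width
        gauss = h * np.exp(-0.5 * arg**2)
        bias.values[k] += gauss
        bias.hills[k].append((s0, width, float(h)))
    bias.n_deposits += 1
    return bias


def _hill_sum(hills: list[tuple[float, float, float]], s: np.ndarray) -> np.ndarray:
    """Exact bias value(s) by direct summation over stored Gaussians."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    total = np.zeros_like(s)
    if hills:
        c = np.array([h[0] for h in hills])
        w = np.array([h[1] for h in hills])
        a = np.array([h[2] for h in hills])
        total = (a[None, :] * np.exp(-0.5 * ((s[:, None] - c[None, :]) / w[None, :]) ** 2)).sum(axis=1)
    return total


def recompute_final_bias(
    cv_series: np.ndarray, bias: BiasState, temperature: float
) -> np.ndarray:
    """End-of-run combined bias evaluated at every frame's CV values.

    ``cv_series`` has shape (n_frames, K).  The per-CV biases are evaluated by
    exact summation over the stored hill history (no grid interpolation
    error), then combined with the parallel-bias softmin.  This is the exact
    limit of re-running the deposition at an arbitrarily fast pace.
    """
    cv_series = np.asarray(cv_series, dtype=float)
    if cv_series.ndim == 1:
        cv_series = cv_series[:, None]
    if cv_series.shape[1] != bias.n_cvs:
        raise ValueError("cv_series width inconsistent with number of CVs")
    kT = KB * temperature
    v = np.column_stack(
        [_hill_sum(bias.hills[k], cv_series[:, k]) for k in range(bias.n_cvs)]
    )  # (F, K)
    a = -v / kT
    amax = a.max(axis=1, keepdims=True)
    v_pb = -kT * (amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1) / bias.n_cvs))
    return v_pb


class PBMetaDHook:
    """Engine hook: evaluates the shared bias and deposits hills on pace."""

    def __init__(
        self,
        specs: list[CVSpec],
        temperature: float,
        height: float = 0.5,
        bias_factor: float = 10.0,
        pace: int = 500,
        shared: bool = True,
    ):
        self.cvs = [make_cv(spec) for spec in specs]
        self.bias = BiasState(
            specs=specs, height=height, bias_factor=bias_factor, pace=pace
        )
        self.temperature = temperature
        self.pace = pace
        self.shared = shared
        if not shared:
            raise NotImplementedError("per-replica bias not implemented; use shared")

    def _cvs_and_grads(self, coords: np.ndarray):
        values = np.empty(len(self.cvs))
        grads = np.empty((len(self.cvs),) + coords.shape)
        for k, cv in enumerate(self.cvs):
            values[k], grads[k] = cv.value_and_grad(coords)
        return values, grads

    def cv_values(self, coords_all: np.ndarray) -> np.ndarray:
        return np.stack(
            [
                [cv.value_and_grad(coords_all[r])[0] for cv in self.cvs]
                for r in range(coords_all.shape[0])
            ]
        )

    def energy_forces(self, step: int, coords_all: np.ndarray):
        n_rep = coords_all.shape[0]
        energies = np.zeros(n_rep)
        forces = np.zeros_like(coords_all)
        for r in range(n_rep):
            values, grads = self._cvs_and_grads(coords_all[r])
            energies[r], forces[r] = evaluate_bias_forces(
                values, grads, self.bias, self.temperature
            )
        return energies, forces

    def on_step_end(self, step: int, coords_all: np.ndarray) -> None:
        if self.pace > 0 and step % self.pace == 0:
            for r in range(coords_all.shape[0]):
                values, _ = self._cvs_and_grads(coords_all[r])
                deposit_hill(self.bias, values, self.temperature)
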