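"""Per-cell mechanics: contraction law, node equilibrium and motor forces.

The cell is a quasi-spherical agent whose membrane is sampled by 24
sensing nodes.  Each node pulls on the matrix; the matrix resists with an
effective stiffness K_sub, and the node settles at the strain where the
cell's piecewise contraction law balances the substrate line
sigma = -K_sub * eps.  The contraction law has three branches: a passive
line outside the active strain range and two active branches meeting at
the strain of maximum force eps_tilde = sigma_max / K_act.

Forces (all in nN):
  traction  F_i = sigma_i * (S/n) * zeta * n_i    (n_i outward normal),
  protrusion F_prot = kappa * F_scale * e_rnd      (kappa ~ U[0,1]),
  field force |F_EF| = min(E, E_sat) * Omega * S   (toward the fiber),
  repulsion  F_ij = c_rep * (k_e/eps_r) (Omega S)^2 / r_ij^2 away from j,
  drag       F = f_sh * eta * v   with f_sh = 6 pi r for a single cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .membrane import DIRECTIONS
from .params import ModelParams

PHENOTYPES = ("MSC", "CM_early", "CM_late")


# ---------------------------------------------------------------------------
# contraction law and node equilibrium
# ---------------------------------------------------------------------------

def internal_stress(eps, params: ModelParams):
    """Three-branch piecewise cell stress (kPa) at internal strain ``eps``.

    Passive line K_pas*eps outside [eps_min, eps_max]; rising active branch
    on [eps_min, eps_tilde]; falling active branch on [eps_tilde, eps_max].
    Continuous at all three breakpoints.  Vectorized.
    """
    p = params
    e = np.asarray(eps, dtype=float)
    lower = p.K_act * p.sigma_max * (p.eps_min - e) / (p.K_act * p.eps_min - p.sigma_max)
    upper = p.K_act * p.sigma_max * (p.eps_max - e) / (p.K_act * p.eps_max - p.sigma_max)
    out = np.where(e <= p.eps_tilde, lower, upper) + p.K_pas * e
    passive = p.K_pas * e
    out = np.where((e < p.eps_min) | (e > p.eps_max), passive, out)
    return out if out.ndim else float(out)


def equilibrium_strain(k_sub, params: ModelParams):
    """Node equilibrium strain: intersection of the contraction law with the
    substrate resistance line sigma = -K_sub*eps.

    On the rising active branch the law is sigma = a + b*eps, so the
    intersection is eps = -a/(b + K_sub), which for any K_sub > 0 lies in
    (-a/b, 0) and hence always on that branch; the closed form is exact.
    Vectorized over K_sub.
    """
    k = np.asarray(k_sub, dtype=float)
    if np.any(k <= 0):
        raise ValueError("K_sub must be > 0")
    a, b = params.mid_branch_intercept, params.mid_branch_slope
    eps = -a / (b + k)
    return eps if eps.ndim else float(eps)


def node_equilibrium_strain(k_sub: float, params: ModelParams) -> float:
    """Scalar node-equilibrium strain with a bisection fallback for
    parameter sets where the closed form leaves the rising branch."""
    eps = equilibrium_strain(k_sub, params)
    if params.eps_min <= eps <= params.eps_tilde:
        return float(eps)
    # fallback: root of sigma(eps) + K_sub*eps on the full piecewise law
    lo, hi = params.eps_min, 0.0
    f = lambda e: internal_stress(e, params) + k_sub * e
    if f(lo) * f(hi) > 0:
        return 0.0  # passive root
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# cell state
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    """State of one cell agent."""

    id: int
    position: np.ndarray                  # (3,) um
    phenotype: str = "MSC"
    radius: float = 10.0
    mi: float = 0.0                       # maturation index in [0, 1]
    gamma_c: float = 0.0                  # instantaneous stimulus
    gamma_sum: float = 0.0                # accumulator over the current cycle
    gamma_steps: int = 0
    cycle_hours: float = 0.0              # time elapsed in the current cycle
    e_pol: np.ndarray = field(default_factory=lambda: np.zeros(3))
    blocked_octants: frozenset = frozenset()
    group: int = -1                       # connected-component id, -1 = free
    cj_partners: set = field(default_factory=set)
    # per-step force decomposition (nN), for debugging/dumps
    f_trac: np.ndarray = field(default_factory=lambda: np.zeros(3))
    f_prot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    f_elec: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    node_strain: Optional[np.ndarray] = None   # (24,)
    node_stress: Optional[np.ndarray] = None   # (24,)

    @property
    def active_nodes(self) -> np.ndarray:
        from .membrane import OCTANTS
        mask = np.ones(len(DIRECTIONS), dtype=bool)
        for o in self.blocked_octants:
            mask &= OCTANTS != o
        return mask

    @property
    def cj_count(self) -> int:
        return len(self.cj_partners)

    def gamma_cycle_mean(self) -> float:
        """Running time-average of the stimulus over the current cycle."""
        if self.gamma_steps == 0:
            return self.gamma_c
        return self.gamma_sum / self.gamma_steps


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def traction_forces(stress: np.ndarray, active: np.ndarray,
                    params: ModelParams):
    """Nodal tractions and resultant from per-node stresses.

    ``stress`` (24,) kPa, ``active`` boolean (24,).  Nodal force is
    sigma_i * (S/n) * zeta along the outward normal, so the resultant
    points toward the side where the matrix resists most (stiffer side) —
    the durotaxis drive.  Inactive (contact-blocked) nodes contribute
    nothing.  Returns (per-node (24,3) nN, resultant (3,) nN).
    """
    scale = params.node_area * params.zeta
    f_nodes = (stress * active)[:, None] * scale * DIRECTIONS
    return f_nodes, f_nodes.sum(axis=0)


def protrusion_force(f_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Random protrusion force: kappa * f_scale along a uniform random unit
    vector, kappa ~ U[0,1].  ``f_scale`` is the mean active nodal traction
    magnitude (same order of magnitude as the traction forces)."""
    kappa = rng.uniform()
    return kappa * f_scale * random_unit_vector(rng)


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - probability ~0
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def field_force(field_vec: np.ndarray, params: ModelParams,
                c_ef: float = None) -> np.ndarray:
    """Electrotactic force (nN) from the field vector (V/m): magnitude
    c_ef * min(E, E_sat) * Omega * S, along the field (toward the fiber).

    ``c_ef`` defaults to the calibrated scale in ``params`` (pass 1.0 for
    the bare force law).
    """
    E = float(np.linalg.norm(field_vec))
    if E == 0.0:
        return np.zeros(3)
    if c_ef is None:
        c_ef = params.c_ef if params.c_ef is not None else 1.0
    mag_N = min(E, params.E_sat) * params.Omega * params.membrane_area_m2
    return (c_ef * mag_N * 1e9 / E) * np.asarray(field_vec, dtype=float)


def coulomb_repulsion_magnitude(q_i: float, q_j: float, r: float,
                                ke_over_eps: float, c_rep: float = 1.0) -> float:
    """Bare pairwise repulsion magnitude c_rep * (k_e/eps_r) q_i q_j / r^2
    (caller's units)."""
    if r <= 0:
        raise ValueError("separation must be > 0")
    return c_rep * ke_over_eps * q_i * q_j / (r * r)


def repulsion_forces(positions: np.ndarray, params: ModelParams) -> np.ndarray:
    """Pairwise cell-cell electric repulsion, (n, 3) nN.

    Coulomb form (k_e/eps_r)(Omega S)^2 / r^2 scaled by the calibration
    constant c_rep; direction pushes cells apart.
    """
    if params.c_rep is None:
        raise ValueError("c_rep is unset; run through a scenario setup or "
                         "set it explicitly")
    pos = np.atleast_2d(positions)
    n = pos.shape[0]
    if n < 2:
        return np.zeros_like(pos)
    diff = pos[:, None, :] - pos[None, :, :]          # i - j, points j -> i
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(r2, np.inf)
    if np.any(r2[np.isfinite(r2)] < 1e-12):
        raise ValueError("coincident cell centers")
    qs = params.Omega * params.membrane_area_m2       # C
    pref = params.c_rep * 1e9 * (params.k_e / params.eps_r) * qs * qs
    # r in um -> m^2 in denominator
    inv = pref / (r2 * 1e-12)
    return np.einsum("ij,ijk->ik", inv / np.sqrt(r2), diff)


def electric_force(field_vec: np.ndarray, position: np.ndarray,
                   other_positions: np.ndarray,
                   params: ModelParams) -> np.ndarray:
    """Total electric force on one cell: field term plus repulsion from the
    listed neighbours (nN)."""
    f = field_force(field_vec, params)
    others = np.atleast_2d(other_positions) if np.size(other_positions) else None
    if others is not None and others.shape[0] > 0:
        stack = np.vstack([np.asarray(position)[None, :], others])
        f = f + repulsion_forces(stack, params)[0]
    return f


def drag_velocity(force: np.ndarray, f_sh: float,
                  params: ModelParams) -> np.ndarray:
    """Overdamped velocity (um/h) from the force balance F = f_sh * eta * v.

    ``f_sh`` in um (6 pi r for a single cell, shape-corrected for groups).
    """
    if f_sh <= 0:
        raise ValueError("shape factor must be > 0")
    return np.asarray(force, dtype=float) / (f_sh * params.eta_int)


def single_cell_shape_factor(params: ModelParams) -> float:
    return 6.0 * np.pi * params.r_cell
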