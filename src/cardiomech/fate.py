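"""Mechanical stimulus, maturation, differentiation, proliferation, death.

The stimulus a cell perceives is the mean equilibrium strain over its
active membrane nodes (negative under contraction; softer surroundings
let the cell contract more, making the stimulus more negative).  The
cycle time is t_mat = t_min + t_p * gamma (signed gamma, clamped below at
one time step), accumulated as a maturation index MI that advances by
dt / t_mat per step using the running cycle-average stimulus.

At MI = 1 a stem cell whose instantaneous stimulus falls in the
differentiation window becomes an early cardiomyocyte; a mature free cell
with fewer than CJ_max junctions divides into two daughters; any cell
whose stimulus exceeds the apoptosis threshold dies.  An early
cardiomyocyte joined to a stable group becomes a late (cycle-arrested)
cardiomyocyte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mechanics import Cell, random_unit_vector
from .params import ModelParams


@dataclass
class FateEvent:
    time: float
    cell_id: int
    event: str          # differentiate | divide | apoptose | arrest


def mechanical_stimulus(node_strain: np.ndarray, active: np.ndarray,
                        previous: float) -> float:
    """Mean strain over active membrane nodes; a fully enclosed cell (no
    active node) keeps its previous reading."""
    if not np.any(active):
        return previous
    return float(node_strain[active].mean())


def maturation_time(gamma: float, params: ModelParams) -> float:
    """Cycle time t_mat = t_min + t_p * gamma, clamped below at dt.

    Signed gamma: a contracting cell (negative stimulus) matures faster
    than the unstimulated t_min.
    """
    return max(params.t_min + params.t_p * gamma, params.dt)


def maturation_update(cell: Cell, gamma: float, params: ModelParams) -> float:
    """Advance the maturation index one step: MI is the ratio of elapsed
    cycle time to the cycle time implied by the running cycle-average
    stimulus, capped at 1.  The ratio form means a single step through an
    anomalously soft spot cannot complete the cycle by itself."""
    cell.gamma_sum += gamma
    cell.gamma_steps += 1
    cell.cycle_hours += params.dt
    t_mat = maturation_time(cell.gamma_cycle_mean(), params)
    cell.mi = min(cell.cycle_hours / t_mat, 1.0)
    return cell.mi


def reset_cycle(cell: Cell) -> None:
    cell.mi = 0.0
    cell.gamma_sum = 0.0
    cell.gamma_steps = 0
    cell.cycle_hours = 0.0


def in_differentiation_window(gamma: float, params: ModelParams) -> bool:
    return params.gamma_min < gamma <= params.gamma_max


def phenotype_update(cell: Cell, in_stable_group: bool,
                     params: ModelParams) -> Optional[str]:
    """Apply the phenotype rules; returns the event name or None.

    Order: apoptosis (checked every step) takes precedence; then stem-cell
    differentiation at MI = 1 inside the stimulus window; then maturation
    to the arrested late phenotype for grouped early cardiomyocytes.
    """
    if cell.gamma_c > params.gamma_apop:
        return "apoptose"
    if cell.phenotype == "MSC" and cell.mi >= 1.0 \
            and in_differentiation_window(cell.gamma_c, params):
        cell.phenotype = "CM_early"
        reset_cycle(cell)
        return "differentiate"
    if cell.phenotype == "CM_early" and in_stable_group:
        cell.phenotype = "CM_late"
        return "arrest"
    return None


def can_divide(cell: Cell, params: ModelParams) -> bool:
    return (cell.phenotype in ("MSC", "CM_early")
            and cell.mi >= 1.0
            and cell.cj_count < params.CJ_max)


def daughter_positions(mother_pos: np.ndarray, all_positions: np.ndarray,
                       rng: np.random.Generator, params: ModelParams,
                       max_tries: int = 50) -> Optional[np.ndarray]:
    """Placement of the second daughter: mother + 2r along a random unit
    direction, resampled until the site is inside the domain, clear of the
    fiber and overlaps no cell; None defers the division to the next step."""
    r = params.r_cell
    two_r = 2.0 * r
    L = np.array(params.domain)
    ay, az = params.fiber_axis_yz
    clear = params.fiber_outer_radius + r
    for _ in range(max_tries):
        site = mother_pos + two_r * random_unit_vector(rng)
        if np.any(site < r) or np.any(site > L - r):
            continue
        if np.hypot(site[1] - ay, site[2] - az) < clear:
            continue
        if all_positions.size and np.any(
                np.linalg.norm(all_positions - site, axis=1) < two_r * (1 - 1e-9)):
            continue
        return site
    return None
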