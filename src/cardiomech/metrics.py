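"""Outcome measures: group aspect ratio, main-group statistics, arrival times."""

from __future__ import annotations

from collections import Counter

import numpy as np

from .params import ModelParams


def group_extents_global(positions: np.ndarray, r_cell: float) -> np.ndarray:
    """Peak-to-peak member spread along the global X/Y/Z axes plus one cell
    diameter, floored at 2r (cells have volume)."""
    pos = np.atleast_2d(positions)
    ext = np.ptp(pos, axis=0) + 2.0 * r_cell
    return np.maximum(ext, 2.0 * r_cell)


def aspect_ratio(positions: np.ndarray, r_cell: float) -> float:
    """Elongation AR = sqrt(l_x^2 / (l_y l_z)) on the global axes; 1 for an
    isotropic group, > 1 for a group stretched along the fiber axis."""
    lx, ly, lz = group_extents_global(positions, r_cell)
    return float(np.sqrt(lx * lx / (ly * lz)))


def main_group_stats(labels: np.ndarray, params: ModelParams):
    """(size, members, formed) of the main group: largest junction-connected
    component, ties broken by the lowest member index; formed when it holds
    at least ``main_group_fraction`` of the living cells."""
    n = len(labels)
    if n == 0:
        return 0, np.array([], dtype=int), False
    counts = Counter(labels.tolist())
    best_size = max(counts.values())
    best_label = min(lbl for lbl, c in counts.items() if c == best_size)
    members = np.flatnonzero(labels == best_label)
    formed = best_size >= params.main_group_fraction * n
    return int(best_size), members, bool(formed)


def distance_to_fiber_axis(positions: np.ndarray,
                           params: ModelParams) -> np.ndarray:
    pos = np.atleast_2d(positions)
    ay, az = params.fiber_axis_yz
    return np.hypot(pos[:, 1] - ay, pos[:, 2] - az)


def touching_fiber(positions: np.ndarray, params: ModelParams) -> np.ndarray:
    """Boolean mask of cells whose body touches the fiber surface."""
    reach = params.fiber_outer_radius + params.r_cell
    return distance_to_fiber_axis(positions, params) <= reach * (1 + 1e-9)


def summarize_arrival_times(first_touch: dict, all_ids) -> dict:
    """Mean first-touch time over arrived cells; never-arriving cells are
    censored and reported as a count."""
    arrived = [first_touch[i] for i in all_ids if i in first_touch]
    censored = sum(1 for i in all_ids if i not in first_touch)
    return {
        "n_arrived": len(arrived),
        "n_censored": censored,
        "mean_time_to_fiber": float(np.mean(arrived)) if arrived else float("nan"),
    }
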