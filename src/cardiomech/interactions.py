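"""Cell-cell contacts, stable junctions and collective group motion.

Two cells are in contact when their center distance is 2r (within a small
relative tolerance).  A contact becomes a stable cell junction (CJ) when
its direction is sufficiently aligned with the population's global
polarization: |e_ij . G_pol| >= l_adh.  Junction-connected cells form
groups that translate rigidly, dragged by the vector sum of their
members' motor forces with an ellipsoid-corrected shape factor; a stalled
group lets individual members relocate along the group surface instead.

Junctions are persistent: once formed they dissolve only when the pair
separates beyond a band around 2r (or a partner dies), not by
re-evaluation against the current global polarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .params import ModelParams
from .membrane import DIRECTIONS


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_pairs(positions: np.ndarray, params: ModelParams) -> list:
    """All pairs (i, j, dist, e_ij) with ||X_ij|| <= 2r(1+tol), i < j.

    e_ij points from cell j to cell i (the direction of the repulsive push
    on i); e_ji = -e_ij.
    """
    pos = np.atleast_2d(positions)
    n = pos.shape[0]
    if n < 2:
        return []
    thresh = 2.0 * params.r_cell * (1.0 + params.contact_tol)
    pairs = cKDTree(pos).query_pairs(thresh, output_type="ndarray")
    out = []
    for i, j in pairs:
        diff = pos[i] - pos[j]
        dist = float(np.linalg.norm(diff))
        e = diff / dist if dist > 0 else np.zeros(3)
        out.append((int(i), int(j), dist, e))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def polarization(f_trac: np.ndarray, f_field: np.ndarray,
                 previous: np.ndarray) -> np.ndarray:
    """Cell polarization: normalized sum of the mechanical and electrical
    stimulus directions.  Zero or exactly cancelling summands keep the
    previous direction (documented tie-break)."""
    total = np.zeros(3)
    for f in (f_trac, f_field):
        n = np.linalg.norm(f)
        if n > 1e-12:
            total = total + np.asarray(f) / n
    n = np.linalg.norm(total)
    if n < 1e-9:
        return np.asarray(previous, dtype=float)
    return total / n


def global_polarization(e_pols: np.ndarray, previous: np.ndarray) -> np.ndarray:
    """Global polarization: normalized resultant of all cell polarizations;
    a zero resultant keeps the previous step's direction."""
    pols = np.atleast_2d(e_pols)
    nrm = np.linalg.norm(pols, axis=1, keepdims=True)
    nrm[nrm < 1e-12] = 1.0
    res = (pols / nrm).sum(axis=0)
    n = np.linalg.norm(res)
    if n < 1e-9:
        return np.asarray(previous, dtype=float)
    return res / n


# ---------------------------------------------------------------------------
# junction classification
# ---------------------------------------------------------------------------

def contact_projection(e_ij: np.ndarray, g_pol: np.ndarray) -> float:
    """l_ij = |e_ij . G_pol| in [0, 1] (a tissue direction has no sign)."""
    return float(abs(np.dot(e_ij, g_pol)))


def classify_junctions(contacts: list, g_pol: np.ndarray,
                       params: ModelParams) -> set:
    """CJ edge set from the current contacts: touching at 2r within
    tolerance and projection >= l_adh (boundary inclusive)."""
    edges = set()
    two_r = 2.0 * params.r_cell
    for i, j, dist, e_ij in contacts:
        if abs(dist - two_r) > two_r * params.contact_tol:
            continue
        if contact_projection(e_ij, g_pol) >= params.l_adh:
            edges.add((min(i, j), max(i, j)))
    return edges


def junction_components(n: int, edges: set) -> np.ndarray:
    """Connected-component label per cell (singletons get their own label)."""
    if not edges:
        return np.arange(n)
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def articulation_points(members: list, edges: set) -> set:
    """Cut vertices of the junction subgraph induced on ``members``.

    Iterative Hopcroft-Tarjan; removing any non-articulation member leaves
    the rest of its group connected.
    """
    members = list(members)
    idx = {m: k for k, m in enumerate(members)}
    adj = [[] for _ in members]
    for a, b in edges:
        if a in idx and b in idx:
            adj[idx[a]].append(idx[b])
            adj[idx[b]].append(idx[a])
    n = len(members)
    disc = [-1] * n
    low = [0] * n
    parent = [-1] * n
    cut = set()
    timer = 0
    for root in range(n):
        if disc[root] != -1:
            continue
        stack = [(root, 0)]
        root_children = 0
        while stack:
            v, ptr = stack[-1]
            if ptr == 0:
                disc[v] = low[v] = timer
                timer += 1
            if ptr < len(adj[v]):
                stack[-1] = (v, ptr + 1)
                w = adj[v][ptr]
                if disc[w] == -1:
                    parent[w] = v
                    if v == root:
                        root_children += 1
                    stack.append((w, 0))
                elif w != parent[v]:
                    low[v] = min(low[v], disc[w])
            else:
                stack.pop()
                if parent[v] != -1:
                    p = parent[v]
                    low[p] = min(low[p], low[v])
                    if p != root and low[v] >= disc[p]:
                        cut.add(members[p])
        if root_children > 1:
            cut.add(members[root])
    return cut


# ---------------------------------------------------------------------------
# groups
# ---------------------------------------------------------------------------

@dataclass
class CellGroup:
    """Geometry and drag of one junction-connected group."""

    members: np.ndarray        # cell indices
    l_max: float
    l_med: float
    l_min: float
    r_grp: float
    f_sh: float

    @classmethod
    def from_positions(cls, members, positions: np.ndarray,
                       params: ModelParams) -> "CellGroup":
        members = np.asarray(list(members), dtype=int)
        pos = positions[members]
        r = params.r_cell
        n = len(members)
        if n == 1:
            ext = np.full(3, 2.0 * r)
        else:
            centered = pos - pos.mean(axis=0)
            cov = centered.T @ centered / n
            _, vecs = np.linalg.eigh(cov)
            proj = centered @ vecs
            ext = np.ptp(proj, axis=0) + 2.0 * r   # cells have volume
        ext = np.sort(ext)[::-1]
        l_max, l_med, l_min = (float(v) for v in ext)
        r_grp = r * n ** (1.0 / 3.0)
        f_sh = group_shape_factor(l_max, l_med, l_min, r_grp)
        return cls(members=members, l_max=l_max, l_med=l_med, l_min=l_min,
                   r_grp=r_grp, f_sh=f_sh)


def group_shape_factor(l_max: float, l_med: float, l_min: float,
                       r_grp: float) -> float:
    """Ellipsoid-corrected Stokes shape factor
    6 pi r_grp ((l_max l_med) / l_min^2)^0.096; the spherical limit
    (l_max = l_med = l_min) reduces to the single-cell 6 pi r."""
    if min(l_max, l_med, l_min) <= 0:
        raise ValueError("group extents must be > 0")
    return 6.0 * np.pi * r_grp * ((l_max * l_med) / l_min ** 2) ** 0.096


def group_velocity(total_force: np.ndarray, group: CellGroup,
                   params: ModelParams) -> np.ndarray:
    """v_grp = sum of member motor forces / (f_sh * eta), um/h."""
    return np.asarray(total_force, dtype=float) / (group.f_sh * params.eta_int)


def clamp_shift_to_domain(shift: np.ndarray, member_pos: np.ndarray,
                          params: ModelParams) -> np.ndarray:
    """Reduce a rigid translation so every member stays >= r_cell inside the
    box (componentwise clipping preserves rigidity)."""
    r = params.r_cell
    L = np.array(params.domain)
    out = np.asarray(shift, dtype=float).copy()
    for d in range(3):
        lo = (r - member_pos[:, d]).max()
        hi = (L[d] - r - member_pos[:, d]).min()
        out[d] = np.clip(out[d], min(lo, 0.0), max(hi, 0.0))
    return out


# ---------------------------------------------------------------------------
# relocation
# ---------------------------------------------------------------------------

def relocate_candidates(cell_idx: int, group_members, positions: np.ndarray,
                        desired_dir: np.ndarray, params: ModelParams,
                        max_anchors: int = 10) -> list:
    """Candidate sites for an internal migration of one group member.

    Sites sit at distance 2r from an anchor member along each membrane
    direction, evaluated along the cell's desired direction; valid sites
    are inside the domain, clear of the fiber and overlap nobody.
    Returns (score, site, anchor) sorted best-first.
    """
    r = params.r_cell
    two_r = 2.0 * r
    L = np.array(params.domain)
    ay, az = params.fiber_axis_yz
    clear = params.fiber_outer_radius + r
    cur = positions[cell_idx]
    d = np.asarray(desired_dir, dtype=float)
    others = [m for m in group_members if m != cell_idx]
    if not others:
        return []
    anchors = sorted(others, key=lambda m: -float((positions[m] - cur) @ d))
    anchors = anchors[:max_anchors]
    mask = np.ones(positions.shape[0], dtype=bool)
    mask[cell_idx] = False
    occupied = positions[mask]
    out = []
    for m in anchors:
        sites = positions[m] + two_r * DIRECTIONS
        inside = np.all((sites >= r) & (sites <= L - r), axis=1)
        radial = np.hypot(sites[:, 1] - ay, sites[:, 2] - az) >= clear
        for site in sites[inside & radial]:
            dd = np.linalg.norm(occupied - site, axis=1)
            if np.any(dd < two_r * (1.0 - 1e-9)):
                continue
            score = float((site - cur) @ d)
            out.append((score, site, m))
    out.sort(key=lambda t: -t[0])
    return out
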