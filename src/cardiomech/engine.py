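"""Time-stepping engine: one hour per step, reproducible per seed.

Each step runs, in order: matrix refresh (cached), per-cell sensing and
motor forces, polarization, contact/junction bookkeeping, fate events,
movement (rigid for junction-connected groups, individual otherwise, then
relocation inside stalled groups) and overlap resolution.  Forces are
computed synchronously from the previous step's positions, so the update
is independent of cell ordering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import fate as fate_mod
from . import interactions as inter
from . import mechanics as mech
from . import metrics as metr
from .ecm import EcmModel
from .electric import ElectricFieldModel
from .membrane import DIRECTIONS, OCTANTS, octant_of
from .params import ModelParams

SCENARIOS = ("DIFF", "F-ECM", "MSF-ECM", "MSF-PZE-ECM")


@dataclass
class ScenarioConfig:
    """One experiment: initial phenotype, duration and stimuli."""

    name: str
    initial_phenotype: str
    steps: int
    applied_strain: float
    field_mode: str
    params: ModelParams

    @classmethod
    def preset(cls, name: str, params: Optional[ModelParams] = None,
               **overrides) -> "ScenarioConfig":
        """Build one of the four standard experiments.

        DIFF: 60 stem cells, 75 h, no load, no field (differentiation by
        matrix stiffness alone).  F-ECM: 60 cardiomyocytes, 250 h, fibered
        matrix only.  MSF-ECM: adds the 0.25 longitudinal strain.
        MSF-PZE-ECM: adds the strain-generated electric field.
        """
        presets = {
            "DIFF": dict(initial_phenotype="MSC", steps=75,
                         applied_strain=0.0, field_mode="off"),
            "F-ECM": dict(initial_phenotype="CM_early", steps=250,
                          applied_strain=0.0, field_mode="off"),
            "MSF-ECM": dict(initial_phenotype="CM_early", steps=250,
                            applied_strain=0.25, field_mode="off"),
            "MSF-PZE-ECM": dict(initial_phenotype="CM_early", steps=250,
                                applied_strain=0.25, field_mode="lookup"),
        }
        if name not in presets:
            raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
        chosen = dict(presets[name])
        chosen.update({k: v for k, v in overrides.items() if k in chosen})
        param_overrides = {k: v for k, v in overrides.items()
                           if k not in chosen}
        p = params if params is not None else ModelParams()
        p = dataclasses.replace(p, applied_strain=chosen["applied_strain"],
                                **param_overrides).validate()
        return cls(name=name, params=p, **chosen)


# ---------------------------------------------------------------------------
# ECM cache: the load state is static within a scenario, so the solved
# matrix and its probe field are shared across replicates.
# ---------------------------------------------------------------------------

_ECM_CACHE: Dict[tuple, EcmModel] = {}
_CSUB_CACHE: Dict[tuple, float] = {}

#: Internal seeds of the substrate-constant identification; fixed so the
#: calibration is deterministic and independent of user seeds.
_CALIBRATION_SEEDS = (101, 102, 103)
_CALIBRATION_TARGET_H = 18.0   # observed first differentiation time


def _geometry_key(p: ModelParams) -> tuple:
    return (p.domain, p.E_ecm, p.E_fib, p.nu, p.fiber_outer_diam,
            p.fiber_thickness, p.fiber_core, p.resolution, p.r_cell,
            p.gamma_target)


def _calibration_key(p: ModelParams) -> tuple:
    # one constant per matrix composition: thickness variants share it
    return (p.domain, p.E_ecm, p.E_fib, p.nu, p.fiber_outer_diam,
            p.fiber_core, p.resolution, p.r_cell, p.gamma_target)


def _raw_model(params: ModelParams) -> EcmModel:
    """Cached mesh/solution/probe field for a geometry and load state;
    built with a placeholder substrate constant that callers overwrite."""
    key = _geometry_key(params) + (params.applied_strain,)
    if key not in _ECM_CACHE:
        _ECM_CACHE[key] = EcmModel.build(params, c_sub=1.0)
    return _ECM_CACHE[key]


def identify_c_sub(params: ModelParams) -> float:
    """Identify the substrate constant against the differentiation
    observable: bisect c_sub so the median first-differentiation time in
    the stem-cell scenario equals the observed 18 h.

    A static anchor (gamma_target at the softest position) would ignore
    that migrating cells average the stimulus along their paths; running
    the actual scenario on fixed internal seeds identifies the constant
    under the same dynamics the model is used with.  Monotone: a stiffer
    reading (larger c_sub) slows maturation and delays the first event.
    """
    from .ecm import calibrate_c_sub, reference_traction_force

    base = dataclasses.replace(params, applied_strain=0.0,
                               fiber_thickness=ModelParams.fiber_thickness,
                               c_sub=None, c_rep=None).validate()
    model0 = _raw_model(base)

    model0.field.c_sub = 1.0
    c0 = calibrate_c_sub(model0.field, base)

    def median_first_diff(c: float) -> float:
        model0.field.c_sub = c
        model0.c_sub = c
        times = []
        model0.f_ref = reference_traction_force(model0.field, base)
        for s in _CALIBRATION_SEEDS:
            p = dataclasses.replace(base, c_sub=c, c_rep=None).validate()
            cfg = ScenarioConfig(name="DIFF", initial_phenotype="MSC",
                                 steps=75, applied_strain=0.0,
                                 field_mode="off", params=p)
            st = init_state(cfg, s, ecm=model0)
            t_first = float("inf")
            for _ in range(cfg.steps):
                step(st)
                ev = [e for e in st.events if e.event == "differentiate"]
                if ev:  # only the first event matters for the bisection
                    t_first = min(e.time for e in ev)
                    break
            times.append(t_first)
        return float(np.median(times))

    lo, hi = c0 / 30.0, c0 * 3.0
    if median_first_diff(lo) > _CALIBRATION_TARGET_H:
        return lo
    if median_first_diff(hi) < _CALIBRATION_TARGET_H:
        return hi
    for _ in range(12):
        mid = float(np.sqrt(lo * hi))
        if median_first_diff(mid) < _CALIBRATION_TARGET_H:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def get_ecm_model(params: ModelParams) -> EcmModel:
    """Cached ECM model; the substrate constant is identified once per
    matrix composition (on the unstrained default geometry) and reused
    across fiber thicknesses and load states."""
    c_sub = params.c_sub
    if c_sub is None:
        ckey = _calibration_key(params)
        if ckey not in _CSUB_CACHE:
            _CSUB_CACHE[ckey] = identify_c_sub(params)
        c_sub = _CSUB_CACHE[ckey]
    from .ecm import reference_traction_force

    model = _raw_model(params)
    if model.field.c_sub != c_sub or model.f_ref == 0.0:
        model.field.c_sub = c_sub
        model.c_sub = c_sub
        model.f_ref = reference_traction_force(model.field, params)
    return model


def clear_ecm_cache() -> None:
    _ECM_CACHE.clear()
    _CSUB_CACHE.clear()


# ---------------------------------------------------------------------------
# simulation state
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    params: ModelParams
    cells: List[mech.Cell]
    rng: np.random.Generator
    efield: ElectricFieldModel
    ecm: EcmModel
    step_index: int = 0
    cj_edges: set = field(default_factory=set)     # frozenset pairs of cell ids
    g_pol: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    next_id: int = 0
    events: List[fate_mod.FateEvent] = field(default_factory=list)
    records: List[dict] = field(default_factory=list)
    first_touch: Dict[int, float] = field(default_factory=dict)
    all_ids: set = field(default_factory=set)
    main_group_formation_time: Optional[float] = None

    @property
    def time(self) -> float:
        return self.step_index * self.params.dt

    def positions(self) -> np.ndarray:
        if not self.cells:
            return np.zeros((0, 3))
        return np.array([c.position for c in self.cells])

    def id_index(self) -> Dict[int, int]:
        return {c.id: k for k, c in enumerate(self.cells)}


def seed_cells(params: ModelParams, rng: np.random.Generator,
               phenotype: str, n: Optional[int] = None) -> List[mech.Cell]:
    """Uniform random non-overlapping seeding, clear of walls and fiber."""
    n = params.n_cells if n is None else n
    r = params.r_cell
    L = np.array(params.domain)
    ay, az = params.fiber_axis_yz
    clear = params.fiber_outer_radius + r
    placed = []
    guard = 0
    while len(placed) < n:
        guard += 1
        if guard > 100000:
            raise RuntimeError("could not seed cells without overlap")
        pos = r + rng.uniform(size=3) * (L - 2 * r)
        if np.hypot(pos[1] - ay, pos[2] - az) < clear:
            continue
        if placed and np.any(np.linalg.norm(np.array(placed) - pos, axis=1) < 2 * r):
            continue
        placed.append(pos)
    return [mech.Cell(id=i, position=np.array(p), phenotype=phenotype,
                      radius=r) for i, p in enumerate(placed)]


def init_state(config: ScenarioConfig, seed: int,
               ecm: Optional[EcmModel] = None) -> SimulationState:
    params = config.params
    rng = np.random.default_rng(seed)
    if ecm is None:
        ecm = get_ecm_model(params)
    if params.c_rep is None:
        params.c_rep = params.derive_c_rep(ecm.f_ref)
    efield = ElectricFieldModel(mode=config.field_mode)
    cells = seed_cells(params, rng, config.initial_phenotype)
    st = SimulationState(params=params, cells=cells, rng=rng, efield=efield,
                         ecm=ecm, next_id=len(cells))
    st.all_ids = {c.id for c in cells}
    _update_first_touch(st)
    _record_metrics(st)
    return st


# ---------------------------------------------------------------------------
# step phases
# ---------------------------------------------------------------------------

def _sense_and_forces(st: SimulationState):
    """Phase 1-2: contacts, face blocking, node strains, motor forces."""
    p = st.params
    cells = st.cells
    n = len(cells)
    pos = st.positions()

    contacts = inter.contact_pairs(pos, p)
    blocked = [set() for _ in range(n)]
    for i, j, dist, e_ij in contacts:
        blocked[i].add(octant_of(-e_ij))   # face of i toward j
        blocked[j].add(octant_of(e_ij))
    for k, c in enumerate(cells):
        c.blocked_octants = frozenset(blocked[k])

    # vectorized sensing: K_sub at every membrane node of every cell
    node_pos = (pos[:, None, :] + p.r_cell * DIRECTIONS[None]).reshape(-1, 3)
    node_dir = np.tile(DIRECTIONS, (n, 1))
    k_sub = st.ecm.field.k_sub(node_pos, node_dir).reshape(n, 24)
    eps = mech.equilibrium_strain(k_sub, p)
    sigma = mech.internal_stress(eps, p)

    field_dirs = st.efield.directions_at(pos, p)
    field_mag = st.efield.magnitude(p)
    rep = mech.repulsion_forces(pos, p) if n > 1 else np.zeros_like(pos)

    # active-node masks from the blocked octant faces
    active = np.ones((n, 24), dtype=bool)
    for k in range(n):
        for o in blocked[k]:
            active[k] &= OCTANTS != o

    scale = p.node_area * p.zeta
    f_trac = scale * np.einsum("ni,id->nd", sigma * active, DIRECTIONS)
    n_active = active.sum(axis=1)
    # protrusion scale: mean active nodal traction magnitude (same order
    # of magnitude as the traction forces)
    f_scale = np.where(n_active > 0,
                       scale * np.abs(sigma * active).sum(axis=1)
                       / np.maximum(n_active, 1), 0.0)
    kappa = st.rng.uniform(size=n)
    e_rnd = st.rng.standard_normal((n, 3))
    e_rnd /= np.maximum(np.linalg.norm(e_rnd, axis=1, keepdims=True), 1e-12)
    f_prot = (kappa * f_scale)[:, None] * e_rnd

    # electrotaxis: saturated magnitude along the (radial) field direction
    mag_eff = min(field_mag, p.E_sat) if field_mag > 0 else 0.0
    f_ef = (p.c_ef * mag_eff * p.Omega * p.membrane_area_m2 * 1e9) * field_dirs

    for k, c in enumerate(cells):
        c.node_strain = eps[k]
        c.node_stress = sigma[k]
        c.f_trac = f_trac[k]
        c.f_prot = f_prot[k]
        c.f_elec = f_ef[k] + rep[k]

    # polarization (mechanical + electrical stimulus directions)
    def _unit_rows(v):
        nn = np.linalg.norm(v, axis=1, keepdims=True)
        out = np.zeros_like(v)
        ok = nn[:, 0] > 1e-12
        out[ok] = v[ok] / nn[ok]
        return out

    if n:
        pol = _unit_rows(_unit_rows(f_trac) + _unit_rows(f_ef))
        prev = np.array([c.e_pol for c in cells])
        degenerate = np.linalg.norm(pol, axis=1) < 1e-9
        pol[degenerate] = prev[degenerate]
        for k, c in enumerate(cells):
            c.e_pol = pol[k]
        st.g_pol = inter.global_polarization(pol, st.g_pol)
    return contacts


def _update_junctions(st: SimulationState, contacts):
    """Phase 3: dissolve separated junctions, classify new ones.

    Junctions form only between differentiated (cardiac) cells; they
    persist until the pair separates beyond the tolerance band.
    """
    p = st.params
    cells = st.cells
    idx = st.id_index()
    two_r = 2.0 * p.r_cell
    keep = set()
    for edge in st.cj_edges:
        a, b = tuple(edge)
        if a not in idx or b not in idx:
            continue
        d = np.linalg.norm(cells[idx[a]].position - cells[idx[b]].position)
        if d <= two_r * (1.0 + p.separation_tol):
            keep.add(edge)
    new_edges = inter.classify_junctions(contacts, st.g_pol, p)
    for i, j in new_edges:
        ci, cj = cells[i], cells[j]
        if ci.phenotype == "MSC" or cj.phenotype == "MSC":
            continue
        keep.add(frozenset((ci.id, cj.id)))
    st.cj_edges = keep
    _refresh_groups(st)


def _refresh_groups(st: SimulationState):
    idx = st.id_index()
    n = len(st.cells)
    edges = {tuple(sorted((idx[a], idx[b])))
             for e in st.cj_edges for a, b in [tuple(e)]
             if a in idx and b in idx}
    labels = inter.junction_components(n, edges)
    partners = [set() for _ in range(n)]
    for i, j in edges:
        partners[i].add(st.cells[j].id)
        partners[j].add(st.cells[i].id)
    for k, c in enumerate(st.cells):
        c.group = int(labels[k])
        c.cj_partners = partners[k]
    return labels, edges


def _fate_phase(st: SimulationState):
    """Phase 4: stimulus accumulation, differentiation, arrest, division,
    apoptosis.  Population bookkeeping: N' = N + divisions - apoptoses."""
    p = st.params
    t = st.time
    dead = []
    divisions = []
    # group sizes for the stable-group test
    from collections import Counter
    sizes = Counter(c.group for c in st.cells)
    for c in st.cells:
        active = c.active_nodes
        c.gamma_c = fate_mod.mechanical_stimulus(c.node_strain, active, c.gamma_c)
        fate_mod.maturation_update(c, c.gamma_c, p)
        in_stable = sizes[c.group] >= 2
        event = fate_mod.phenotype_update(c, in_stable, p)
        if event == "apoptose":
            dead.append(c.id)
        if event:
            st.events.append(fate_mod.FateEvent(t, c.id, event))
        if event is None and fate_mod.can_divide(c, p):
            divisions.append(c)

    all_pos = st.positions()
    for mother in divisions:
        if mother.id in dead:
            continue
        site = fate_mod.daughter_positions(mother.position, all_pos, st.rng, p)
        if site is None:
            continue  # crowded: division deferred to a later step
        daughter = mech.Cell(id=st.next_id, position=site,
                             phenotype=mother.phenotype, radius=p.r_cell,
                             e_pol=mother.e_pol.copy())
        st.next_id += 1
        fate_mod.reset_cycle(mother)
        st.cells.append(daughter)
        st.all_ids.add(daughter.id)
        all_pos = np.vstack([all_pos, site[None]])
        st.events.append(fate_mod.FateEvent(t, mother.id, "divide"))

    if dead:
        dead_set = set(dead)
        st.cells = [c for c in st.cells if c.id not in dead_set]
        st.cj_edges = {e for e in st.cj_edges
                       if not (set(e) & dead_set)}
    _refresh_groups(st)


def _movement_phase(st: SimulationState):
    """Phase 5: rigid group translation, individual migration, relocation."""
    p = st.params
    cells = st.cells
    if not cells:
        return
    pos = st.positions()
    labels, edges = _refresh_groups(st)
    total_force = np.array([c.f_trac + c.f_elec + c.f_prot for c in cells])

    from collections import defaultdict
    groups = defaultdict(list)
    for k, lbl in enumerate(labels):
        groups[lbl].append(k)

    velocity = np.zeros_like(pos)
    stalled = []
    for lbl, members in groups.items():
        if len(members) == 1:
            k = members[0]
            v = mech.drag_velocity(total_force[k],
                                   mech.single_cell_shape_factor(p), p)
            cells[k].velocity = v
            velocity[k] = v
        else:
            grp = inter.CellGroup.from_positions(members, pos, p)
            f_grp = total_force[members].sum(axis=0)
            v_grp = inter.group_velocity(f_grp, grp, p)
            shift = inter.clamp_shift_to_domain(v_grp * p.dt, pos[members], p)
            for k in members:
                cells[k].velocity = v_grp
            velocity[members] = shift[None] / p.dt
            if np.linalg.norm(v_grp) * p.dt < p.relocation_threshold * p.r_cell:
                stalled.append(members)

    # substep the advection so nobody moves more than half a radius between
    # overlap resolutions: a full 1 h step at typical speeds would drive
    # colliding groups several radii into each other and the violent
    # push-apart would tear junctions (or let groups tunnel through)
    v_max = float(np.linalg.norm(velocity, axis=1).max()) if len(cells) else 0.0
    n_sub = int(min(5, max(1, np.ceil(v_max * p.dt / (2.0 * p.r_cell)))))
    for k_sub in range(n_sub):
        new_pos = st.positions() + velocity * (p.dt / n_sub)
        # intermediate substeps only need rough separation; the final pass
        # restores the strict non-overlap invariant
        _apply_positions(st, new_pos,
                         max_iter=8 if k_sub < n_sub - 1 else 80)
    for members in stalled:
        _relocate_in_group(st, members, total_force)


def _relocate_in_group(st: SimulationState, members, total_force,
                       max_moves: int = 3):
    """Internal migration in a stalled group: non-articulation members move
    to the best adjacent free site along their own desired direction."""
    p = st.params
    pos = st.positions()
    idx = st.id_index()
    edge_idx = {tuple(sorted((idx[a], idx[b])))
                for e in st.cj_edges for a, b in [tuple(e)]
                if a in idx and b in idx}
    cut = inter.articulation_points(list(members), edge_idx)
    order = sorted(members, key=lambda k: -float(np.linalg.norm(total_force[k])))
    moves = 0
    for k in order:
        if moves >= max_moves or k in cut:
            continue
        f = total_force[k]
        nf = np.linalg.norm(f)
        if nf < 1e-12:
            continue
        cand = inter.relocate_candidates(k, members, pos, f / nf, p)
        accepted = None
        for score, site, anchor in cand:
            if score <= 0:
                break
            accepted = (site, anchor)
            break
        if accepted is None:
            continue
        site, anchor = accepted
        cell = st.cells[k]
        old = cell.position.copy()
        cell.position = np.asarray(site, dtype=float)
        pos[k] = cell.position
        # junction bookkeeping: stretched edges dissolve, the anchor attaches
        two_r = 2.0 * p.r_cell
        band = two_r * (1.0 + p.separation_tol)
        st.cj_edges = {e for e in st.cj_edges
                       if cell.id not in e or _edge_len(st, e, idx) <= band}
        st.cj_edges.add(frozenset((cell.id, st.cells[anchor].id)))
        moves += 1
        st.events.append(fate_mod.FateEvent(st.time, cell.id, "relocate"))
    _refresh_groups(st)


def _edge_len(st: SimulationState, edge, idx) -> float:
    a, b = tuple(edge)
    if a not in idx or b not in idx:
        return np.inf
    return float(np.linalg.norm(st.cells[idx[a]].position
                                - st.cells[idx[b]].position))


def _apply_positions(st: SimulationState, new_pos: np.ndarray,
                     max_iter: int = 30):
    """Domain clamp, fiber clearance and pairwise overlap resolution.

    Overlaps are relaxed Jacobi-style: every overlapping pair contributes
    a symmetric half-gap push along its center line, accumulated and
    applied at once, iterated until the packing is clean.
    """
    from scipy.spatial import cKDTree

    p = st.params
    r = p.r_cell
    two_r = 2.0 * r
    L = np.array(p.domain)
    ay, az = p.fiber_axis_yz
    clear = p.fiber_outer_radius + r
    pos = new_pos
    tol = 1e-7 * r

    # junction edges act as adhesion constraints: attached pairs are pulled
    # back toward contact distance, so crowding resolution cannot tear a
    # stable junction apart
    idx = st.id_index()
    cj = [(idx[a], idx[b]) for e in st.cj_edges
          for a, b in [tuple(e)] if a in idx and b in idx]
    cj = np.array(cj, dtype=int).reshape(-1, 2)

    for _ in range(max_iter):
        pos = np.clip(pos, r, L - r)
        # radial push-out of the fiber volume
        dy = pos[:, 1] - ay
        dz = pos[:, 2] - az
        rad = np.hypot(dy, dz)
        inside = rad < clear
        if np.any(inside):
            safe = np.maximum(rad[inside], 1e-9)
            pos[inside, 1] = ay + dy[inside] / safe * clear
            pos[inside, 2] = az + dz[inside] / safe * clear
        if pos.shape[0] < 2:
            if not np.any(inside):
                break
            continue
        pairs = cKDTree(pos).query_pairs(two_r - tol, output_type="ndarray")
        if pairs.shape[0] == 0 and not np.any(inside):
            break
        if pairs.shape[0]:
            ii, jj = pairs[:, 0], pairs[:, 1]
            eij = pos[ii] - pos[jj]
            dij = np.linalg.norm(eij, axis=1)
            bad = dij < 1e-9
            if np.any(bad):
                eij[bad] = np.array([mech.random_unit_vector(st.rng)
                                     for _ in range(int(bad.sum()))])
                dij = np.maximum(dij, 1e-9)
            eij = eij / dij[:, None]
            # full half-gap correction, shared over each cell's overlap
            # count (position-based-dynamics style) so dense packings relax
            # without overshooting
            deg = np.bincount(pairs.ravel(), minlength=pos.shape[0])
            w = 1.0 / np.maximum(deg, 1)
            gap = (two_r - dij)[:, None] * eij
            np.add.at(pos, ii, 0.5 * w[ii, None] * gap)
            np.add.at(pos, jj, -0.5 * w[jj, None] * gap)
        if cj.shape[0]:
            ai, bi = cj[:, 0], cj[:, 1]
            eab = pos[ai] - pos[bi]
            dab = np.maximum(np.linalg.norm(eab, axis=1), 1e-9)
            stretch = dab > two_r * (1 + 1e-6)
            if np.any(stretch):
                pull = ((dab - two_r) / dab)[:, None] * eab
                degc = np.bincount(cj.ravel(), minlength=pos.shape[0])
                wc = 1.0 / np.maximum(degc, 1)
                np.add.at(pos, ai[stretch],
                          -0.5 * wc[ai[stretch], None] * pull[stretch])
                np.add.at(pos, bi[stretch],
                          0.5 * wc[bi[stretch], None] * pull[stretch])
    pos = np.clip(pos, r, L - r)
    for k, c in enumerate(st.cells):
        c.position = pos[k]


def _update_first_touch(st: SimulationState):
    pos = st.positions()
    if not len(pos):
        return
    touch = metr.touching_fiber(pos, st.params)
    for k, c in enumerate(st.cells):
        if touch[k] and c.id not in st.first_touch:
            st.first_touch[c.id] = st.time


def _record_metrics(st: SimulationState):
    cells = st.cells
    n = len(cells)
    labels, _ = _refresh_groups(st)
    from collections import Counter
    phen = Counter(c.phenotype for c in cells)
    if n:
        size, members, formed = metr.main_group_stats(labels, st.params)
        group_sizes = Counter(labels.tolist())
        n_groups = sum(1 for v in group_sizes.values() if v >= 2)
        ar = metr.aspect_ratio(st.positions()[members], st.params.r_cell) \
            if size >= 2 else 1.0
        mean_dist = float(metr.distance_to_fiber_axis(st.positions(),
                                                      st.params).mean())
    else:
        size, formed, n_groups, ar, mean_dist = 0, False, 0, 1.0, float("nan")
    if formed and st.main_group_formation_time is None:
        st.main_group_formation_time = st.time
    st.records.append({
        "time": st.time,
        "n_cells": n,
        "n_msc": phen.get("MSC", 0),
        "n_cm_early": phen.get("CM_early", 0),
        "n_cm_late": phen.get("CM_late", 0),
        "n_groups": n_groups,
        "main_group_size": size,
        "main_group_formed": bool(formed),
        "main_group_ar": ar,
        "mean_dist_to_fiber": mean_dist,
        "n_cj_edges": len(st.cj_edges),
    })


def step(st: SimulationState) -> SimulationState:
    """Advance the state by one time step (1 h by default)."""
    contacts = _sense_and_forces(st)
    _update_junctions(st, contacts)
    _fate_phase(st)
    _movement_phase(st)
    st.step_index += 1
    _update_first_touch(st)
    _record_metrics(st)
    return st


# ---------------------------------------------------------------------------
# scenario drivers
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    config: ScenarioConfig
    seed: int
    metrics: pd.DataFrame
    events: pd.DataFrame
    state: SimulationState
    manifest: dict

    @property
    def final(self) -> dict:
        return self.metrics.iloc[-1].to_dict()


def run_scenario(config: ScenarioConfig, seed: int,
                 progress: bool = False) -> ScenarioResult:
    st = init_state(config, seed)
    for _ in range(config.steps):
        step(st)
    metrics = pd.DataFrame(st.records)
    events = pd.DataFrame([dataclasses.asdict(e) for e in st.events],
                          columns=["time", "cell_id", "event"])
    arrivals = metr.summarize_arrival_times(st.first_touch, st.all_ids)
    manifest = {
        "scenario": config.name,
        "seed": int(seed),
        "steps": int(config.steps),
        "c_sub": float(st.ecm.c_sub),
        "f_ref": float(st.ecm.f_ref),
        "c_ef": float(config.params.c_ef),
        "zeta": float(config.params.zeta),
        "c_rep": float(config.params.c_rep),
        "params": config.params.to_dict(),
        "arrivals": arrivals,
        "main_group_formation_time": st.main_group_formation_time,
    }
    return ScenarioResult(config=config, seed=seed, metrics=metrics,
                          events=events, state=st, manifest=manifest)


def replicate_seeds(base_seed: int, n: int) -> list:
    """Deterministic disjoint replicate seeds derived from a base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n, dtype=np.uint32)]


def run_replicates(config: ScenarioConfig, n: int,
                   base_seed: int) -> List[ScenarioResult]:
    return [run_scenario(config, s) for s in replicate_seeds(base_seed, n)]


def aggregate_results(results: List[ScenarioResult]) -> pd.DataFrame:
    """Per-replicate headline numbers with a mean/sd footer."""
    rows = []
    for r in results:
        fin = r.final
        rows.append({
            "seed": r.seed,
            "final_n_cells": fin["n_cells"],
            "final_main_group_size": fin["main_group_size"],
            "final_main_group_ar": fin["main_group_ar"],
            "main_group_formation_time": r.manifest["main_group_formation_time"],
            "mean_time_to_fiber": r.manifest["arrivals"]["mean_time_to_fiber"],
            "n_censored": r.manifest["arrivals"]["n_censored"],
        })
    return pd.DataFrame(rows)
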