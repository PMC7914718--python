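"""Linear-elastic FEM of the fibered hydrogel block and compliance probes.

The matrix is a structured grid of trilinear hexahedra (2x2x2 Gauss
quadrature) covering the culture box, with per-element Young's modulus:
hydrogel everywhere except a hollow cylindrical fiber of stiffer material
along the central X axis.  At coarse resolutions the fiber wall is thinner
than an element, so elements are assigned a thickness-weighted blended
modulus (cross-section area fraction of fiber wall inside the element);
any element with a positive fiber fraction is tagged ``fiber``.

Cells do not deform this matrix; they *read* it.  The cell-scale quantity
is the effective substrate resistance K_sub sensed by a membrane node: a
unit contractile force dipole (the cell pulling against its own
footprint) applied at a location, the collinear relative displacement u
of its two adhesion patches read back, mapped to a stiffness through the
cell radius and a single global calibration constant c_sub,

    K_sub = c_sub * (f / u) / r_cell ,

normalized by the identical probe on the homogeneous fiber-free matrix so
that a uniform gel reads exactly E_ecm everywhere.  Self-equilibration
makes the probe sensitive to the local material (the fiber, the imposed
prestress) rather than to the distance from the free boundary.  The engine precomputes this field at element centers once per
load configuration and interpolates it; the point-probe operation solves
a single right-hand side and is the reference the field is checked
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .params import ModelParams


class MeshError(ValueError):
    pass


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

# corner order of a VTK hexahedron in natural coordinates
_XI_CORNERS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

_GAUSS = 1.0 / np.sqrt(3.0)


def _shape_gradients(xi: np.ndarray, h: float) -> np.ndarray:
    """(8, 3) physical gradients dN_a/dx at natural point xi, cube edge h."""
    g = np.empty((8, 3))
    for a in range(8):
        xa = _XI_CORNERS[a]
        g[a, 0] = xa[0] * (1 + xi[1] * xa[1]) * (1 + xi[2] * xa[2]) / 8.0
        g[a, 1] = xa[1] * (1 + xi[0] * xa[0]) * (1 + xi[2] * xa[2]) / 8.0
        g[a, 2] = xa[2] * (1 + xi[0] * xa[0]) * (1 + xi[1] * xa[1]) / 8.0
    return g * (2.0 / h)  # dxi/dx = 2/h


def _b_matrix(grad: np.ndarray) -> np.ndarray:
    """(6, 24) strain-displacement matrix (engineering shear) from gradients."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def elastic_matrix(E: float, nu: float) -> np.ndarray:
    """(6, 6) isotropic elasticity matrix (engineering shear convention)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def unit_hex_stiffness(nu: float, h: float) -> np.ndarray:
    """(24, 24) stiffness of a cube element of edge h with E = 1."""
    C = elastic_matrix(1.0, nu)
    K = np.zeros((24, 24))
    w = (h / 2.0) ** 3  # Jacobian determinant per Gauss point, weight 1
    for gx in (-_GAUSS, _GAUSS):
        for gy in (-_GAUSS, _GAUSS):
            for gz in (-_GAUSS, _GAUSS):
                B = _b_matrix(_shape_gradients(np.array([gx, gy, gz]), h))
                K += w * (B.T @ C @ B)
    return K


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass
class EcmMesh:
    """Structured hexahedral mesh of the culture box."""

    params: ModelParams
    resolution: float
    shape: tuple                 # (nx, ny, nz) element counts
    coords: np.ndarray           # (n_nodes, 3) node coordinates, um
    connectivity: np.ndarray     # (n_elems, 8) node ids, VTK hex order
    E_elem: np.ndarray           # (n_elems,) Young's modulus, kPa
    tag: np.ndarray              # (n_elems,) 0 = matrix, 1 = fiber
    fixed_dofs: np.ndarray = field(default=None)    # constrained dof ids
    fixed_vals: np.ndarray = field(default=None)    # imposed values, um

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_elems(self) -> int:
        return self.connectivity.shape[0]

    @property
    def axes(self) -> tuple:
        nx, ny, nz = self.shape
        L = self.params.domain
        return (np.linspace(0, L[0], nx + 1),
                np.linspace(0, L[1], ny + 1),
                np.linspace(0, L[2], nz + 1))

    def node_id(self, i: int, j: int, k: int) -> int:
        nx, ny, nz = self.shape
        return (i * (ny + 1) + j) * (nz + 1) + k

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        L = self.params.domain
        return bool(np.all(p >= 0) and np.all(p <= np.array(L)))

    def element_of(self, point) -> int:
        """Element index containing a point (half-open on upper boundaries)."""
        if not self.contains(point):
            raise MeshError(f"point {point} outside the domain")
        nx, ny, nz = self.shape
        h = self.resolution
        idx = np.minimum((np.asarray(point) / h).astype(int), [nx - 1, ny - 1, nz - 1])
        return int((idx[0] * ny + idx[1]) * nz + idx[2])


def _fiber_fraction(params: ModelParams, yc: np.ndarray, zc: np.ndarray,
                    h: float, nsub: int = 8) -> tuple:
    """Cross-section area fractions (wall, core) of each element.

    yc, zc are element-center transverse coordinates; the element section
    [yc-h/2, yc+h/2] x [zc-h/2, zc+h/2] is subsampled on an nsub x nsub grid.
    """
    ay, az = params.fiber_axis_yz
    r_out = params.fiber_outer_radius
    r_in = params.fiber_inner_radius
    offs = (np.arange(nsub) + 0.5) / nsub - 0.5
    dy, dz = np.meshgrid(offs * h, offs * h, indexing="ij")
    yy = yc[:, None, None] + dy[None]
    zz = zc[:, None, None] + dz[None]
    rr = np.hypot(yy - ay, zz - az)
    wall = ((rr <= r_out) & (rr >= r_in)).mean(axis=(1, 2))
    core = (rr < r_in).mean(axis=(1, 2))
    return wall, core


def build_mesh(params: ModelParams, resolution: Optional[float] = None,
               with_fiber: bool = True) -> EcmMesh:
    """Build the structured mesh with matrix/fiber element moduli.

    ``resolution`` must divide every domain dimension.  At coarse
    resolutions the fiber modulus is blended by cross-section area
    fraction (thickness-weighted tagging).
    """
    p = params
    h = float(resolution if resolution is not None else p.resolution)
    L = np.array(p.domain)
    n = L / h
    if not np.allclose(n, np.round(n)):
        raise MeshError(f"resolution {h} does not divide domain {p.domain}")
    nx, ny, nz = (int(round(v)) for v in n)

    xs, ys, zs = (np.linspace(0, L[d], c + 1) for d, c in enumerate((nx, ny, nz)))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    conn = np.column_stack([
        nid(ii, jj, kk), nid(ii + 1, jj, kk), nid(ii + 1, jj + 1, kk),
        nid(ii, jj + 1, kk), nid(ii, jj, kk + 1), nid(ii + 1, jj, kk + 1),
        nid(ii + 1, jj + 1, kk + 1), nid(ii, jj + 1, kk + 1)])

    E_elem = np.full(conn.shape[0], p.E_ecm)
    tag = np.zeros(conn.shape[0], dtype=int)
    if with_fiber:
        yc = (jj + 0.5) * h
        zc = (kk + 0.5) * h
        wall, core = _fiber_fraction(p, yc, zc, h)
        E_elem = E_elem + wall * (p.E_fib - p.E_ecm)
        if p.fiber_core == "void":
            # near-zero core modulus keeps the system definite
            E_elem = E_elem + core * (1e-3 * p.E_ecm - p.E_ecm)
        tag[wall > 0] = 1
        if tag.sum() == 0:
            raise MeshError("no element was tagged as fiber; refine the mesh "
                            "or increase fiber dimensions")
    return EcmMesh(params=p, resolution=h, shape=(nx, ny, nz), coords=coords,
                   connectivity=conn, E_elem=E_elem, tag=tag)


# ---------------------------------------------------------------------------
# boundary conditions, assembly, solve
# ---------------------------------------------------------------------------

def _boundary_conditions(mesh: EcmMesh, applied_strain: float):
    """3-2-1 rigid-body constraints plus imposed end-plane X displacements.

    The minimal point constraints contain the published set (p1: Ux=Uy=0,
    p2: Uy=Uz=0) and complete it so all six rigid-body modes are removed:
    p1=(0,0,0) fixes x,y,z; p2=(Lx,0,0) fixes y,z; p3=(0,Ly,0) fixes z.
    With an applied strain, u_x = 0 on the X0 plane and u_x = strain*Lx on
    the far plane (equal to the +-strain*Lx/2 convention up to a rigid
    translation).
    """
    nx, ny, nz = mesh.shape
    fixed = {}
    p1 = mesh.node_id(0, 0, 0)
    p2 = mesh.node_id(nx, 0, 0)
    p3 = mesh.node_id(0, ny, 0)
    for dof in (3 * p1, 3 * p1 + 1, 3 * p1 + 2):
        fixed[dof] = 0.0
    fixed[3 * p2 + 1] = 0.0
    fixed[3 * p2 + 2] = 0.0
    fixed[3 * p3 + 2] = 0.0
    if applied_strain > 0:
        Lx = mesh.params.domain[0]
        on_x0 = np.isclose(mesh.coords[:, 0], 0.0)
        on_xL = np.isclose(mesh.coords[:, 0], Lx)
        for nid in np.flatnonzero(on_x0):
            fixed[3 * nid] = 0.0
        for nid in np.flatnonzero(on_xL):
            fixed[3 * nid] = applied_strain * Lx
    dofs = np.array(sorted(fixed), dtype=int)
    vals = np.array([fixed[d] for d in dofs])
    return dofs, vals


def assemble_stiffness(mesh: EcmMesh) -> sp.csr_matrix:
    """Global stiffness matrix (kPa um -> force in nN per um displacement)."""
    Ku = unit_hex_stiffness(mesh.params.nu, mesh.resolution)
    conn = mesh.connectivity
    ne = conn.shape[0]
    edofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    vals = (mesh.E_elem[:, None, None] * Ku[None]).ravel()
    ndof = 3 * mesh.n_nodes
    K = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


@dataclass
class FemSolution:
    """Solved displacement/strain state of the matrix under a load case."""

    mesh: EcmMesh
    displacement: np.ndarray        # (n_nodes, 3), um
    strain: np.ndarray              # (n_elems, 6) engineering strain at centroid
    stress: np.ndarray              # (n_elems, 6), kPa
    residual: float
    applied_strain: float
    _lu: object = None              # factorization of the reduced system
    _free: np.ndarray = None        # free dof ids
    _ndof: int = 0
    _probe: object = None           # lazily built ProbeOperator

    def solve_free(self, rhs_free: np.ndarray) -> np.ndarray:
        """Solve the constrained system for extra right-hand sides."""
        return self._lu.solve(rhs_free)

    def probe_operator(self) -> "ProbeOperator":
        if self._probe is None:
            self._probe = ProbeOperator(self.mesh, self.applied_strain)
        return self._probe


def _centroid_B(h: float) -> np.ndarray:
    return _b_matrix(_shape_gradients(np.zeros(3), h))


def solve_displacements(mesh: EcmMesh, applied_strain: float = 0.0) -> FemSolution:
    """Solve the linear-elastic system under the imposed boundary strain."""
    if applied_strain < 0:
        raise MeshError("applied_strain must be >= 0")
    K = assemble_stiffness(mesh)
    ndof = K.shape[0]
    fixed, vals = _boundary_conditions(mesh, applied_strain)
    mesh.fixed_dofs, mesh.fixed_vals = fixed, vals
    free = np.setdiff1d(np.arange(ndof), fixed)
    u = np.zeros(ndof)
    u[fixed] = vals
    rhs = -K[:, fixed] @ vals
    Kff = K[free][:, free].tocsc()
    try:
        lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A")
    except RuntimeError as exc:  # pragma: no cover - singular system guard
        raise MeshError(f"singular stiffness system: {exc}") from exc
    u[free] = lu.solve(rhs[free])
    residual = float(np.linalg.norm((K @ u)[free]))

    B0 = _centroid_B(mesh.resolution)
    conn = mesh.connectivity
    edofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    ue = u[edofs]                               # (ne, 24)
    strain = ue @ B0.T                          # (ne, 6)
    Cu = elastic_matrix(1.0, mesh.params.nu)
    stress = (strain @ Cu.T) * mesh.E_elem[:, None]
    return FemSolution(mesh=mesh, displacement=u.reshape(-1, 3), strain=strain,
                       stress=stress, residual=residual,
                       applied_strain=applied_strain,
                       _lu=lu, _free=free, _ndof=ndof)


# ---------------------------------------------------------------------------
# probe operator: free-floating compliance
# ---------------------------------------------------------------------------

class ProbeOperator:
    """Solves probe load cases as if the gel extended beyond the box.

    The compliance a cell senses should reflect the local material, not
    the distance to the free surface of the finite culture block (the gel
    is homogeneous up to its boundary, and the reference model reads a
    uniform stimulus there).  Symmetry (roller) boundary conditions on
    all six faces — normal displacement fixed, tangential free — make
    each face a mirror plane, so a probe near a wall sees its own image
    continuation instead of free-surface softening; the leading image
    correction of a self-equilibrated dipole decays with the cube of the
    wall distance.  The rollers also remove every rigid-body mode, so the
    system is definite without point constraints.
    """

    def __init__(self, mesh: EcmMesh, applied_strain: float = 0.0):
        K = assemble_stiffness(mesh)
        ndof = K.shape[0]
        L = np.array(mesh.params.domain)
        fixed = []
        for d in range(3):
            on_face = np.isclose(mesh.coords[:, d], 0.0) | \
                np.isclose(mesh.coords[:, d], L[d])
            fixed.append(3 * np.flatnonzero(on_face) + d)
        fixed = np.unique(np.concatenate(fixed))
        free = np.setdiff1d(np.arange(ndof), fixed)
        self._lu = spla.splu(K[free][:, free].tocsc(),
                             permc_spec="MMD_AT_PLUS_A")
        self._free = free
        self._ndof = ndof
        self.mesh = mesh
        self.applied_strain = applied_strain

    def _solve_free(self, rf: np.ndarray) -> np.ndarray:
        return self._lu.solve(rf)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Displacement response (ndof,) or (ndof, m) to probe load(s)."""
        rhs = np.asarray(rhs, dtype=float)
        single = rhs.ndim == 1
        rf = rhs.reshape(self._ndof, -1)[self._free]
        out = np.zeros((self._ndof, rf.shape[1]))
        out[self._free] = self._solve_free(rf)
        return out[:, 0] if single else out


# ---------------------------------------------------------------------------
# compliance probes
# ---------------------------------------------------------------------------

def _point_load_weights(mesh: EcmMesh, point: np.ndarray):
    """Consistent nodal distribution of a point force: trilinear weights on
    the 8 corners of the containing element."""
    h = mesh.resolution
    e = mesh.element_of(point)
    nodes = mesh.connectivity[e]
    x0 = mesh.coords[nodes[0]]
    t = np.clip((np.asarray(point, dtype=float) - x0) / h, 0.0, 1.0)
    w = np.empty(8)
    for a, xa in enumerate(_XI_CORNERS):
        fx = (1 - t[0]) if xa[0] < 0 else t[0]
        fy = (1 - t[1]) if xa[1] < 0 else t[1]
        fz = (1 - t[2]) if xa[2] < 0 else t[2]
        w[a] = fx * fy * fz
    return nodes, w


def _reflect_into_domain(x: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Mirror a point back into the box (image method): probe samples that
    would fall outside the gel are folded inward, so a probe at the wall
    reads the same material as an interior one instead of the free-surface
    compliance (the cultured gel is homogeneous up to its boundary)."""
    out = np.abs(np.asarray(x, dtype=float))
    over = out > L
    out[over] = 2 * L[over] - out[over]
    return np.clip(out, 0.0, L)


def _patch_dofs_weights(mesh: EcmMesh, point: np.ndarray, samples: int = 3):
    """Load distribution of a physical adhesion patch centered at ``point``.

    The patch is a cube of side r_cell sampled on a samples^3 lattice;
    each sample is spread trilinearly onto its containing element, so the
    distribution has a fixed physical size independent of the mesh
    resolution.  Sample positions are mirrored into the domain.  Returns
    (node ids, weights) with weights summing to 1.
    """
    p = mesh.params
    half = p.r_cell / 2.0
    offs = (np.arange(samples) + 0.5) / samples - 0.5
    acc = {}
    L = np.array(p.domain)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                s = _reflect_into_domain(np.asarray(point, dtype=float)
                                         + 2 * half * np.array([ox, oy, oz]), L)
                nodes, w = _point_load_weights(mesh, s)
                for nid, wa in zip(nodes, w):
                    acc[nid] = acc.get(nid, 0.0) + wa / samples ** 3
    nids = np.fromiter(acc.keys(), dtype=int)
    ws = np.fromiter(acc.values(), dtype=float)
    return nids, ws


def _dipole_rhs_and_reader(mesh: EcmMesh, point, direction):
    """Self-equilibrated dipole load for a compliance probe.

    A cell measures its surroundings against itself: a unit contractile
    force pair (+f at point + r*d, -f at point - r*d, each spread over an
    adhesion patch).  The reader functional returns the relative approach
    of the two patches.  Self-equilibration makes the probe insensitive
    to far boundaries and rigid-body handling.
    """
    p = mesh.params
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    L = np.array(p.domain)
    x_plus = _reflect_into_domain(np.asarray(point, dtype=float)
                                  + p.r_cell * d, L)
    x_minus = _reflect_into_domain(np.asarray(point, dtype=float)
                                   - p.r_cell * d, L)
    rhs = np.zeros(3 * mesh.n_nodes)
    reader = np.zeros(3 * mesh.n_nodes)
    for sign, x in ((1.0, x_plus), (-1.0, x_minus)):
        nids, ws = _patch_dofs_weights(mesh, x)
        for nid, wa in zip(nids, ws):
            rhs[3 * nid:3 * nid + 3] += sign * wa * d
            reader[3 * nid:3 * nid + 3] += sign * wa * d
    return rhs, reader


def raw_probe(operator: ProbeOperator, point, direction) -> float:
    """Uncalibrated dipole-probe stiffness (f/u)/r_cell at a point."""
    mesh = operator.mesh
    rhs, reader = _dipole_rhs_and_reader(mesh, point, direction)
    u = operator.solve(rhs)
    u_col = float(reader @ u)
    if u_col <= 0:
        raise MeshError("non-positive colinear probe displacement")
    return (1.0 / u_col) / mesh.params.r_cell


_REFERENCE_OP_CACHE: dict = {}


def _reference_probe_operator(params: ModelParams,
                              resolution: Optional[float] = None) -> ProbeOperator:
    mesh = build_mesh(params, resolution=resolution, with_fiber=False)
    key = _raw_field_key(mesh, homogeneous=True) + ("op",)
    if key not in _REFERENCE_OP_CACHE:
        _REFERENCE_OP_CACHE[key] = ProbeOperator(mesh)
    return _REFERENCE_OP_CACHE[key]


def probe_compliance(solution: FemSolution, point, direction,
                     c_sub: Optional[float] = None) -> float:
    """Effective substrate resistance K_sub (kPa) at a point and direction.

    Applies a unit contractile force dipole along ``direction`` (the
    cell's sensing pull against its own footprint), reads the collinear
    relative displacement of the two adhesion patches, and normalizes by
    the identical probe on the homogeneous fiber-free matrix so that
    discretization and boundary effects divide out:

        K_sub = c_sub * E_ecm * probe(fibered) / probe(homogeneous).

    A homogeneous matrix therefore reads exactly c_sub * E_ecm anywhere;
    the stiffer fiber reads proportionally higher.  With ``c_sub`` omitted
    the uncalibrated (c_sub = 1) value is returned.
    """
    mesh = solution.mesh
    if not mesh.contains(point):
        raise MeshError(f"point {point} outside the domain")
    k_fib = raw_probe(solution.probe_operator(), point, direction)
    k_hom = raw_probe(_reference_probe_operator(mesh.params, mesh.resolution),
                      point, direction)
    val = mesh.params.E_ecm * k_fib / k_hom
    return val * (c_sub if c_sub is not None else 1.0)


# ---------------------------------------------------------------------------
# precomputed nodal stiffness field
# ---------------------------------------------------------------------------

def compute_raw_field(mesh: EcmMesh, chunk: int = 1024) -> np.ndarray:
    """(ne, 3) uncalibrated dipole-probe stiffness at every element center
    along each coordinate direction (independent of the load state)."""
    op = ProbeOperator(mesh)
    ndof = op._ndof
    free_mask = np.zeros(ndof, dtype=bool)
    free_mask[op._free] = True
    pos_in_free = np.cumsum(free_mask) - 1              # dof id -> row in free
    ne = mesh.n_elems
    h = mesh.resolution
    nx, ny, nz = mesh.shape
    ii = np.arange(ne) // (ny * nz)
    jj = (np.arange(ne) // nz) % ny
    kk = np.arange(ne) % nz
    centers_xyz = np.column_stack([(ii + 0.5) * h, (jj + 0.5) * h,
                                   (kk + 0.5) * h])
    eye = np.eye(3)
    comp = np.zeros((ne, 3))
    probes = [(e, d) for e in range(ne) for d in range(3)]
    n_free = op._free.size
    for start in range(0, len(probes), chunk):
        batch = probes[start:start + chunk]
        rhs = np.zeros((n_free, len(batch)))
        readers = []
        for col, (e, d) in enumerate(batch):
            load, reader = _dipole_rhs_and_reader(mesh, centers_xyz[e], eye[d])
            nzd = np.flatnonzero(load)
            ok = free_mask[nzd]
            rhs[pos_in_free[nzd[ok]], col] = load[nzd[ok]]
            readers.append((pos_in_free[nzd[ok]], reader[nzd[ok]]))
        sol = op._solve_free(rhs)
        for col, (e, d) in enumerate(batch):
            rows, w = readers[col]
            comp[e, d] = w @ sol[rows, col]
    k_raw = (1.0 / comp) / mesh.params.r_cell            # kPa, uncalibrated
    return k_raw.reshape(nx, ny, nz, 3)


#: Raw probe fields cached per geometry (they are load-independent).
_RAW_FIELD_CACHE: dict = {}


def _raw_field_key(mesh: EcmMesh, homogeneous: bool) -> tuple:
    p = mesh.params
    key = (p.domain, mesh.resolution, p.nu, p.E_ecm, p.r_cell)
    if not homogeneous:
        key += (p.E_fib, p.fiber_outer_diam, p.fiber_thickness, p.fiber_core)
    return key + (homogeneous,)


def _cached_raw_field(mesh: EcmMesh) -> np.ndarray:
    # a mesh without tagged fiber elements is the homogeneous reference
    key = _raw_field_key(mesh, homogeneous=bool(mesh.tag.sum() == 0))
    if key not in _RAW_FIELD_CACHE:
        _RAW_FIELD_CACHE[key] = compute_raw_field(mesh)
    return _RAW_FIELD_CACHE[key]


def _reference_raw_field(params: ModelParams,
                         resolution: Optional[float] = None) -> np.ndarray:
    """Probe field of the homogeneous (fiber-free) matrix with the same
    operator; the denominator that cancels geometric probe artifacts."""
    mesh = build_mesh(params, resolution=resolution, with_fiber=False)
    key = _raw_field_key(mesh, homogeneous=True)
    if key not in _RAW_FIELD_CACHE:
        _RAW_FIELD_CACHE[key] = compute_raw_field(mesh)
    return _RAW_FIELD_CACHE[key]


class SubstrateField:
    """Interpolated per-axis substrate-resistance field K_sub(x, e).

    Sampled at element centers with the self-equilibrated dipole probe of
    :func:`probe_compliance` and normalized by the same probe applied to
    the homogeneous (fiber-free) matrix, so every geometric artifact of
    probing a finite discretized block divides out: a homogeneous gel is
    sensed as exactly homogeneous, and only material heterogeneity (the
    stiffer fiber) and load-induced stiffening modulate the reading.  A
    direction-resolved value is assembled as the quadratic form
    sum_d K_d(x) e_d^2.  Under an applied strain the X component is
    augmented by the local prestress ratio sigma_xx/E (geometric
    stiffening of the loaded direction).
    """

    def __init__(self, solution: FemSolution, chunk: int = 1024):
        mesh = solution.mesh
        nx, ny, nz = mesh.shape
        k_raw = _cached_raw_field(mesh)
        k_hom = _reference_raw_field(mesh.params, resolution=mesh.resolution)
        # normalized reading: the homogeneous matrix is sensed as exactly
        # E_ecm, the fiber as proportionally stiffer
        self._k_elem = mesh.params.E_ecm * (k_raw / k_hom)

        if solution.applied_strain > 0:
            ratio = (solution.stress[:, 0]
                     / mesh.E_elem).reshape(nx, ny, nz)  # sigma_xx / E
            self._k_elem = self._k_elem.copy()
            self._k_elem[..., 0] *= (1.0 + ratio)
        h = mesh.resolution
        L = mesh.params.domain
        centers = tuple(np.linspace(h / 2, L[d] - h / 2, s)
                        for d, s in enumerate(mesh.shape))
        self._centers = centers
        self._interp = RegularGridInterpolator(
            centers, self._k_elem, bounds_error=False, fill_value=None)
        self.mesh = mesh
        self.c_sub = 1.0

    def k_axis(self, points: np.ndarray) -> np.ndarray:
        """(n, 3) per-axis raw*c_sub stiffness at points (clipped to the
        element-center lattice)."""
        pts = np.atleast_2d(points).copy()
        for d in range(3):
            pts[:, d] = np.clip(pts[:, d], self._centers[d][0],
                                self._centers[d][-1])
        return self._interp(pts) * self.c_sub

    def k_sub(self, points: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Direction-resolved substrate resistance, kPa.

        ``points`` (n, 3) and ``directions`` (n, 3) unit vectors.
        """
        ka = self.k_axis(points)
        d2 = np.atleast_2d(directions) ** 2
        return np.einsum("nd,nd->n", ka, d2)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _candidate_cell_grid(params: ModelParams, stride: float = 20.0) -> np.ndarray:
    """Admissible cell-center positions on a regular grid: at least r_cell
    from every wall and clear of the fiber surface."""
    L = params.domain
    r = params.r_cell
    axes = [np.arange(r, L[d] - r + 1e-9, stride) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    ay, az = params.fiber_axis_yz
    dist = np.hypot(pts[:, 1] - ay, pts[:, 2] - az)
    return pts[dist >= params.fiber_outer_radius + r]


def _cell_node_stiffness(field: SubstrateField, centers: np.ndarray,
                         params: ModelParams) -> np.ndarray:
    """(n, 24) raw substrate stiffness at the membrane nodes of cells
    centered at ``centers``."""
    from .membrane import DIRECTIONS

    centers = np.atleast_2d(centers)
    n = centers.shape[0]
    pts = (centers[:, None, :] + params.r_cell * DIRECTIONS[None]).reshape(-1, 3)
    dirs = np.tile(DIRECTIONS, (n, 1))
    return field.k_sub(pts, dirs).reshape(n, 24)


def cell_sensed_stimulus(field: SubstrateField, centers: np.ndarray,
                         params: ModelParams, c_sub: float = None) -> np.ndarray:
    """Mean equilibrium strain over the 24 membrane nodes for cells at
    ``centers`` (vectorized; all nodes active)."""
    from .mechanics import equilibrium_strain

    k = _cell_node_stiffness(field, centers, params)
    if c_sub is not None:
        k = k * c_sub
    eps = equilibrium_strain(k, params)
    return eps.mean(axis=1)


def calibrate_c_sub(field: SubstrateField, params: ModelParams,
                    stride: float = 20.0) -> float:
    """Calibrate the substrate constant so the most compliant admissible
    cell position senses exactly ``params.gamma_target``.

    With gamma_target = -0.02625 the fastest possible maturation time is
    t_min + t_p*gamma = 18 h, anchoring the earliest differentiation event;
    every stiffer position then senses a weaker (less negative) stimulus.
    Monotone in c_sub, solved by bisection.
    """
    assert field.c_sub == 1.0, "calibrate on an uncalibrated field"
    centers = _candidate_cell_grid(params, stride)
    target = params.gamma_target
    k_raw = _cell_node_stiffness(field, centers, params)
    a, b = params.mid_branch_intercept, params.mid_branch_slope

    def min_gamma(c):
        return float((-a / (b + c * k_raw)).mean(axis=1).min())

    lo, hi = 1e-6, 1e6
    glo, ghi = min_gamma(lo), min_gamma(hi)
    if not (glo < target < ghi):
        raise MeshError("calibration target outside achievable stimulus range")
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if min_gamma(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def reference_traction_force(field: SubstrateField, params: ModelParams,
                             stride: float = 20.0) -> float:
    """Median traction resultant (nN) over admissible cell positions in
    the calibrated field; the typical migration drive, and the scale the
    repulsion constant is anchored to.  The median rather than the mean:
    the soft boundary layer produces outlier resultants that would
    otherwise set a contact barrier far above the bulk drive."""
    from .membrane import DIRECTIONS
    from .mechanics import equilibrium_strain, internal_stress

    centers = _candidate_cell_grid(params, stride)
    k = _cell_node_stiffness(field, centers, params)
    eps = equilibrium_strain(k, params)
    sig = internal_stress(eps, params)
    scale = params.node_area * params.zeta
    res = scale * np.einsum("ni,id->nd", sig, DIRECTIONS)
    return float(np.median(np.linalg.norm(res, axis=1)))


@dataclass
class EcmModel:
    """Bundle: mesh + solved load case + calibrated substrate field."""

    mesh: EcmMesh
    solution: FemSolution
    field: SubstrateField
    c_sub: float
    f_ref: float = 0.0        # median traction resultant, nN (set on retrieval)

    @classmethod
    def build(cls, params: ModelParams, resolution: Optional[float] = None,
              with_fiber: bool = True,
              c_sub: Optional[float] = None) -> "EcmModel":
        mesh = build_mesh(params, resolution=resolution, with_fiber=with_fiber)
        sol = solve_displacements(mesh, params.applied_strain)
        field = SubstrateField(sol)
        if c_sub is None:
            c_sub = params.c_sub
        if c_sub is None:
            c_sub = calibrate_c_sub(field, params)
        field.c_sub = float(c_sub)
        return cls(mesh=mesh, solution=sol, field=field, c_sub=float(c_sub))
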