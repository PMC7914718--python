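"""Model parameters and their invariants.

Single source of truth for every symbol used by the simulator.  Internal
unit system: micrometre (length), hour (time), kilopascal (stress).  In
these units a force comes out in kPa*um^2 = nanonewton, which is the
natural scale of single-cell tractions.  Electrical quantities (field in
V/m, charge density in C/m^2) are converted to nN inside the force laws.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: Coulomb constant, N m^2 C^-2 (physical constant).
K_COULOMB = 8.988e9

#: Hours per day, used to express the day-scale maturation constants.
HOURS_PER_DAY = 24.0


class ParamError(ValueError):
    """A model parameter violates one of its invariants."""


@dataclass
class ModelParams:
    """All tunable constants of the model plus geometry/numerics knobs.

    Defaults are the reference parameter set of the model (cell stiffnesses,
    strain bounds, stimulus windows, maturation times) together with the
    standard culture geometry: an 800x400x400 um hydrogel block with a
    hollow stiffer fiber of 40 um outer diameter along the central X axis.
    """

    # -- cell contractile machinery -------------------------------------
    K_pas: float = 2.8          # passive element stiffness, kPa
    K_act: float = 7.0          # actin-myosin stiffness, kPa
    sigma_max: float = 0.25     # max contractile stress, kPa
    eps_max: float = 0.09       # upper strain bound of active force generation
    eps_min: float = -0.09      # lower strain bound
    eps_tilde: float = field(default=0.0)  # strain of max force; derived sigma_max/K_act

    # -- ECM material ----------------------------------------------------
    nu: float = 0.4             # Poisson ratio (matrix and fiber)
    E_ecm: float = 20.0         # matrix Young's modulus, kPa
    E_fib: float = 25.0         # fiber Young's modulus, kPa
    eta: float = 1000.0         # ECM viscosity, Pa s

    # -- adhesion / traction scale --------------------------------------
    k_bind: float = 1e8         # binding constant, mol^-1
    n_r: float = 1.5e5          # receptor count
    psi: float = 1e-5           # ligand concentration, mol
    zeta: float = 1.0           # dimensionless adhesivity (k*n_r*psi normalized
                                # by its printed value); keeps tractions O(nN)

    # -- electrical ------------------------------------------------------
    E_sat: float = 1200.0       # electric-field saturation, V/m
    Omega: float = 5e-2         # cell surface charge density, C/m^2
    k_e: float = K_COULOMB      # Coulomb constant, N m^2 C^-2
    eps_r: float = 80.0         # relative permittivity of the hydrogel

    # -- junctions and fate ----------------------------------------------
    l_adh: float = 0.50         # minimum contact projection for a junction
    CJ_max: int = 4             # junction count at which the cell cycle arrests
    t_min: float = 6.0 * HOURS_PER_DAY    # minimum maturation time, h
    t_p: float = 200.0 * HOURS_PER_DAY    # proportional maturation time, h
    gamma_min: float = -0.04    # differentiation window, lower stimulus bound
    gamma_max: float = -0.01    # differentiation window, upper stimulus bound
    gamma_apop: float = 0.6     # apoptosis stimulus threshold

    # -- cell and domain geometry ----------------------------------------
    r_cell: float = 10.0        # cell radius, um
    dt: float = 1.0             # time step, h
    n_nodes: int = 24           # membrane sensing nodes per cell
    domain: tuple = (800.0, 400.0, 400.0)   # box dimensions, um
    fiber_outer_diam: float = 40.0          # fiber outer diameter, um
    fiber_thickness: float = 18.0           # fiber wall thickness, um
    fiber_core: str = "hydrogel"            # hollow core fill: hydrogel | void
    applied_strain: float = 0.0             # imposed longitudinal strain

    # -- numerics / population -------------------------------------------
    resolution: float = 40.0    # FEM element edge length, um
    contact_tol: float = 0.02   # relative band on ||Xij|| = 2r for contact;
                                # covers the slack the pairwise overlap
                                # resolver leaves in jammed packings
    separation_tol: float = 0.25  # relative band beyond 2r before a CJ
                                  # dissolves; junctions tolerate transient
                                  # stretch from crowding resolution
    relocation_threshold: float = 0.1  # stalled-group speed threshold, x r_cell/dt
    main_group_fraction: float = 0.55
    n_cells: int = 60
    n_replicates: int = 10
    seed: int = 0

    # -- calibration constants (recorded in every run manifest) ----------
    gamma_target: float = -0.02625  # bulk stimulus the substrate constant is
                                    # calibrated to (t_min + t_p*gamma = 18 h)
    c_sub: Optional[float] = None   # substrate-stiffness calibration; None =
                                    # auto-calibrate on the scenario mesh
    c_rep: Optional[float] = None   # cell-cell repulsion scale; None = derive
                                    # so repulsion = traction scale at r = 2.5 r_cell
    c_ef: Optional[float] = None    # electrotactic force scale; None = derive so
                                    # the saturated field force equals the cell's
                                    # maximal nodal motor force

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @property
    def membrane_area(self) -> float:
        """Total membrane surface S = 4 pi r^2, um^2."""
        return 4.0 * math.pi * self.r_cell ** 2

    @property
    def node_area(self) -> float:
        """Per-node membrane area share S/n, um^2."""
        return self.membrane_area / self.n_nodes

    @property
    def membrane_area_m2(self) -> float:
        """Total membrane surface in m^2 (for electrical force laws)."""
        return self.membrane_area * 1e-12

    @property
    def eta_int(self) -> float:
        """Viscosity in internal units, kPa h."""
        return self.eta * 1e-3 / 3600.0

    @property
    def fiber_outer_radius(self) -> float:
        return self.fiber_outer_diam / 2.0

    @property
    def fiber_inner_radius(self) -> float:
        return self.fiber_outer_radius - self.fiber_thickness

    @property
    def fiber_axis_yz(self) -> tuple:
        """(y, z) of the fiber axis: center of the transverse cross-section."""
        return (self.domain[1] / 2.0, self.domain[2] / 2.0)

    # Piecewise contraction law, middle branch written as sigma = a + b*eps.
    @property
    def mid_branch_intercept(self) -> float:
        """a = K_act*sigma_max*eps_min / (K_act*eps_min - sigma_max), kPa."""
        return (self.K_act * self.sigma_max * self.eps_min
                / (self.K_act * self.eps_min - self.sigma_max))

    @property
    def mid_branch_slope(self) -> float:
        """b = K_pas - K_act*sigma_max / (K_act*eps_min - sigma_max), kPa."""
        return (self.K_pas - self.K_act * self.sigma_max
                / (self.K_act * self.eps_min - self.sigma_max))

    def substrate_stiffness_for_stimulus(self, gamma: float) -> float:
        """Substrate stiffness (kPa) at which the equilibrium strain equals gamma."""
        a, b = self.mid_branch_intercept, self.mid_branch_slope
        if gamma >= 0:
            raise ParamError("gamma must be negative (contraction)")
        return a / (-gamma) - b

    def derive_c_ef(self) -> float:
        """Electrotactic force scale so the saturated field force equals the
        maximal nodal motor force a*(S/n)*zeta (the bare E*Omega*S with the
        printed constants would drive cells two orders of magnitude faster
        than any other force in the model)."""
        f_max_nodal = self.mid_branch_intercept * self.node_area * self.zeta
        f_sat_raw = 1e9 * self.E_sat * self.Omega * self.membrane_area_m2
        return f_max_nodal / f_sat_raw

    def derive_c_rep(self, f_ref: float) -> float:
        """Repulsion scale so cell-cell repulsion equals the reference
        traction force ``f_ref`` (nN) at a center separation of 2.5 r_cell.

        The engine passes the typical (median) traction resultant of the
        calibrated matrix: repulsion then balances the migration drive at
        contact range instead of acting as a long-range population
        pressure, which would preclude aggregation.
        """
        r0_m = 2.5 * self.r_cell * 1e-6
        qs = self.Omega * self.membrane_area_m2               # C
        raw_nN = 1e9 * (self.k_e / self.eps_r) * qs * qs / (r0_m * r0_m)
        return f_ref / raw_nN

    # ------------------------------------------------------------------
    # validation / serialization
    # ------------------------------------------------------------------
    def validate(self) -> "ModelParams":
        """Return a copy with derived fields filled; raise on any violated
        invariant, naming the offending field."""
        p = dataclasses.replace(self)
        if p.sigma_max <= 0:
            raise ParamError("sigma_max must be > 0")
        if not (p.K_act > p.K_pas > 0):
            raise ParamError("K_act > K_pas > 0 required (K_act, K_pas)")
        p.eps_tilde = p.sigma_max / p.K_act
        if not (p.eps_min < 0 < p.eps_tilde < p.eps_max):
            raise ParamError(
                "eps_min < 0 < eps_tilde < eps_max violated "
                f"(eps_min={p.eps_min}, eps_tilde={p.eps_tilde}, eps_max={p.eps_max})")
        if not (p.gamma_min < p.gamma_max < 0 < p.gamma_apop):
            raise ParamError(
                "gamma_min < gamma_max < 0 < gamma_apop violated "
                f"(gamma_min={p.gamma_min}, gamma_max={p.gamma_max}, "
                f"gamma_apop={p.gamma_apop})")
        if not (0 < p.fiber_thickness < p.fiber_outer_diam / 2.0):
            raise ParamError("fiber_thickness must lie in (0, fiber_outer_diam/2)")
        if not (2.0 * p.r_cell < min(p.domain)):
            raise ParamError("2*r_cell must be smaller than every domain dimension")
        if p.eta <= 0:
            raise ParamError("eta must be > 0")
        if p.dt <= 0:
            raise ParamError("dt must be > 0")
        if p.n_nodes != 24:
            raise ParamError("n_nodes is fixed at 24 (rhombicuboctahedral membrane)")
        if not (0 < p.l_adh <= 1):
            raise ParamError("l_adh must lie in (0, 1]")
        if p.t_min <= 0 or p.t_p <= 0:
            raise ParamError("t_min and t_p must be > 0 (t_min, t_p)")
        if not (p.gamma_min < p.gamma_target < p.gamma_max):
            raise ParamError("gamma_target must lie inside (gamma_min, gamma_max)")
        if p.applied_strain < 0:
            raise ParamError("applied_strain must be >= 0")
        if p.fiber_core not in ("hydrogel", "void"):
            raise ParamError("fiber_core must be 'hydrogel' or 'void'")
        # c_rep stays None when unset: the engine anchors it to the typical
        # traction resultant of the calibrated substrate field
        if p.c_ef is None:
            p.c_ef = p.derive_c_ef()
        p.domain = tuple(float(d) for d in p.domain)
        return p

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["domain"] = list(self.domain)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParamError(f"unknown parameter(s): {sorted(unknown)}")
        d = dict(d)
        if "domain" in d:
            d["domain"] = tuple(d["domain"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate(params: ModelParams) -> ModelParams:
    """Functional alias for :meth:`ModelParams.validate`."""
    return params.validate()
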