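"""Electric field generated by the strained piezoelectric fiber.

Two modes are offered.  ``lookup`` maps the fiber wall thickness to the
field magnitude the deformed fiber induces in the surrounding hydrogel
(defaults 2->50, 5->75, 10->100, 18->200 V/m, linearly interpolated); it
is the default because it needs no piezoelectric material constants.
``constitutive`` is a reduced radially-polarized shell model for users who
do have material data: the longitudinal stress E_fib*strain drives an
electric displacement d*sigma across the wall, a wall field q/D_r and a
surface potential V = field*thickness; the hydrogel field is V over the
fiber-to-boundary gap.  The outer surface takes the positive charge, so
the field points radially inward and drives cells toward the fiber.

The field magnitude is returned raw; saturation (E_sat) is applied by the
electric force law, never here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ModelParams

#: Default thickness (um) -> ECM field magnitude (V/m) calibration.
DEFAULT_LOOKUP = ((2.0, 50.0), (5.0, 75.0), (10.0, 100.0), (18.0, 200.0))


class FieldConfigError(ValueError):
    pass


@dataclass
class PiezoConstants:
    """Reduced material constants for the constitutive mode.

    d: effective piezoelectric strain coefficient, C/N (charge per stress);
    D_r: radial dielectric permittivity, F/m.
    """

    d: float
    D_r: float


@dataclass
class ElectricFieldModel:
    """Field magnitude/direction experienced by a cell."""

    mode: str = "off"                      # off | lookup | constitutive
    lookup: tuple = DEFAULT_LOOKUP
    piezo: Optional[PiezoConstants] = None
    warned_axis: bool = field(default=False, repr=False)

    def __post_init__(self):
        if self.mode not in ("off", "lookup", "constitutive"):
            raise FieldConfigError(f"unknown field mode {self.mode!r}")
        th = [t for t, _ in self.lookup]
        mags = [m for _, m in self.lookup]
        if sorted(th) != th or sorted(mags) != mags or min(mags) < 0:
            raise FieldConfigError("lookup table must be monotone with "
                                   "non-negative magnitudes")

    # -- magnitude -----------------------------------------------------
    def magnitude(self, params: ModelParams) -> float:
        """Raw (unsaturated) field magnitude, V/m, for the configured fiber
        thickness and applied strain."""
        if self.mode == "off" or params.applied_strain <= 0:
            return 0.0
        if self.mode == "lookup":
            th = np.array([t for t, _ in self.lookup])
            mags = np.array([m for _, m in self.lookup])
            return float(np.interp(params.fiber_thickness, th, mags))
        pot_mV, field_Vm = self.solve_constitutive(params)
        return field_Vm

    def solve_constitutive(self, params: ModelParams) -> tuple:
        """(outer-surface potential mV, hydrogel field V/m) from the reduced
        radially-polarized shell model."""
        if self.piezo is None:
            raise FieldConfigError(
                "constitutive mode needs PiezoConstants; use mode='lookup' "
                "if material data are unavailable")
        sigma_long = params.E_fib * 1e3 * params.applied_strain   # Pa
        q = self.piezo.d * sigma_long                             # C/m^2
        wall_field = q / self.piezo.D_r                           # V/m
        t_m = params.fiber_thickness * 1e-6
        potential = wall_field * t_m                              # V, outer +
        gap = (min(params.domain[1], params.domain[2]) / 2.0
               - params.fiber_outer_radius) * 1e-6                # m
        return potential * 1e3, potential / gap

    # -- vector field ---------------------------------------------------
    def field_at(self, position, params: ModelParams) -> np.ndarray:
        """Field vector (V/m) at a position; radially inward toward the
        fiber axis, zero when off or undeformed."""
        mag = self.magnitude(params)
        if mag == 0.0:
            return np.zeros(3)
        return mag * self.direction_at(position, params)

    def direction_at(self, position, params: ModelParams) -> np.ndarray:
        """Unit vector from ``position`` toward the fiber axis (radial)."""
        p = np.asarray(position, dtype=float)
        ay, az = params.fiber_axis_yz
        radial = np.array([0.0, ay - p[1], az - p[2]])
        nrm = np.linalg.norm(radial)
        if nrm < 1e-12:
            if not self.warned_axis:
                warnings.warn("position on the fiber axis: radial direction "
                              "undefined, returning zero field")
                self.warned_axis = True
            return np.zeros(3)
        return radial / nrm

    def directions_at(self, positions: np.ndarray,
                      params: ModelParams) -> np.ndarray:
        """Vectorized radial directions for (n, 3) positions."""
        p = np.atleast_2d(positions)
        ay, az = params.fiber_axis_yz
        radial = np.zeros_like(p)
        radial[:, 1] = ay - p[:, 1]
        radial[:, 2] = az - p[:, 2]
        nrm = np.linalg.norm(radial, axis=1, keepdims=True)
        ok = nrm[:, 0] > 1e-12
        out = np.zeros_like(p)
        out[ok] = radial[ok] / nrm[ok]
        return out


def field_at(model: ElectricFieldModel, position, params: ModelParams,
             applied_strain: Optional[float] = None) -> np.ndarray:
    """Functional form of :meth:`ElectricFieldModel.field_at`; an explicit
    ``applied_strain`` overrides the one in ``params``."""
    if applied_strain is not None:
        import dataclasses
        params = dataclasses.replace(params, applied_strain=applied_strain)
    return model.field_at(position, params)
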