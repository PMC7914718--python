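import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomech import ModelParams
from cardiomech import mechanics as mech
from cardiomech.membrane import DIRECTIONS, OCTANTS


def bisect_equilibrium(k_sub, p, tol=1e-14):
    """Independent root of sigma(eps) + K_sub*eps = 0 on the full law."""
    lo, hi = p.eps_min, 0.0
    f = lambda e: mech.internal_stress(e, p) + k_sub * e
    assert f(lo) * f(hi) <= 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# contraction law
# ---------------------------------------------------------------------------

def test_stress_values_at_reference_points(params):
    assert mech.internal_stress(0.0, params) == pytest.approx(0.17898, abs=1e-5)
    assert mech.internal_stress(params.eps_min, params) == pytest.approx(-0.252)
    # both active branches meet at sigma_max + K_pas*eps_tilde
    assert mech.internal_stress(params.eps_tilde, params) == \
        pytest.approx(0.25 + 2.8 * params.eps_tilde)
    assert mech.internal_stress(params.eps_tilde, params) == \
        pytest.approx(0.350, abs=1e-3)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(K_pas=st.floats(0.5, 5.0), K_act_extra=st.floats(0.5, 10.0),
       sigma_max=st.floats(0.05, 1.0), eps_b=st.floats(0.02, 0.3))
def test_contraction_law_continuous_at_breakpoints(K_pas, K_act_extra,
                                                   sigma_max, eps_b):
    """The three-branch law is continuous at eps_min, eps_tilde, eps_max for
    randomized valid parameter sets."""
    K_act = K_pas + K_act_extra
    p = dataclasses.replace(ModelParams(), K_pas=K_pas, K_act=K_act,
                            sigma_max=sigma_max, eps_min=-eps_b, eps_max=eps_b)
    try:
        p = p.validate()
    except Exception:
        return  # eps_tilde outside (0, eps_max): not a valid law
    h = 1e-9
    for brk in (p.eps_min, p.eps_tilde, p.eps_max):
        left = mech.internal_stress(brk - h, p)
        right = mech.internal_stress(brk + h, p)
        assert abs(left - right) < 1e-6  # h-Lipschitz continuity
    # exact continuity: evaluate the adjoining closed forms at the point
    a, b = p.mid_branch_intercept, p.mid_branch_slope
    mid_at_tilde = a + b * p.eps_tilde
    up_at_tilde = (p.K_act * p.sigma_max * (p.eps_max - p.eps_tilde)
                   / (p.K_act * p.eps_max - p.sigma_max)
                   + p.K_pas * p.eps_tilde)
    assert abs(mid_at_tilde - up_at_tilde) < 1e-12
    assert abs((a + b * p.eps_min) - p.K_pas * p.eps_min) < 1e-12


# ---------------------------------------------------------------------------
# node equilibrium
# ---------------------------------------------------------------------------

def test_equilibrium_closed_form_value(params):
    assert mech.equilibrium_strain(20.0, params) == \
        pytest.approx(-0.007221, abs=1e-6)


def test_equilibrium_matches_bisection_oracle(params):
    grid = np.geomspace(0.1, 1000.0, 60)
    for k in grid:
        ours = mech.node_equilibrium_strain(float(k), params)
        oracle = bisect_equilibrium(float(k), params)
        assert abs(ours - oracle) < 1e-10


def test_equilibrium_limits(params):
    # rigid substrate: no deformation
    assert abs(mech.equilibrium_strain(1e9, params)) < 1e-8
    # vanishing resistance: free contraction at -a/b on the rising branch
    a, b = params.mid_branch_intercept, params.mid_branch_slope
    assert mech.equilibrium_strain(1e-9, params) == pytest.approx(-a / b,
                                                                  rel=1e-6)


def test_equilibrium_monotone_in_stiffness(params):
    ks = np.geomspace(0.1, 1000.0, 40)
    eps = mech.equilibrium_strain(ks, params)
    assert (np.diff(np.abs(eps)) < 0).all()     # stiffer => less contraction
    assert (eps < 0).all()


def test_equilibrium_rejects_nonpositive_stiffness(params):
    with pytest.raises(ValueError):
        mech.equilibrium_strain(0.0, params)


# ---------------------------------------------------------------------------
# traction
# ---------------------------------------------------------------------------

def test_uniform_stress_cancels(params):
    sigma = np.full(24, 0.1)
    _, res = mech.traction_forces(sigma, np.ones(24, bool), params)
    nodal = 0.1 * params.node_area * params.zeta
    assert np.linalg.norm(res) < 1e-6 * nodal


def test_stiff_side_attracts(params):
    """Doubling the stress on the +Y-facing nodes pulls the resultant +Y."""
    sigma = np.full(24, 0.1)
    sigma[DIRECTIONS[:, 1] > 0] *= 2.0
    _, res = mech.traction_forces(sigma, np.ones(24, bool), params)
    assert res[1] > 0
    assert abs(res[0]) < 1e-9 and abs(res[2]) < 1e-9


def test_blocked_face_pushes_away(params):
    """Deactivating one contact face under uniform stress points the
    resultant away from that face."""
    sigma = np.full(24, 0.1)
    active = OCTANTS != 7          # block the (+,+,+) face
    _, res = mech.traction_forces(sigma, active, params)
    assert res[0] < 0 and res[1] < 0 and res[2] < 0


# ---------------------------------------------------------------------------
# protrusion
# ---------------------------------------------------------------------------

def test_protrusion_bounded_and_mean(params):
    rng = np.random.default_rng(0)
    f_scale = 2.0
    mags = np.array([np.linalg.norm(mech.protrusion_force(f_scale, rng))
                     for _ in range(100000)])
    assert (mags <= f_scale + 1e-12).all()
    assert mags.mean() == pytest.approx(f_scale / 2, rel=0.01)
    assert np.linalg.norm(mech.protrusion_force(0.0, rng)) == 0.0


# ---------------------------------------------------------------------------
# electric forces
# ---------------------------------------------------------------------------

def test_field_force_saturates(params):
    f = mech.field_force(np.array([1500.0, 0.0, 0.0]), params, c_ef=1.0)
    assert f[0] == pytest.approx(7.54e-8 * 1e9, rel=1e-3)   # nN
    f_sat = mech.field_force(np.array([1200.0, 0.0, 0.0]), params, c_ef=1.0)
    assert f[0] == pytest.approx(f_sat[0])
    assert np.allclose(mech.field_force(np.zeros(3), params), 0.0)


def test_field_force_monotone_below_saturation(params):
    mags = [np.linalg.norm(mech.field_force(np.array([E, 0, 0]), params))
            for E in (100.0, 400.0, 800.0, 1200.0, 2000.0)]
    assert mags[0] < mags[1] < mags[2] < mags[3]
    assert mags[3] == pytest.approx(mags[4])


def test_pairwise_repulsion_antisymmetric(params):
    p = dataclasses.replace(params, c_rep=1e-6)
    pos = np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0]])
    f = mech.repulsion_forces(pos, p)
    assert np.allclose(f[0], -f[1])
    assert f[0, 0] < 0 and f[1, 0] > 0          # pushed apart


def test_bare_coulomb_magnitude_example():
    # unit charges, k_e/eps_r = 1, r = 2 -> magnitude 1/4
    assert mech.coulomb_repulsion_magnitude(1.0, 1.0, 2.0, 1.0) == 0.25


def test_coincident_centers_rejected(params):
    p = dataclasses.replace(params, c_rep=1e-6)
    pos = np.zeros((2, 3))
    with pytest.raises(ValueError, match="coincident"):
        mech.repulsion_forces(pos, p)


# ---------------------------------------------------------------------------
# drag
# ---------------------------------------------------------------------------

def test_velocity_unit_check(params):
    v = mech.drag_velocity(np.array([1.0, 0.0, 0.0]),
                           mech.single_cell_shape_factor(params), params)
    assert v[0] == pytest.approx(19.1, abs=0.05)    # um/h from 1 nN
    assert np.allclose(mech.drag_velocity(np.zeros(3), 100.0, params), 0.0)


def test_velocity_inverse_in_viscosity(params):
    thick = dataclasses.replace(params, eta=2000.0).validate()
    v1 = mech.drag_velocity(np.ones(3), 100.0, params)
    v2 = mech.drag_velocity(np.ones(3), 100.0, thick)
    assert np.allclose(v1, 2.0 * v2)
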