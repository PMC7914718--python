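import dataclasses

import numpy as np
import pytest

from cardiomech import ModelParams, build_mesh, probe_compliance, \
    solve_displacements
from cardiomech.ecm import (MeshError, SubstrateField, assemble_stiffness,
                            elastic_matrix, unit_hex_stiffness)


@pytest.fixture(scope="module")
def small():
    return ModelParams(domain=(240.0, 160.0, 160.0)).validate()


@pytest.fixture(scope="module")
def hom_solution(small):
    return solve_displacements(build_mesh(small, with_fiber=False), 0.0)


@pytest.fixture(scope="module")
def fib_solution(small):
    return solve_displacements(build_mesh(small), 0.0)


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def test_default_box_at_40um_gives_2000_elements(params):
    mesh = build_mesh(params)
    assert mesh.shape == (20, 10, 10)
    assert mesh.n_elems == 2000
    assert mesh.n_nodes == 21 * 11 * 11


def test_no_fiber_variant_all_matrix(params):
    mesh = build_mesh(params, with_fiber=False)
    assert (mesh.tag == 0).all()
    assert np.allclose(mesh.E_elem, params.E_ecm)


def test_fiber_elements_ring_the_axis(params):
    mesh = build_mesh(params)
    assert mesh.tag.sum() > 0
    # tagged elements surround the X axis in the cross-section
    centers = mesh.coords[mesh.connectivity].mean(axis=1)
    ay, az = params.fiber_axis_yz
    rad = np.hypot(centers[:, 1] - ay, centers[:, 2] - az)
    assert rad[mesh.tag == 1].max() < params.fiber_outer_radius + mesh.resolution
    # blended modulus strictly between matrix and fiber at this resolution
    blended = mesh.E_elem[mesh.tag == 1]
    assert (blended > params.E_ecm).all() and (blended < params.E_fib).all()


def test_fiber_fraction_grows_with_thickness(params):
    thick = build_mesh(dataclasses.replace(params, fiber_thickness=18.0).validate())
    thin = build_mesh(dataclasses.replace(params, fiber_thickness=2.0).validate())
    assert thick.E_elem.max() > thin.E_elem.max()


def test_resolution_must_divide_domain(params):
    with pytest.raises(MeshError, match="divide"):
        build_mesh(params, resolution=37.0)


# ---------------------------------------------------------------------------
# solves
# ---------------------------------------------------------------------------

def test_patch_test_uniaxial_extension(small):
    """Homogeneous block under imposed X strain: exact constant strain with
    free lateral Poisson contraction."""
    sol = solve_displacements(build_mesh(small, with_fiber=False), 0.25)
    assert np.allclose(sol.strain[:, 0], 0.25, atol=1e-10)
    assert np.allclose(sol.strain[:, 1], -small.nu * 0.25, atol=1e-10)
    assert np.allclose(sol.strain[:, 2], -small.nu * 0.25, atol=1e-10)
    assert np.abs(sol.strain[:, 3:]).max() < 1e-10


def test_zero_strain_zero_displacement(hom_solution):
    assert np.abs(hom_solution.displacement).max() < 1e-12
    assert hom_solution.residual < 1e-8


def test_fibered_block_carries_extra_load(small):
    """Volume-averaged axial stress exceeds the matrix-only value (the
    stiffer inclusion carries extra load; rule-of-mixtures lower bound)."""
    sol = solve_displacements(build_mesh(small), 0.25)
    assert sol.stress[:, 0].mean() > small.E_ecm * 0.25


def test_stiffness_matrix_symmetric_positive_definite(small):
    mesh = build_mesh(small, resolution=40.0)
    K = assemble_stiffness(mesh)
    asym = abs(K - K.T).max()
    assert asym < 1e-9
    # after removing rigid-body motion the spectrum is positive
    from cardiomech.ecm import _boundary_conditions
    fixed, _ = _boundary_conditions(mesh, 0.0)
    free = np.setdiff1d(np.arange(K.shape[0]), fixed)
    sub = K[free][:, free].toarray()
    assert np.linalg.eigvalsh(sub).min() > 0


def test_unit_stiffness_scales_linearly_with_modulus():
    K1 = unit_hex_stiffness(0.4, 40.0)
    C = elastic_matrix(2.0, 0.4)
    assert np.allclose(2.0 * K1, K1 * 2.0)
    assert np.allclose(C, 2.0 * elastic_matrix(1.0, 0.4))


# ---------------------------------------------------------------------------
# compliance probes
# ---------------------------------------------------------------------------

def test_probe_linear_in_modulus(small, hom_solution):
    pt, d = (100.0, 60.0, 100.0), (1, 0, 0)
    base = probe_compliance(hom_solution, pt, d)
    doubled = dataclasses.replace(small, E_ecm=40.0).validate()
    sol2 = solve_displacements(build_mesh(doubled, with_fiber=False), 0.0)
    assert probe_compliance(sol2, pt, d) == pytest.approx(2 * base, rel=1e-9)


def test_probe_fiber_surface_stiffer_than_corner(small, fib_solution):
    k_fib = probe_compliance(fib_solution, (120.0, 80.0, 110.0), (0, 0, 1))
    k_corner = probe_compliance(fib_solution, (30.0, 30.0, 30.0), (1, 0, 0))
    assert k_fib > k_corner


def test_probe_translation_invariance_interior(small, hom_solution):
    k_a = probe_compliance(hom_solution, (100.0, 60.0, 100.0), (1, 0, 0))
    k_b = probe_compliance(hom_solution, (140.0, 60.0, 100.0), (1, 0, 0))
    assert abs(k_a - k_b) / k_a < 0.05


def test_probe_refinement_stable(small, fib_solution):
    """Interior probe values change < 10% between successive mesh halvings."""
    fine = solve_displacements(build_mesh(small, resolution=20.0), 0.0)
    for pt, d in [((100.0, 40.0, 40.0), (1, 0, 0)),
                  ((120.0, 80.0, 110.0), (0, 0, 1))]:
        k40 = probe_compliance(fib_solution, pt, d)
        k20 = probe_compliance(fine, pt, d)
        assert abs(k20 - k40) / k40 < 0.10


def test_probe_outside_domain_rejected(fib_solution):
    with pytest.raises(MeshError, match="outside"):
        probe_compliance(fib_solution, (-5.0, 0.0, 0.0), (1, 0, 0))


def test_homogeneous_field_reads_matrix_modulus(small, hom_solution):
    """The sensed stiffness of a homogeneous gel is E_ecm everywhere."""
    field = SubstrateField(hom_solution)
    pts = np.array([[60.0, 60.0, 60.0], [120.0, 80.0, 40.0],
                    [200.0, 100.0, 120.0]])
    vals = field.k_axis(pts)
    assert np.allclose(vals, small.E_ecm, rtol=1e-6)


def test_field_fiber_bump_and_strain_stiffening(small):
    fib = SubstrateField(solve_displacements(build_mesh(small), 0.0))
    ay, az = small.fiber_axis_yz
    near = fib.k_sub(np.array([[120.0, ay, az + 20.0]]),
                     np.array([[0.0, 0.0, 1.0]]))[0]
    far = fib.k_sub(np.array([[120.0, 30.0, 30.0]]),
                    np.array([[0.0, 0.0, 1.0]]))[0]
    assert near > far
    strained = SubstrateField(solve_displacements(build_mesh(small), 0.25))
    x_dir = np.array([[1.0, 0.0, 0.0]])
    pt = np.array([[120.0, 40.0, 40.0]])
    assert strained.k_sub(pt, x_dir)[0] > fib.k_sub(pt, x_dir)[0] * 1.1
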