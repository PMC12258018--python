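"""Forward solver physics: reciprocity, symmetry, scaling, sensitivities."""

from __future__ import annotations

import numpy as np
import pytest

from oxisense.forward import (
    DegenerateMeasurementError,
    ForwardSolver,
    IMPattern,
    Measurement,
    delta_vr,
)
from oxisense.geometry import (
    ConductivityField,
    SIGMA_CLOT,
    build_mesh,
    edge_array,
    insert_spherical_target,
    symmetric_array,
)


def test_measurement_validation():
    with pytest.raises(ValueError, match="disjoint"):
        Measurement(inject=(0, 1), measure=(1, 2))
    with pytest.raises(ValueError, match="distinct"):
        Measurement(inject=(3, 3), measure=(1, 2))
    with pytest.raises(ValueError, match="reciprocity"):
        IMPattern([Measurement((0, 1), (2, 3)), Measurement((2, 3), (0, 1))])


def test_reciprocity(tiny_hom_solution):
    """Swapping inject and measure pairs reproduces the voltage."""
    _, sol = tiny_hom_solution
    meas = [Measurement((0, 2), (5, 7)), Measurement((0, 9), (3, 12)),
            Measurement((1, 14), (6, 8)), Measurement((4, 5), (10, 11))]
    v = sol.measure(IMPattern(meas)).v
    v_swapped = sol.measure(IMPattern([m.swapped() for m in meas])).v
    assert np.all(np.abs(v - v_swapped) <= 1e-8 * np.abs(v))


def test_rotational_symmetry(even_mesh, geom):
    """Measurements related by the geometry's 90-degree rotation agree for a
    rotation-symmetric array on a rotation-symmetric mesh."""
    solver = ForwardSolver(even_mesh, symmetric_array(0.03, geom), geom)
    sol = solver.factorize(ConductivityField.homogeneous(even_mesh))

    def rot(m):
        r = lambda e: (e // 8) * 8 + (e % 8 + 2) % 8
        return Measurement(inject=(r(m.inject[0]), r(m.inject[1])),
                           measure=(r(m.measure[0]), r(m.measure[1])))

    meas = [Measurement((0, 9), (3, 12)), Measurement((0, 1), (10, 11)),
            Measurement((1, 2), (5, 6))]
    v = sol.measure(IMPattern(meas)).v
    v_rot = sol.measure(IMPattern([rot(m) for m in meas])).v
    assert np.all(np.abs(v - v_rot) <= 1e-6 * np.abs(v))


def test_conductivity_scaling(tiny_mesh, geom):
    """v scales as 1/sigma: exactly when the contact impedance co-scales
    (the full system is homogeneous), approximately when it is held fixed
    (the contact layer does not scale with the volume conductivity)."""
    pat = IMPattern([Measurement((0, 9), (3, 12)), Measurement((0, 2), (5, 7))])
    arr = symmetric_array(0.03, geom)
    solver = ForwardSolver(tiny_mesh, arr, geom)
    hom = ConductivityField.homogeneous(tiny_mesh)
    v = solver.factorize(hom).measure(pat).v

    doubled = ConductivityField(hom.sigma * 2, hom.region)
    arr_scaled = symmetric_array(0.03, geom,
                                 contact_impedance=arr.contact_impedance / 2)
    v_exact = ForwardSolver(tiny_mesh, arr_scaled, geom).factorize(
        doubled).measure(pat).v
    assert np.allclose(v_exact, v / 2, rtol=1e-12)

    v_approx = solver.factorize(doubled).measure(pat).v
    assert np.allclose(v_approx, v / 2, rtol=0.1)


def test_current_conservation(tiny_hom_solution):
    """Electrode currents sum to zero and match the driven amplitude."""
    _, sol = tiny_hom_solution
    I = sol.electrode_currents((0, 12))
    assert I[0] == pytest.approx(1.0, rel=1e-10)
    assert I[12] == pytest.approx(-1.0, rel=1e-10)
    assert abs(I.sum()) <= 1e-10


def test_factorized_reuse_matches_fresh_solves(tiny_mesh, geom):
    """The pair-solution cache returns the same voltages as independent
    factorizations per injection."""
    pat = IMPattern([Measurement((0, 9), (3, 12)), Measurement((1, 3), (5, 7)),
                     Measurement((2, 10), (6, 14))])
    solver = ForwardSolver(tiny_mesh, edge_array(geom), geom)
    hom = ConductivityField.homogeneous(tiny_mesh)
    v_cached = solver.factorize(hom).measure(pat).v
    v_fresh = np.array(
        [solver.factorize(hom).measure(IMPattern([m])).v[0] for m in pat]
    )
    assert np.allclose(v_cached, v_fresh, rtol=1e-12, atol=0)


def test_delta_vr_basics(tiny_hom_solution):
    _, sol = tiny_hom_solution
    pat = IMPattern([Measurement((0, 9), (3, 12))])
    v = sol.measure(pat)
    assert np.array_equal(delta_vr(v, v), [0.0])
    with pytest.raises(DegenerateMeasurementError):
        delta_vr(np.array([1.0]), np.array([1e-14]))


def test_clot_proximity_increases_response(tiny_mesh, geom):
    """A clot beside the measuring electrodes perturbs dVr more than the
    same clot far from every electrode."""
    pat = IMPattern([Measurement((0, 2), (1, 3))])  # top-plane corner-ish
    solver = ForwardSolver(tiny_mesh, edge_array(geom), geom)
    hom = ConductivityField.homogeneous(tiny_mesh)
    sol = solver.factorize(hom)
    v_hom = sol.measure(pat)

    near = insert_spherical_target(hom, tiny_mesh, [0.035, 0.02, 0.018], 0.014)
    far = insert_spherical_target(hom, tiny_mesh, [-0.035, -0.02, -0.018],
                                  0.014)
    dv_near = delta_vr(solver.factorize(near).measure(pat), v_hom)
    dv_far = delta_vr(solver.factorize(far).measure(pat), v_hom)
    assert np.abs(dv_near).max() > np.abs(dv_far).max()


def test_delta_vr_sign_consistent_with_jacobian(tiny_mesh, geom):
    """First-order consistency: the sign of dVr for a conductivity drop
    matches the sign predicted by the Jacobian entries at the clot."""
    pat = IMPattern([Measurement((0, 2), (1, 3))])
    solver = ForwardSolver(tiny_mesh, edge_array(geom), geom)
    hom = ConductivityField.homogeneous(tiny_mesh)
    sol = solver.factorize(hom)
    v_hom = sol.measure(pat)
    J = sol.jacobian(pat)

    center = [0.035, 0.02, 0.018]
    clot = insert_spherical_target(hom, tiny_mesh, center, 0.014, SIGMA_CLOT)
    dv = delta_vr(solver.factorize(clot).measure(pat), v_hom)
    dsigma = clot.sigma - hom.sigma
    predicted = (J @ dsigma) / v_hom.v
    assert np.sign(dv[0]) == np.sign(predicted[0])


def test_first_order_jacobian_prediction(tiny_hom_solution, tiny_mesh):
    """For a 1e-3 relative perturbation, J * dsigma predicts the voltage
    change within 10%."""
    solver, sol = tiny_hom_solution
    pat = IMPattern([Measurement((0, 9), (3, 12)), Measurement((0, 2), (5, 7))])
    J = sol.jacobian(pat)
    v0 = sol.measure(pat).v
    hom = ConductivityField.homogeneous(tiny_mesh)
    dsigma = hom.sigma * 1e-3
    pert = ConductivityField(hom.sigma + dsigma, hom.region)
    v1 = solver.factorize(pert).measure(pat).v
    rel_err = np.abs((v1 - v0) - J @ dsigma) / np.abs(v1 - v0)
    assert np.all(rel_err <= 0.10)


def test_jacobian_reciprocal_rows_identical(tiny_hom_solution):
    _, sol = tiny_hom_solution
    m = Measurement((0, 9), (3, 12))
    J = sol.jacobian(IMPattern([m]))
    J_swapped = sol.jacobian(IMPattern([m.swapped()]))
    assert np.allclose(J, J_swapped, rtol=1e-10)


def test_jacobian_magnitude_near_electrodes(tiny_mesh, geom):
    """For an intra-plane measurement, sensitivity near the involved
    electrodes exceeds sensitivity at the volume centre."""
    pat = IMPattern([Measurement((0, 2), (1, 3))])
    solver = ForwardSolver(tiny_mesh, edge_array(geom), geom)
    sol = solver.factorize(ConductivityField.homogeneous(tiny_mesh))
    J = np.abs(sol.jacobian(pat)[0])
    pos = edge_array(geom).positions()
    involved = pos[[0, 2, 1, 3]].mean(axis=0)
    near_idx = np.argmin(
        np.linalg.norm(tiny_mesh.centroids - involved * 0.9, axis=1)
    )
    center_idx = np.argmin(np.linalg.norm(tiny_mesh.centroids, axis=1))
    assert J[near_idx] > J[center_idx]
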