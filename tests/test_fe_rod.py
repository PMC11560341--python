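"""Reduced FE rod: meshing, equilibrium solves, CAP mapping, VTK export."""

import numpy as np
import pytest

from nervestretch.fe_rod import (
    build_mesh,
    export_field,
    gaussian_waist,
    linear_taper,
    map_cap_field,
    solve_force_controlled,
    solve_stretch_controlled,
    uniform_profile,
)
from nervestretch.stretch_map import fit_reduction_spline

ALPHA, BETA = 0.183, 1.88
F_110 = 0.2503700540861287  # closed-form force at lam=1.1, d0=1.42 mm


def closed_form_lambda(alpha, beta, A0, force, lo=1.0, hi=1.5):
    """Independent bisection on T11(lam)*A0/lam = force (plain formulas)."""
    def g(lam):
        t11 = (2 * alpha + 4 * beta * (lam**2 + 2 / lam - 3)) * (lam**2 - 1 / lam)
        return t11 * A0 / lam - force
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def test_build_mesh_uniform():
    mesh = build_mesh(uniform_profile(1.42), 28.8, 10)
    assert mesh.n_elem == 10
    assert np.allclose(mesh.A0_elem, np.pi * 0.71**2, rtol=1e-12)
    assert mesh.length == pytest.approx(28.8)


def test_build_mesh_single_element_and_taper():
    mesh1 = build_mesh(uniform_profile(1.0), 10.0, 1)
    assert mesh1.n_elem == 1 and mesh1.z_nodes.tolist() == [0.0, 10.0]
    taper = build_mesh(linear_taper(1.42, 1.0, 28.8), 28.8, 20)
    assert np.all(np.diff(taper.A0_elem) < 0)


def test_build_mesh_rejects_bad_geometry():
    with pytest.raises(ValueError):
        build_mesh(linear_taper(1.0, -1.0, 10.0), 10.0, 10)
    with pytest.raises(ValueError):
        build_mesh(uniform_profile(1.0), 10.0, 0)


def test_force_controlled_uniform_matches_closed_form():
    mesh = build_mesh(uniform_profile(1.42), 28.8, 10)
    sol = solve_force_controlled(mesh, ALPHA, BETA, F_110)
    lam_ref = closed_form_lambda(ALPHA, BETA, np.pi * 0.71**2, F_110)
    assert np.allclose(sol.lam_elem, 1.1, atol=1e-6)
    assert np.allclose(sol.lam_elem, lam_ref, atol=1e-8)


def test_force_controlled_zero_force():
    mesh = build_mesh(uniform_profile(1.42), 28.8, 5)
    sol = solve_force_controlled(mesh, ALPHA, BETA, 0.0)
    assert np.all(sol.lam_elem == 1.0)
    assert np.allclose(sol.T11_elem, 0.0, atol=1e-14)


def test_force_balance_residual():
    mesh = build_mesh(gaussian_waist(1.42, 0.9, 28.8), 28.8, 40)
    sol = solve_force_controlled(mesh, ALPHA, BETA, 0.2)
    residual = sol.T11_elem * mesh.A0_elem / sol.lam_elem - sol.force
    assert np.max(np.abs(residual)) <= 1e-8


def test_tapered_rod_thinner_elements_stretch_more():
    mesh = build_mesh(linear_taper(1.42, 1.0, 28.8), 28.8, 20)
    sol = solve_force_controlled(mesh, ALPHA, BETA, 0.15)
    assert np.all(np.diff(sol.lam_elem) > 0)  # A0 decreases along z


def test_force_exceeding_cap_rejected():
    mesh = build_mesh(uniform_profile(1.42), 28.8, 3)
    with pytest.raises(ValueError):
        solve_force_controlled(mesh, ALPHA, BETA, 100.0)


def test_stretch_controlled_consistency():
    mesh = build_mesh(uniform_profile(1.42), 28.8, 10)
    sol = solve_stretch_controlled(mesh, ALPHA, BETA, 1.1)
    assert sol.force == pytest.approx(F_110, abs=1e-4)
    assert sol.global_stretch == pytest.approx(1.1, abs=1e-8)


def test_stretch_controlled_reference_state():
    mesh = build_mesh(uniform_profile(1.42), 28.8, 4)
    sol = solve_stretch_controlled(mesh, ALPHA, BETA, 1.0)
    assert sol.force == 0.0
    assert np.all(sol.lam_elem == 1.0)


def test_stretch_controlled_tapered_brackets_mean():
    mesh = build_mesh(linear_taper(1.42, 1.1, 28.8), 28.8, 20)
    sol = solve_stretch_controlled(mesh, ALPHA, BETA, 1.1)
    assert sol.lam_elem.min() < 1.1 < sol.lam_elem.max()
    assert sol.global_stretch == pytest.approx(1.1, abs=1e-8)


def test_force_stretch_roundtrip():
    mesh = build_mesh(gaussian_waist(1.42, 1.0, 28.8), 28.8, 30)
    sol1 = solve_stretch_controlled(mesh, ALPHA, BETA, 1.08)
    sol2 = solve_force_controlled(mesh, ALPHA, BETA, sol1.force)
    assert np.max(np.abs(sol1.lam_elem - sol2.lam_elem)) <= 1e-7


def test_volume_conservation_identity():
    mesh = build_mesh(gaussian_waist(1.42, 0.95, 28.8), 28.8, 25)
    sol = solve_force_controlled(mesh, ALPHA, BETA, 0.18)
    ref_vol = np.sum(mesh.A0_elem * mesh.dL_elem)
    def_vol = np.sum((mesh.A0_elem / sol.lam_elem) * (sol.lam_elem * mesh.dL_elem))
    assert def_vol == pytest.approx(ref_vol, rel=1e-14)


def linear_map_curve():
    return fit_reduction_spline([(1.0, 0.0), (1.1, 50.0), (1.2, 100.0)])


def test_map_cap_field_linear_oracle():
    mesh = build_mesh(uniform_profile(1.42), 28.8, 5)
    sol = solve_force_controlled(mesh, ALPHA, BETA, 0.0)
    sol.lam_elem = np.full(5, 1.05)
    sol = map_cap_field(sol, linear_map_curve())
    assert np.allclose(sol.reduction_elem, 25.0, atol=1e-6)


def test_map_cap_field_reference_and_knot():
    mesh = build_mesh(uniform_profile(1.42), 28.8, 4)
    sol = solve_force_controlled(mesh, ALPHA, BETA, 0.0)
    sol = map_cap_field(sol, linear_map_curve())
    assert np.allclose(sol.reduction_elem, 0.0, atol=1e-9)  # lam = 1 everywhere
    sol.lam_elem = np.full(4, 1.1)
    sol = map_cap_field(sol, linear_map_curve())
    assert np.allclose(sol.reduction_elem, 50.0, atol=1e-6)


def test_map_cap_field_clamp_policies():
    mesh = build_mesh(uniform_profile(1.42), 28.8, 3)
    sol = solve_force_controlled(mesh, ALPHA, BETA, 0.0)
    sol.lam_elem = np.array([1.05, 1.25, 1.30])
    clamped = map_cap_field(sol, linear_map_curve(), clamp_policy="clamp")
    assert clamped.reduction_elem[1] == pytest.approx(100.0, abs=1e-6)
    with pytest.raises(ValueError):
        map_cap_field(sol, linear_map_curve(), clamp_policy="error")
    ext = map_cap_field(sol, linear_map_curve(), clamp_policy="extend")
    assert ext.reduction_elem[2] > 100.0


def test_reduction_monotone_in_global_stretch():
    mesh = build_mesh(gaussian_waist(1.42, 1.1, 28.8), 28.8, 20)
    curve = linear_map_curve()
    means = []
    for gs in (1.02, 1.05, 1.08, 1.11):
        sol = map_cap_field(solve_stretch_controlled(mesh, ALPHA, BETA, gs), curve)
        means.append(sol.reduction_elem.mean())
    assert np.all(np.diff(means) > 0)


def read_vtk_cell_scalars(path):
    """Minimal legacy-ASCII VTK reader for the exported line mesh."""
    lines = path.read_text().splitlines()
    arrays, points = {}, []
    i = 0
    while i < len(lines):
        tok = lines[i].split()
        if tok[:1] == ["POINTS"]:
            n = int(tok[1])
            points = [float(lines[i + 1 + k].split()[0]) for k in range(n)]
            i += n
        elif tok[:1] == ["SCALARS"]:
            name = tok[1]
            count = int(lines[i - 1].split()[-1]) if "DATA" in lines[i - 1] else None
            # walk back to the nearest CELL_DATA / POINT_DATA count
            j = i
            while count is None:
                j -= 1
                t2 = lines[j].split()
                if t2 and t2[0] in ("CELL_DATA", "POINT_DATA"):
                    count = int(t2[1])
            vals = [float(lines[i + 2 + k]) for k in range(count)]
            arrays[name] = np.array(vals)
            i += 1 + count
        i += 1
    return np.array(points), arrays


def test_export_deformed_length_and_roundtrip(tmp_path):
    mesh = build_mesh(uniform_profile(1.42), 28.8, 10)
    sol = solve_stretch_controlled(mesh, ALPHA, BETA, 1.1)
    sol = map_cap_field(sol, linear_map_curve())
    path = export_field(sol, mesh, tmp_path / "rod.vtk")
    z, arrays = read_vtk_cell_scalars(path)
    assert z[-1] - z[0] == pytest.approx(28.8 * 1.1, abs=1e-6)
    # text round-trip is bit-identical (printed at full precision)
    assert np.array_equal(arrays["stretch"], sol.lam_elem)
    assert np.array_equal(arrays["axial_stress_MPa"], sol.T11_elem)
    assert np.array_equal(arrays["cap_reduction_pct"], sol.reduction_elem)


def test_export_reference_state_geometry(tmp_path):
    mesh = build_mesh(uniform_profile(1.42), 28.8, 6)
    sol = solve_force_controlled(mesh, ALPHA, BETA, 0.0)
    path = export_field(sol, mesh, tmp_path / "ref.vtk")
    z, arrays = read_vtk_cell_scalars(path)
    assert np.allclose(z, mesh.z_nodes, atol=1e-12)
    assert np.allclose(arrays["radius_mm"], 0.71, atol=1e-12)
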