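"""Reduced finite-element model of a stretched nerve.

A statically determinate 1-D axisymmetric rod of incompressible
Raghavan–Vorp material under axial load: the axial force is spatially
constant, so equilibrium decouples into one nonlinear scalar equation per
element,

    g(lam_e) = T11(lam_e) * A0_e / lam_e - F = 0,

solved by safeguarded Newton (bisection fallback) on a bracketing
interval. Uniaxial tension of an incompressible isotropic rod is captured
exactly by this reduction, which keeps every solution checkable against
the closed form. A stretch-controlled solve wraps a scalar root find on
the force so the length-weighted mean element stretch matches a prescribed
global stretch. Element stretches are mapped to predicted CAP reduction by
linear interpolation of a calibrated stretch–reduction curve, and fields
are exported as legacy-ASCII VTK for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .mechanics import circular_area, model_stress
from .stretch_map import CAPStretchCurve

__all__ = [
    "RodMesh",
    "RodSolution",
    "build_mesh",
    "solve_force_controlled",
    "solve_stretch_controlled",
    "map_cap_field",
    "export_field",
    "uniform_profile",
    "linear_taper",
    "gaussian_waist",
]


@dataclass
class RodMesh:
    """Axisymmetric rod discretisation in the reference configuration."""

    z_nodes: np.ndarray   # mm, strictly increasing
    A0_elem: np.ndarray   # mm^2, per element

    def __post_init__(self):
        self.z_nodes = np.asarray(self.z_nodes, dtype=float)
        self.A0_elem = np.asarray(self.A0_elem, dtype=float)
        if np.any(np.diff(self.z_nodes) <= 0):
            raise ValueError("z_nodes must be strictly increasing")
        if self.A0_elem.size != self.z_nodes.size - 1:
            raise ValueError("need one area per element")
        if np.any(self.A0_elem <= 0):
            raise ValueError("element areas must be positive")

    @property
    def n_elem(self) -> int:
        return self.A0_elem.size

    @property
    def dL_elem(self) -> np.ndarray:
        return np.diff(self.z_nodes)

    @property
    def length(self) -> float:
        return float(self.z_nodes[-1] - self.z_nodes[0])


@dataclass
class RodSolution:
    """Equilibrium fields of a solved rod."""

    lam_elem: np.ndarray
    T11_elem: np.ndarray
    force: float
    global_stretch: float
    converged: bool
    iterations: np.ndarray
    reduction_elem: np.ndarray | None = None


def uniform_profile(diameter: float) -> Callable[[float], float]:
    return lambda z: diameter


def linear_taper(d_start: float, d_end: float, length: float) -> Callable[[float], float]:
    return lambda z: d_start + (d_end - d_start) * z / length


def gaussian_waist(
    d_outer: float, d_waist: float, length: float, width: float | None = None
) -> Callable[[float], float]:
    """Symmetric narrowing at mid-length, emulating a focal constriction."""
    w = width if width is not None else length / 6.0
    return lambda z: d_outer - (d_outer - d_waist) * np.exp(
        -0.5 * ((z - length / 2.0) / w) ** 2
    )


def build_mesh(profile: Callable[[float], float], length: float, n_elem: int) -> RodMesh:
    """Uniform mesh; areas from the diameter profile at element midpoints."""
    if n_elem < 1:
        raise ValueError("need at least one element")
    if length <= 0:
        raise ValueError("length must be positive")
    z = np.linspace(0.0, length, n_elem + 1)
    mids = 0.5 * (z[:-1] + z[1:])
    d = np.array([float(profile(zm)) for zm in mids])
    if np.any(d <= 0):
        raise ValueError("diameter profile must be positive everywhere")
    return RodMesh(z_nodes=z, A0_elem=circular_area(d))


def _element_force(alpha: float, beta: float, A0: float, lam) -> float:
    """Axial force carried by an element at stretch lam (N)."""
    return model_stress(alpha, beta, lam) * A0 / lam


def _solve_element(
    alpha: float,
    beta: float,
    A0: float,
    force: float,
    lam_cap: float,
    tol: float,
    max_iter: int,
) -> tuple[float, int]:
    """Safeguarded Newton for g(lam) = T11*A0/lam - F on [1, lam_cap]."""
    g = lambda lam: _element_force(alpha, beta, A0, lam) - force
    if force == 0.0:
        return 1.0, 0
    g_cap = g(lam_cap)
    if g_cap < 0:
        raise ValueError(
            f"force {force} N exceeds element capacity at stretch cap {lam_cap}"
        )
    lo, hi = 1.0, lam_cap
    lam = 0.5 * (lo + hi)
    h = 1e-8
    for it in range(1, max_iter + 1):
        g_val = g(lam)
        if abs(g_val) <= tol:
            return lam, it
        if g_val > 0:
            hi = lam
        else:
            lo = lam
        dg = (g(lam + h) - g(lam - h)) / (2.0 * h)
        step_ok = dg != 0
        if step_ok:
            lam_new = lam - g_val / dg
            step_ok = lo < lam_new < hi
        lam = lam_new if step_ok else 0.5 * (lo + hi)
    raise RuntimeError(
        f"element solve failed to converge in {max_iter} iterations (|g|={abs(g(lam)):.3e} N)"
    )


def solve_force_controlled(
    mesh: RodMesh,
    alpha: float,
    beta: float,
    force: float,
    lam_cap: float = 1.5,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> RodSolution:
    """Equilibrium under a prescribed axial force.

    The rod is statically determinate, so each element's stretch solves a
    local scalar equation; per-element residuals are driven to |g| <= tol
    (N). Raises when the force would push any element past ``lam_cap``.
    """
    if force < 0:
        raise ValueError("force must be nonnegative")
    if alpha + beta <= 0:
        raise ValueError("material must have positive stiffness (alpha + beta > 0)")
    lam = np.empty(mesh.n_elem)
    iters = np.zeros(mesh.n_elem, dtype=int)
    for e in range(mesh.n_elem):
        try:
            lam[e], iters[e] = _solve_element(
                alpha, beta, mesh.A0_elem[e], force, lam_cap, tol, max_iter
            )
        except (ValueError, RuntimeError) as err:
            raise type(err)(f"element {e}: {err}") from err
    t11 = np.asarray(model_stress(alpha, beta, lam))
    dL = mesh.dL_elem
    global_stretch = float(np.sum(lam * dL) / np.sum(dL))
    return RodSolution(
        lam_elem=lam,
        T11_elem=np.atleast_1d(t11),
        force=force,
        global_stretch=global_stretch,
        converged=True,
        iterations=iters,
    )


def solve_stretch_controlled(
    mesh: RodMesh,
    alpha: float,
    beta: float,
    global_stretch: float,
    lam_cap: float = 1.5,
    tol: float = 1e-10,
    stretch_tol: float = 1e-8,
    max_iter: int = 100,
) -> RodSolution:
    """Equilibrium at a prescribed overall (length-weighted mean) stretch.

    An outer scalar solve finds the force at which the force-controlled
    solution's global stretch matches the target to ``stretch_tol``.
    """
    if global_stretch < 1.0:
        raise ValueError("global stretch must be >= 1")
    if global_stretch == 1.0:
        return solve_force_controlled(mesh, alpha, beta, 0.0, lam_cap, tol, max_iter)
    # upper force bound: smallest element capacity at the stretch cap
    f_hi = float(np.min([_element_force(alpha, beta, a, lam_cap) for a in mesh.A0_elem]))

    def mismatch(force: float) -> float:
        sol = solve_force_controlled(mesh, alpha, beta, force, lam_cap, tol, max_iter)
        return sol.global_stretch - global_stretch

    if mismatch(f_hi) < 0:
        raise ValueError(
            f"global stretch {global_stretch} unreachable below stretch cap {lam_cap}"
        )
    force = brentq(mismatch, 0.0, f_hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    sol = solve_force_controlled(mesh, alpha, beta, float(force), lam_cap, tol, max_iter)
    if abs(sol.global_stretch - global_stretch) > stretch_tol:
        raise RuntimeError("outer force solve did not reach the stretch tolerance")
    return sol


def map_cap_field(
    sol: RodSolution,
    curve: CAPStretchCurve,
    clamp_policy: str = "clamp",
    knot_step: float = 1e-3,
) -> RodSolution:
    """Predict per-element CAP reduction from element stretches.

    The calibrated curve is sampled to a dense (stretch, reduction) knot
    table and linearly interpolated at each element stretch. Below the
    calibrated range the reduction is 0; above it the boundary value is
    used when ``clamp_policy='clamp'``, an error raised for ``'error'``, or
    the last segment extended for ``'extend'``.
    """
    table = curve.sample(step=knot_step)
    lam_k, red_k = table[:, 0], table[:, 1]
    lam = sol.lam_elem
    if clamp_policy == "error":
        if np.any(lam > lam_k[-1] + 1e-12):
            raise ValueError("element stretch above the calibrated curve range")
        red = np.interp(lam, lam_k, red_k, left=0.0)
    elif clamp_policy == "extend":
        red = np.interp(lam, lam_k, red_k, left=0.0)
        above = lam > lam_k[-1]
        if np.any(above):
            slope = (red_k[-1] - red_k[-2]) / (lam_k[-1] - lam_k[-2])
            red[above] = red_k[-1] + slope * (lam[above] - lam_k[-1])
    elif clamp_policy == "clamp":
        red = np.interp(lam, lam_k, red_k, left=0.0)  # np.interp clamps right
    else:
        raise ValueError(f"unknown clamp policy {clamp_policy!r}")
    sol.reduction_elem = np.asarray(red, dtype=float)
    return sol


def export_field(sol: RodSolution, mesh: RodMesh, path: str | Path) -> Path:
    """Write the deformed rod as a legacy-ASCII VTK unstructured grid.

    Nodes advance axially by the cumulative element elongations; the local
    radius scales as lam**-1/2 (isochoric uniaxial kinematics) and is
    stored as point data. Cell data: stretch, axial_stress_MPa and, when
    mapped, cap_reduction_pct.
    """
    path = Path(path)
    lam, dL = sol.lam_elem, mesh.dL_elem
    z_def = mesh.z_nodes[0] + np.concatenate([[0.0], np.cumsum(lam * dL)])
    r0 = np.sqrt(mesh.A0_elem / np.pi)
    # node radius: mean of adjacent element radii after thinning
    r_elem = r0 / np.sqrt(lam)
    r_nodes = np.concatenate([[r_elem[0]], 0.5 * (r_elem[:-1] + r_elem[1:]), [r_elem[-1]]])

    n_pts, n_cells = z_def.size, lam.size
    lines = [
        "# vtk DataFile Version 3.0",
        "deformed axisymmetric nerve rod",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n_pts} double",
    ]
    lines += [f"{z:.17g} 0 0" for z in z_def]
    lines.append(f"CELLS {n_cells} {3 * n_cells}")
    lines += [f"2 {i} {i + 1}" for i in range(n_cells)]
    lines.append(f"CELL_TYPES {n_cells}")
    lines += ["3"] * n_cells  # VTK_LINE

    def scalars(name: str, vals: np.ndarray) -> list[str]:
        return [f"SCALARS {name} double 1", "LOOKUP_TABLE default"] + [
            f"{v:.17g}" for v in vals
        ]

    lines.append(f"CELL_DATA {n_cells}")
    lines += scalars("stretch", lam)
    lines += scalars("axial_stress_MPa", sol.T11_elem)
    if sol.reduction_elem is not None:
        lines += scalars("cap_reduction_pct", sol.reduction_elem)
    lines.append(f"POINT_DATA {n_pts}")
    lines += scalars("radius_mm", r_nodes)
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as err:
        raise OSError(f"cannot write VTK file {path}: {err}") from err
    return path
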