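"""Recovery of the computational start shape from in vivo geometry.

Imaged cross-sections are acquired while the vessel is pressurized and
axially stretched, so using them directly as a stress-free reference would
overestimate the in vivo lumen.  Two preconditioning steps recover a start
shape whose pressurized, stretched state reproduces the imaged contours:

* axial shrink-stretch: the slab is shortened geometrically by 1/lam_z and
  then stretched back to lam_z (default 5%) during the solve;
* circumferential pre-shrink: a uniform in-plane scale factor s about the
  lumen centroid is found by a scalar root-find so that the re-inflated
  lumen circumference matches the imaged one within a relative tolerance
  (default 0.5%).

The shrunk configuration is stress-free by construction; all stresses and
strains reported downstream are measured relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import VesselSliceContours
from .fem import MMHG_TO_KPA, SolutionField, SolverError, solve_inflation
from .materials import MaterialRegistry
from .mesh import ThinSliceMesh, build_mesh

__all__ = ["PreshrinkResult", "axial_prestretch_factor", "circumferential_preshrink",
           "PreshrinkError"]


class PreshrinkError(RuntimeError):
    """The shrink-factor root-find failed (no bracket or no convergence)."""


def axial_prestretch_factor(axial_stretch_fraction: float = 0.05) -> float:
    """Axial stretch ratio applied during the solve (default 5% -> 1.05).

    The paired geometric shrink applied to the slab beforehand is the
    reciprocal, so the stretched slab recovers the imaged thickness.
    """
    if axial_stretch_fraction < 0:
        raise ValueError("axial stretch fraction must be >= 0")
    return 1.0 + axial_stretch_fraction


@dataclass
class PreshrinkResult:
    """Converged circumferential pre-shrink of one slice model."""

    shrink_factor: float
    mesh: ThinSliceMesh                # shrunk (stress-free) mesh
    solution: SolutionField            # inflation of the shrunk mesh
    residual: float                    # |recovered/target - 1| of lumen circumference
    iterations: int
    target_circumference: float


def _solve_scaled(mesh0: ThinSliceMesh, registry: MaterialRegistry, s: float,
                  pressure: float, lam_z: float, n_steps: int, tol: float,
                  warm: tuple[ThinSliceMesh, SolutionField, float] | None = None):
    mesh_s = mesh0.scaled_inplane(s)
    if warm is not None:
        # warm start: the converged deformed shape is close to the imaged
        # geometry for every shrink iterate, so transport the previous
        # deformed configuration, rescaled in-plane to the target
        # circumference, and try a one-shot Newton solve at full load
        mesh_prev, sol_prev, scale = warm
        x_prev = mesh_prev.nodes + sol_prev.displacements
        c = mesh_s.centroid
        x_guess = x_prev.copy()
        x_guess[:, :2] = c + scale * (x_prev[:, :2] - c)
        u0 = (x_guess - mesh_s.nodes).ravel()
        try:
            sol = solve_inflation(mesh_s, registry, pressure, lam_z,
                                  n_steps=1, tol=tol, u0=u0, max_newton=25,
                                  allow_substeps=False)
            return mesh_s, sol
        except SolverError:
            pass
    sol = solve_inflation(mesh_s, registry, pressure, lam_z,
                          n_steps=n_steps, tol=tol)
    return mesh_s, sol


def circumferential_preshrink(slc: VesselSliceContours, registry: MaterialRegistry,
                              pressure: float, axial_stretch: float = 1.05,
                              tol: float = 0.005, max_iter: int = 25,
                              bracket: tuple[float, float] = (0.85, 1.0),
                              mesh_options: dict | None = None,
                              solver_tol: float = 1e-8) -> PreshrinkResult:
    """Find the uniform in-plane shrink factor for one slice.

    The slice is meshed once; candidate factors scale the mesh in-plane
    about the lumen centroid (the axial shrink 1/lam_z is applied to the
    slab first).  Root-finding is a bracketed secant/bisection hybrid on
    f(s) = recovered/target - 1; inner iterations use a relaxed solver
    setting, the returned solution is re-solved at full tolerance.

    ``pressure`` is in kPa.
    """
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    slc.validate()
    opts = dict(mesh_options or {})
    mesh0 = build_mesh(slc, **opts).scaled_axial(1.0 / axial_stretch)
    # target on the same ray discretization as the recovered ring
    ring = mesh0.nodes[mesh0.inner_ring][:, :2]
    d = np.diff(np.vstack([ring, ring[:1]]), axis=0)
    target = float(np.hypot(d[:, 0], d[:, 1]).sum())

    if pressure == 0.0 and abs(axial_stretch - 1.0) < 1e-14:
        mesh_s, sol = _solve_scaled(mesh0, registry, 1.0, 0.0, 1.0, 1, solver_tol)
        return PreshrinkResult(1.0, mesh_s, sol, 0.0, 1, target)

    lo, hi = bracket
    warm: list = [None]                 # last converged (mesh, solution)

    def residual_at(s, fast=True):
        mesh_s, sol = _solve_scaled(
            mesh0, registry, s, pressure, axial_stretch,
            n_steps=11 if fast else 12, tol=1e-7 if fast else solver_tol,
            warm=warm[0])
        rec = sol.lumen_circumference()
        warm[0] = (mesh_s, sol, target / rec)
        return rec / target - 1.0, mesh_s, sol

    def finalize(s, evals):
        mesh_s, sol = _solve_scaled(mesh0, registry, s, pressure, axial_stretch,
                                    n_steps=12, tol=solver_tol, warm=warm[0])
        res = abs(sol.lumen_circumference() / target - 1.0)
        return PreshrinkResult(s, mesh_s, sol, res, evals, target)

    evals = 0
    # endpoint s = 1 first: vessels inflate, so f(1) >= 0 is expected
    f_hi, mesh_hi, sol_hi = residual_at(hi)
    evals += 1
    if abs(f_hi) <= tol:
        return finalize(hi, evals)
    if f_hi < 0:
        raise PreshrinkError(
            "preshrink bracket: inflated geometry is smaller than imaged at s=1 "
            f"(f={f_hi:.4f}); imaged state inconsistent with loading")

    # secant march from s=1 before falling back to bisection; the residual
    # is close to affine in s, so this usually brackets and converges in
    # two or three further solves
    a, fa = None, None                  # best negative-side point
    b, fb = hi, f_hi
    s, f = hi, f_hi
    for _ in range(max_iter):
        if a is None:
            # estimate: circumference scales ~ linearly with s
            s_new = max(lo, b / (1.0 + fb))
            if s_new >= b - 1e-5:
                s_new = b - 0.01
        else:
            s_sec = b - fb * (b - a) / (fb - fa)
            s_new = s_sec if a + 1e-5 < s_sec < b - 1e-5 else 0.5 * (a + b)
        f, mesh_s, sol = residual_at(s_new)
        evals += 1
        if abs(f) <= tol:
            return finalize(s_new, evals)
        if f > 0:
            b, fb = s_new, f
        else:
            a, fa = s_new, f
        if a is None and s_new <= lo + 1e-12:
            raise PreshrinkError(
                f"preshrink bracket: no sign change on [{lo}, {hi}] "
                f"(f({lo})={f:.4f}, f({hi})={f_hi:.4f})")
    raise PreshrinkError(f"preshrink did not converge in {max_iter} iterations "
                         f"(last residual {f:.4f})")


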