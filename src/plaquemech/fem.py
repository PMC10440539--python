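"""Quasi-static nearly-incompressible anisotropic hyperelastic inflation of
the thin-slice mesh.

Total-Lagrangian trilinear hexahedra with selective reduced integration
(mean dilatation): the isochoric stress is integrated at 2x2x2 Gauss points,
the volumetric penalty at the element centroid, which avoids volumetric
locking without a mixed formulation.  The lumen pressure is a follower load
evaluated on the current configuration.  The z- face is fixed axially, the
z+ face receives the prescribed axial stretch as a uniform displacement
(plane sections), and the three in-plane rigid modes (two translations, one
rotation) are removed by Lagrange-multiplier constraints on the mean
displacement and mean in-plane moment, which leaves deformation unrestrained.

The load (pressure and axial stretch together) is ramped through a
doubling schedule of at least five increments — the wall is softest near the
reference state and stiffens exponentially, so early increments must be
small — with Newton iteration, backtracking line search, and automatic step
halving down to 1/64 of an increment on divergence.  The material tangent
is obtained by numerical differentiation of the second Piola-Kirchhoff
stress; the (nonsymmetric) follower-load stiffness is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import (DeformationOutOfRangeError, MaterialRegistry,
                        volumetric_penalty)
from .mesh import ThinSliceMesh

__all__ = ["SolutionField", "SolverError", "solve_inflation",
           "mesh_convergence_study", "MMHG_TO_KPA"]

MMHG_TO_KPA = 0.133322

# canonical trilinear hex: (xi, eta, zeta) signs per node
_SIGNS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)
_G = 1.0 / np.sqrt(3.0)
_GPTS_FULL = np.array([[sx * _G, sy * _G, sz * _G] for sx, sy, sz in _SIGNS])
_GPTS_CENTROID = np.zeros((1, 3))
_W_FULL = np.ones(8)
_W_CENTROID = np.array([8.0])

_FACE_SIGNS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
_FG = np.array([[sx * _G, sy * _G] for sx, sy in _FACE_SIGNS])


class SolverError(RuntimeError):
    """Newton divergence or element inversion that step halving cannot fix."""


def _dN_dxi(gpts: np.ndarray) -> np.ndarray:
    """(ngp, 8, 3) shape-function gradients in parent coordinates."""
    ngp = len(gpts)
    out = np.empty((ngp, 8, 3))
    for g, (xi, eta, zeta) in enumerate(gpts):
        for a, (sx, sy, sz) in enumerate(_SIGNS):
            out[g, a] = 0.125 * np.array([
                sx * (1 + sy * eta) * (1 + sz * zeta),
                (1 + sx * xi) * sy * (1 + sz * zeta),
                (1 + sx * xi) * (1 + sy * eta) * sz,
            ])
    return out


def _shape_values(gpts: np.ndarray) -> np.ndarray:
    vals = np.empty((len(gpts), 8))
    for g, (xi, eta, zeta) in enumerate(gpts):
        vals[g] = 0.125 * (1 + _SIGNS[:, 0] * xi) * (1 + _SIGNS[:, 1] * eta) * (1 + _SIGNS[:, 2] * zeta)
    return vals


_DN_FULL = _dN_dxi(_GPTS_FULL)
_DN_CENTROID = _dN_dxi(_GPTS_CENTROID)
_N_FULL = _shape_values(_GPTS_FULL)


def _shape_gradients_ref(elnodes: np.ndarray, gpts: str = "full"):
    """Reference-coordinate shape gradients and weighted Jacobians.

    Returns G (E, ngp, 8, 3) with G[e, g, a] = dN_a/dX at the Gauss point
    and wdet (E, ngp) = quadrature weight x det(dX/dxi).
    """
    dN = _DN_FULL if gpts == "full" else _DN_CENTROID
    w = _W_FULL if gpts == "full" else _W_CENTROID
    J = np.einsum("gad,eax->egxd", dN, elnodes)      # dX/dxi
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    G = np.einsum("gad,egdx->egax", dN, Jinv)
    return G, w[None, :] * detJ


@dataclass
class SolutionField:
    """Converged displacement and recovered nodal stress/strain fields."""

    mesh: ThinSliceMesh
    displacements: np.ndarray          # (N, 3) mm
    node_stress: np.ndarray            # (N, 3, 3) Cauchy, kPa
    node_strain: np.ndarray            # (N, 3, 3) Green-Lagrange
    sigma_max: np.ndarray              # (N,) max principal Cauchy stress
    eps_max: np.ndarray                # (N,) max principal Green-Lagrange strain
    pressure: float                    # kPa
    axial_stretch: float
    newton_iterations: int
    load_steps: int
    residual_norm: float
    load_norm: float
    j_range: tuple[float, float]
    external_force: np.ndarray = field(repr=False, default=None)
    residual: np.ndarray = field(repr=False, default=None)
    free_dofs: np.ndarray = field(repr=False, default=None)
    elem_stress: np.ndarray = field(repr=False, default=None)   # (E, 3, 3) at centroid
    elem_centroid: np.ndarray = field(repr=False, default=None)  # (E, 3) deformed

    @property
    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.displacements

    def lumen_circumference(self) -> float:
        """Perimeter of the deformed lumen ring on the z=0 face."""
        ring = self.deformed_nodes[self.mesh.inner_ring][:, :2]
        d = np.diff(np.vstack([ring, ring[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def ring_values(self, which: str = "inner") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(angles, sigma_max, eps_max) on the lumen or outer node ring."""
        ids = self.mesh.inner_ring if which == "inner" else self.mesh.outer_ring
        return self.mesh.ray_angles, self.sigma_max[ids], self.eps_max[ids]


class _Problem:
    """Precomputed element data for one mesh + material assignment."""

    def __init__(self, mesh: ThinSliceMesh, registry: MaterialRegistry,
                 layer_mode: str | None = None):
        self.mesh = mesh
        self.layer_mode = layer_mode or mesh.layer_mode
        elnodes = mesh.nodes[mesh.elements]
        self.Gd, self.wd = _shape_gradients_ref(elnodes, "full")
        self.Gc, self.wc = _shape_gradients_ref(elnodes, "centroid")
        if np.any(self.wd <= 0) or np.any(self.wc <= 0):
            raise SolverError("non-positive reference Jacobian in mesh")
        # group elements by material
        self.groups = []
        regions = np.asarray(mesh.region)
        for reg_name in np.unique(regions.astype(str)):
            idx = np.where(regions.astype(str) == reg_name)[0]
            mat = registry.for_region(reg_name, self.layer_mode)
            kappa = volumetric_penalty(mat)
            e_c = mesh.frames[idx, :, 0]
            e_a = mesh.frames[idx, :, 2]
            phi = np.deg2rad(mat.phi_deg)
            H = (np.cos(phi) ** 2 * np.einsum("ei,ej->eij", e_c, e_c)
                 + np.sin(phi) ** 2 * np.einsum("ei,ej->eij", e_a, e_a))
            self.groups.append((idx, mat, kappa, H))
        # assembly indices
        ne, nn = mesh.n_elements, mesh.n_nodes
        dofmap = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)
        self.rows = np.repeat(dofmap, 24, axis=1).ravel()
        self.cols = np.tile(dofmap, (1, 24)).ravel()
        self.dofmap = dofmap
        self.ndof = 3 * nn

    # -- constitutive wrappers -------------------------------------------
    def _stress_dev(self, C: np.ndarray, mat, H: np.ndarray) -> np.ndarray:
        from .materials import pk2_isochoric
        Hb = H[:, None, :, :] if C.ndim == 4 else H
        return pk2_isochoric(C, mat, Hb)

    def _stress_vol(self, C: np.ndarray, kappa: float) -> np.ndarray:
        from .materials import pk2_volumetric
        return pk2_volumetric(C, kappa)

    def _tangent_fd(self, C: np.ndarray, stress_fn, S0: np.ndarray,
                    h: float = 1e-7) -> np.ndarray:
        """Numerical dS/dE (minor-symmetric), one-sided differences reusing
        the already-computed stress, vectorized over leading axes."""
        shape = C.shape[:-2]
        D = np.empty(shape + (3, 3, 3, 3))
        for K in range(3):
            for L in range(K, 3):
                dC = np.zeros((3, 3))
                dC[K, L] += h
                dC[L, K] += h
                col = (stress_fn(C + dC) - S0) / h
                D[..., K, L] = col
                D[..., L, K] = col
        return D

    # -- assembly --------------------------------------------------------
    def internal_force_and_tangent(self, u: np.ndarray, want_tangent: bool = True):
        mesh = self.mesh
        ue = u.reshape(-1, 3)[mesh.elements]            # (E, 8, 3)
        eye = np.eye(3)
        Fd = eye + np.einsum("eai,egaJ->egiJ", ue, self.Gd)
        Fc = eye + np.einsum("eai,egaJ->egiJ", ue, self.Gc)
        Jd = np.linalg.det(Fd)
        Jc = np.linalg.det(Fc)
        if np.any(Jd <= 0) or np.any(Jc <= 0):
            raise _InvertedElement()
        Cd = np.einsum("egiI,egiJ->egIJ", Fd, Fd)
        Cc = np.einsum("egiI,egiJ->egIJ", Fc, Fc)

        ne = mesh.n_elements
        fint = np.zeros((ne, 8, 3))
        Ke = np.zeros((ne, 24, 24)) if want_tangent else None
        for idx, mat, kappa, H in self.groups:
            # deviatoric part at full quadrature
            Sd = self._stress_dev(Cd[idx], mat, H)
            self._accumulate(fint, Ke, idx, Fd[idx], Sd, self.Gd[idx], self.wd[idx],
                             lambda Cq, m=mat, Hq=H: self._stress_dev(Cq, m, Hq),
                             Cd[idx], want_tangent)
            # volumetric part at centroid
            Sv = self._stress_vol(Cc[idx], kappa)
            self._accumulate(fint, Ke, idx, Fc[idx], Sv, self.Gc[idx], self.wc[idx],
                             lambda Cq, k=kappa: self._stress_vol(Cq, k),
                             Cc[idx], want_tangent)
        f = np.zeros(self.ndof)
        np.add.at(f, self.dofmap.ravel(), fint.reshape(ne, 24).ravel())
        K = None
        if want_tangent:
            K = sp.coo_matrix((Ke.ravel(), (self.rows, self.cols)),
                              shape=(self.ndof, self.ndof)).tocsr()
        return f, K, (Jd, Jc)

    def _accumulate(self, fint, Ke, idx, F, S, G, w, stress_fn, C, want_tangent):
        P = np.einsum("egiI,egIJ->egiJ", F, S, optimize=True)
        fint[idx] += np.einsum("egiJ,egaJ,eg->eai", P, G, w, optimize=True)
        if not want_tangent:
            return
        D = self._tangent_fd(C, stress_fn, S0=S)
        # geometric part: delta_ij G_aJ S_JL G_bL
        BSB = np.einsum("egaJ,egJL,egbL,eg->eab", G, S, G, w, optimize=True)
        Kg = np.einsum("eab,ij->eaibj", BSB, np.eye(3), optimize=True)
        # material part: (F_iI G_aJ) D_IJKL (F_jK G_bL)
        A = np.einsum("egiI,egIJKL,egjK->egiJjL", F, D, F, optimize=True)
        Km = np.einsum("egaJ,egiJjL,egbL,eg->eaibj", G, A, G, w, optimize=True)
        Ke[idx] += (Kg + Km).reshape(len(idx), 24, 24)

    # -- follower pressure -----------------------------------------------
    def pressure_force(self, u: np.ndarray, pressure: float) -> np.ndarray:
        """Consistent nodal force of the lumen follower pressure (current
        configuration, 2x2 Gauss per quad face)."""
        f = np.zeros(self.ndof)
        if pressure == 0.0 or len(self.mesh.lumen_faces) == 0:
            return f
        faces = self.mesh.lumen_faces
        x = (self.mesh.nodes + u.reshape(-1, 3))[faces]      # (F, 4, 3)
        for xi, eta in _FG:
            M = 0.25 * (1 + _FACE_SIGNS[:, 0] * xi) * (1 + _FACE_SIGNS[:, 1] * eta)
            dM = np.stack([0.25 * _FACE_SIGNS[:, 0] * (1 + _FACE_SIGNS[:, 1] * eta),
                           0.25 * (1 + _FACE_SIGNS[:, 0] * xi) * _FACE_SIGNS[:, 1]], axis=1)
            g1 = np.einsum("a,fax->fx", dM[:, 0], x)
            g2 = np.einsum("a,fax->fx", dM[:, 1], x)
            n = np.cross(g1, g2)                              # points into the wall
            contrib = pressure * np.einsum("a,fx->fax", M, n)
            np.add.at(f.reshape(-1, 3), faces.ravel(), contrib.reshape(-1, 3))
        return f


    def pressure_stiffness(self, u: np.ndarray, pressure: float) -> sp.csr_matrix | None:
        """Load stiffness d f_ext / d u of the follower pressure
        (nonsymmetric; subtracted from the tangent in Newton)."""
        if pressure == 0.0 or len(self.mesh.lumen_faces) == 0:
            return None
        faces = self.mesh.lumen_faces
        x = (self.mesh.nodes + u.reshape(-1, 3))[faces]
        eps = np.zeros((3, 3, 3))
        eps[0, 1, 2] = eps[1, 2, 0] = eps[2, 0, 1] = 1.0
        eps[0, 2, 1] = eps[1, 0, 2] = eps[2, 1, 0] = -1.0
        Kf = np.zeros((len(faces), 4, 3, 4, 3))
        for xi, eta in _FG:
            M = 0.25 * (1 + _FACE_SIGNS[:, 0] * xi) * (1 + _FACE_SIGNS[:, 1] * eta)
            dM1 = 0.25 * _FACE_SIGNS[:, 0] * (1 + _FACE_SIGNS[:, 1] * eta)
            dM2 = 0.25 * (1 + _FACE_SIGNS[:, 0] * xi) * _FACE_SIGNS[:, 1]
            g1 = np.einsum("a,fax->fx", dM1, x)
            g2 = np.einsum("a,fax->fx", dM2, x)
            t1 = np.einsum("ijm,fm,b->fibj", eps, g2, dM1)
            t2 = np.einsum("imj,fm,b->fibj", eps, g1, dM2)
            Kf += pressure * np.einsum("a,fibj->faibj", M, t1 + t2)
        fdof = (3 * faces[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        rows = np.repeat(fdof, 12, axis=1).ravel()
        cols = np.tile(fdof, (1, 12)).ravel()
        return sp.coo_matrix((Kf.ravel(), (rows, cols)),
                             shape=(self.ndof, self.ndof)).tocsr()


class _InvertedElement(Exception):
    pass


def _rigid_constraints(mesh: ThinSliceMesh) -> sp.csr_matrix:
    """Three rows removing in-plane translations and the z-rotation."""
    n = mesh.n_nodes
    X = mesh.nodes[:, 0] - mesh.centroid[0]
    Y = mesh.nodes[:, 1] - mesh.centroid[1]
    L = sp.lil_matrix((3, 3 * n))
    ix = 3 * np.arange(n)
    L[0, ix] = 1.0
    L[1, ix + 1] = 1.0
    L[2, ix] = -Y
    L[2, ix + 1] = X
    return L.tocsr()


def solve_inflation(mesh: ThinSliceMesh, registry: MaterialRegistry,
                    pressure: float, axial_stretch: float = 1.05,
                    layer_mode: str | None = None, n_steps: int = 11,
                    tol: float = 1e-8, max_newton: int = 25,
                    u0: np.ndarray | None = None,
                    allow_substeps: bool = True) -> SolutionField:
    """Solve the thin-slice inflation problem.

    Parameters
    ----------
    pressure : lumen pressure in kPa (use MMHG_TO_KPA for unit conversion).
    axial_stretch : stretch prescribed via the z+ face displacement.
    n_steps : equal load increments (pressure and stretch ramped together).
    u0 : optional displacement warm start (e.g. from a previous pre-shrink
        iterate); it is used as the initial guess for the final load level.
    """
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    prob = _Problem(mesh, registry, layer_mode)
    ndof = prob.ndof
    L = _rigid_constraints(mesh)

    # Dirichlet data
    fixed = np.zeros(ndof, dtype=bool)
    target = np.zeros(ndof)
    zm = 3 * mesh.zminus_nodes + 2
    zp = 3 * mesh.zplus_nodes + 2
    fixed[zm] = True
    fixed[zp] = True
    target[zp] = (axial_stretch - 1.0) * mesh.thickness
    free = ~fixed
    Lf = L[:, free]

    u = np.zeros(ndof)
    total_newton = 0
    steps_done = 0
    if pressure == 0.0 and abs(axial_stretch - 1.0) < 1e-14:
        fint, _, (Jd, Jc) = prob.internal_force_and_tangent(u, want_tangent=False)
        return _recover(prob, u, pressure, axial_stretch, 0, 0, 0.0, 0.0,
                        np.zeros(ndof), fint, free)

    # dense-early (doubling) ramp: the wall is softest near the reference
    # state and stiffens exponentially, so small first increments avoid
    # wasted step halving while late doublings converge in a few iterations
    factors = [2.0 ** -(n_steps - 1 - k) for k in range(n_steps)]
    min_df = factors[0] / 64.0
    f_prev = 0.0
    pending = factors
    warm_used = False
    fext = np.zeros(ndof)
    u_last, f_last = None, None          # previous converged state (secant predictor)
    while pending:
        f_next = pending[0]
        u_try = u.copy()
        if u0 is not None and not warm_used and f_next == 1.0 and f_prev == 0.0:
            u_try = u0.copy()
        elif u_last is not None and f_prev > f_last:
            u_try = u + (u - u_last) * ((f_next - f_prev) / (f_prev - f_last))
        u_try[fixed] = f_next * target[fixed]
        ok, u_new, iters, res, loadn, fext = _newton(
            prob, u_try, fixed, free, Lf, f_next * pressure, f_next * target,
            tol, max_newton)
        if ok:
            u_last, f_last = u, f_prev
            u = u_new
            total_newton += iters
            steps_done += 1
            f_prev = f_next
            pending.pop(0)
            warm_used = True
        else:
            if not allow_substeps:
                raise SolverError("one-shot Newton from the warm start failed")
            df = f_next - f_prev
            if df / 2 < min_df:
                raise SolverError(
                    f"Newton failed at load factor {f_next:.4f} even at the "
                    f"minimum increment (trace: {steps_done} steps done)")
            pending.insert(0, f_prev + df / 2)

    fint, _, _ = prob.internal_force_and_tangent(u, want_tangent=False)
    return _recover(prob, u, pressure, axial_stretch, total_newton, steps_done,
                    res, loadn, fext, fint, free)


def _newton(prob, u, fixed, free, Lf, pressure, target, tol, max_newton):
    u = u.copy()
    u[fixed] = target[fixed]
    res_norm, load_norm, fext = np.inf, 0.0, np.zeros_like(u)
    for it in range(max_newton):
        try:
            fint, K, _ = prob.internal_force_and_tangent(u)
        except (_InvertedElement, DeformationOutOfRangeError):
            return False, u, it, np.inf, 0.0, fext
        fext = prob.pressure_force(u, pressure)
        R = fint - fext
        Rf = R[free]
        load_norm = max(np.linalg.norm(fext), np.linalg.norm(fint), 1e-9)
        res_norm = np.linalg.norm(Rf)
        if res_norm < tol * load_norm or res_norm < 1e-12:
            return True, u, it, res_norm, load_norm, fext
        Kload = prob.pressure_stiffness(u, pressure)
        if Kload is not None:
            K = K - Kload
        Kff = K[free][:, free]
        nfree = Kff.shape[0]
        A = sp.bmat([[Kff, Lf.T], [Lf, None]], format="csc")
        rhs = np.concatenate([-Rf, -Lf @ u[free]])
        try:
            sol = spla.spsolve(A, rhs)
        except Exception:
            return False, u, it, res_norm, load_norm, fext
        du = sol[:nfree]
        if not np.all(np.isfinite(du)):
            return False, u, it, res_norm, load_norm, fext
        # simple backtracking on residual increase; deep halving because the
        # soft-ground-state layers make early linearized steps overshoot
        alpha = 1.0
        for _ in range(14):
            u_new = u.copy()
            u_new[free] += alpha * du
            try:
                fint_n, _, _ = prob.internal_force_and_tangent(u_new, want_tangent=False)
                fext_n = prob.pressure_force(u_new, pressure)
                new_norm = np.linalg.norm((fint_n - fext_n)[free])
            except (_InvertedElement, DeformationOutOfRangeError):
                alpha *= 0.5
                continue
            if new_norm <= max(res_norm * 1.5, tol * load_norm):
                break
            alpha *= 0.5
        else:
            return False, u, it, res_norm, load_norm, fext
        u = u_new
    return False, u, max_newton, res_norm, load_norm, fext


def _recover(prob, u, pressure, axial_stretch, iters, steps, res, loadn,
             fext, fint, free) -> SolutionField:
    """Nodal stress/strain recovery by shape-weighted Gauss-point averaging."""
    mesh = prob.mesh
    ue = u.reshape(-1, 3)[mesh.elements]
    eye = np.eye(3)
    Fd = eye + np.einsum("eai,egaJ->egiJ", ue, prob.Gd)
    Fc = eye + np.einsum("eai,egaJ->egiJ", ue, prob.Gc)
    Cd = np.einsum("egiI,egiJ->egIJ", Fd, Fd)
    Jd = np.linalg.det(Fd)
    Jc = np.linalg.det(Fc)

    ne = mesh.n_elements
    sig = np.zeros((ne, 8, 3, 3))
    sig_c = np.zeros((ne, 3, 3))
    Cc = np.einsum("egiI,egiJ->egIJ", Fc, Fc)
    for idx, mat, kappa, H in prob.groups:
        S = prob._stress_dev(Cd[idx], mat, H)
        s = np.einsum("egiI,egIJ,egjJ->egij", Fd[idx], S, Fd[idx]) / Jd[idx][..., None, None]
        # volumetric (mean-dilatation) pressure from the centroid J
        pvol = kappa * (Jc[idx, 0] - 1.0)
        s += pvol[:, None, None, None] * eye
        sig[idx] = 0.5 * (s + np.swapaxes(s, -1, -2))
        Sc = prob._stress_dev(Cc[idx], mat, H)
        sc = (np.einsum("egiI,egIJ,egjJ->egij", Fc[idx], Sc, Fc[idx])
              / Jc[idx][..., None, None])[:, 0]
        sc += pvol[:, None, None] * eye
        sig_c[idx] = 0.5 * (sc + np.swapaxes(sc, -1, -2))
    E = 0.5 * (Cd - eye)

    nn = mesh.n_nodes
    num_s = np.zeros((nn, 3, 3))
    num_e = np.zeros((nn, 3, 3))
    den = np.zeros(nn)
    w = _N_FULL                                   # (8 gp, 8 nodes)
    ws = np.einsum("ga,egij->eaij", w, sig)
    we = np.einsum("ga,egij->eaij", w, E)
    wsum = np.broadcast_to(w.sum(axis=0), (ne, 8))
    np.add.at(num_s, mesh.elements.ravel(), ws.reshape(-1, 3, 3))
    np.add.at(num_e, mesh.elements.ravel(), we.reshape(-1, 3, 3))
    np.add.at(den, mesh.elements.ravel(), wsum.ravel())
    node_s = num_s / den[:, None, None]
    node_e = num_e / den[:, None, None]
    sig_max = np.linalg.eigvalsh(node_s)[:, -1]
    eps_max = np.linalg.eigvalsh(node_e)[:, -1]

    return SolutionField(
        mesh=mesh, displacements=u.reshape(-1, 3), node_stress=node_s,
        node_strain=node_e, sigma_max=sig_max, eps_max=eps_max,
        pressure=pressure, axial_stretch=axial_stretch,
        newton_iterations=iters, load_steps=steps, residual_norm=res,
        # volume ratio at the mean-dilatation (element) level, the quantity
        # the volumetric penalty controls
        load_norm=loadn, j_range=(float(Jc.min()), float(Jc.max())),
        external_force=fext, residual=fint - fext, free_dofs=free,
        elem_stress=sig_c,
        elem_centroid=(mesh.nodes + u.reshape(-1, 3))[mesh.elements].mean(axis=1),
    )


def mesh_convergence_study(slc, registry: MaterialRegistry, pressure: float,
                           axial_stretch: float = 1.05,
                           base_options: dict | None = None,
                           threshold: float = 0.02, shrink: float = 0.9,
                           max_refinements: int = 10):
    """Refine the mesh until the peak inner-wall stress stabilizes.

    The characteristic element size is reduced by ``1 - shrink`` (10% by
    default) in each in-plane dimension per refinement; the study stops when
    the relative change of the maximum principal stress on the lumen ring
    between successive meshes falls below ``threshold`` (2%).

    Returns (accepted mesh options, report), where report is a list of
    dicts with the resolution, the metric, and the successive difference.
    """
    from .mesh import build_mesh

    opts = dict(n_rays=32, n_radial_per_layer=2, n_slabs=1)
    if base_options:
        opts.update(base_options)

    def metric(o):
        mesh = build_mesh(slc, **o)
        sol = solve_inflation(mesh, registry, pressure, axial_stretch)
        return float(sol.sigma_max[mesh.inner_ring].max()), sol

    report = []
    prev, sol = metric(opts)
    report.append({"options": dict(opts), "max_inner_stress": prev, "diff": None})
    for _ in range(max_refinements):
        new = dict(opts)
        new["n_rays"] = int(np.ceil(opts["n_rays"] / shrink))
        new["n_radial_per_layer"] = int(np.ceil(opts["n_radial_per_layer"] / shrink))
        cur, sol = metric(new)
        diff = abs(cur - prev) / abs(prev)
        report.append({"options": dict(new), "max_inner_stress": cur, "diff": diff})
        if diff < threshold:
            return new, report, sol
        opts, prev = new, cur
    raise SolverError(
        "mesh convergence not reached after "
        f"{max_refinements} refinements; differences: "
        + ", ".join(f"{r['diff']:.3f}" for r in report[1:]))
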