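"""Semi-analytic inflation of a layered incompressible thick-walled cylinder.

Independent verification oracle for the finite-element solver: a concentric
multilayer vessel under internal pressure and fixed axial stretch admits a
one-dimensional solution.  With exact incompressibility the deformation is

    r(R) = sqrt(r_in^2 + (R^2 - R_in^2) / lam_z),
    lam_theta = r / R,  lam_r = 1 / (lam_theta lam_z),

and radial equilibrium d(sigma_r)/dr = (sigma_theta - sigma_r) / r
integrates through the wall with the layer energies, using the classic
reduced-energy identities

    sigma_theta - sigma_r = lam_theta dW^/d lam_theta,
    sigma_z    - sigma_r = lam_z    dW^/d lam_z,

where W^(lam_theta, lam_z) eliminates lam_r by incompressibility.  The inner
deformed radius is found by a bracketed root so that sigma_r(inner) = -p and
sigma_r(outer) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .materials import DeformationOutOfRangeError, MaterialParams, _incompressible_energy

__all__ = ["CylinderSolution", "axisym_cylinder_oracle"]

_H = 1e-6


def _reduced_stress_diffs(p: MaterialParams, lam_t: float, lam_z: float) -> tuple[float, float]:
    """(sigma_theta - sigma_r, sigma_z - sigma_r) at one material point."""
    lam_r = 1.0 / (lam_t * lam_z)

    def W(lt, lr, lz):
        return _incompressible_energy(p, lt, lr, lz)

    Wt = (W(lam_t + _H, lam_r, lam_z) - W(lam_t - _H, lam_r, lam_z)) / (2 * _H)
    Wr = (W(lam_t, lam_r + _H, lam_z) - W(lam_t, lam_r - _H, lam_z)) / (2 * _H)
    Wz = (W(lam_t, lam_r, lam_z + _H) - W(lam_t, lam_r, lam_z - _H)) / (2 * _H)
    return lam_t * Wt - lam_r * Wr, lam_z * Wz - lam_r * Wr


@dataclass(frozen=True)
class CylinderSolution:
    """Radial stress profiles of the inflated layered cylinder (kPa, mm)."""

    r: np.ndarray              # deformed radii
    R: np.ndarray              # reference radii
    sigma_r: np.ndarray
    sigma_theta: np.ndarray
    sigma_z: np.ndarray
    layer_index: np.ndarray    # which layer each sample belongs to
    r_inner: float
    r_outer: float
    pressure: float
    lam_z: float

    def hoop_at(self, r_query: np.ndarray) -> np.ndarray:
        """Hoop stress interpolated at deformed radii (within one layer the
        profile is smooth; queries should not straddle interfaces)."""
        return np.interp(np.asarray(r_query, dtype=float), self.r, self.sigma_theta)


def axisym_cylinder_oracle(layer_radii: np.ndarray, materials: list[MaterialParams],
                           pressure: float, lam_z: float = 1.0,
                           n_per_layer: int = 200) -> CylinderSolution:
    """Solve layered incompressible cylinder inflation.

    Parameters
    ----------
    layer_radii : increasing reference radii [R_in, R_1, ..., R_out] (mm);
        layer k spans (R_k, R_{k+1}).
    materials : one parameter set per layer (len = len(layer_radii) - 1).
    pressure : internal pressure (kPa), >= 0.
    lam_z : axial stretch held fixed during inflation.
    """
    Rb = np.asarray(layer_radii, dtype=float)
    if Rb.ndim != 1 or len(Rb) < 2 or np.any(np.diff(Rb) <= 0):
        raise ValueError("layer_radii must be strictly increasing")
    if len(materials) != len(Rb) - 1:
        raise ValueError("need one material per layer")
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    R_in, R_out = Rb[0], Rb[-1]

    # Reference-radius sample grid with layer bookkeeping.
    R_list, layer_ix = [], []
    for k in range(len(materials)):
        Rk = np.linspace(Rb[k], Rb[k + 1], n_per_layer)
        R_list.append(Rk)
        layer_ix.append(np.full(n_per_layer, k))
    R = np.concatenate(R_list)
    layer_ix = np.concatenate(layer_ix)

    def net_pressure(r_in: float) -> float:
        r = np.sqrt(r_in**2 + (R**2 - R_in**2) / lam_z)
        lam_t = r / R
        dsig = np.array([_reduced_stress_diffs(materials[k], lt, lam_z)[0]
                         for k, lt in zip(layer_ix, lam_t)])
        # integrand in R: (sigma_t - sigma_r)/r * dr/dR, dr/dR = R/(lam_z r)
        integrand = dsig * R / (lam_z * r**2)
        return float(np.trapezoid(integrand, R)) - pressure

    # net_pressure is increasing in r_in; bracket on a grid, skipping
    # candidates rejected by the physical-range guard.
    def safe(x):
        try:
            return net_pressure(x)
        except DeformationOutOfRangeError:
            return np.nan

    grid = R_in * np.geomspace(0.4, 2.5, 48)
    vals = np.array([safe(x) for x in grid])
    ok = np.isfinite(vals)
    cross = np.where(ok[:-1] & ok[1:] & (vals[:-1] * vals[1:] <= 0))[0]
    if len(cross) == 0:
        raise RuntimeError("cylinder oracle: no bracket for the inner radius")
    k = cross[0]
    r_in = brentq(net_pressure, grid[k], grid[k + 1], xtol=1e-12, rtol=1e-14)

    r = np.sqrt(r_in**2 + (R**2 - R_in**2) / lam_z)
    lam_t = r / R
    diffs = np.array([_reduced_stress_diffs(materials[k], lt, lam_z)
                      for k, lt in zip(layer_ix, lam_t)])
    integrand = diffs[:, 0] * R / (lam_z * r**2)
    sigma_r = -pressure + np.concatenate([[0.0], cumulative_trapezoid(integrand, R)])
    sigma_t = sigma_r + diffs[:, 0]
    sigma_z = sigma_r + diffs[:, 1]
    return CylinderSolution(r=r, R=R, sigma_r=sigma_r, sigma_theta=sigma_t,
                            sigma_z=sigma_z, layer_index=layer_ix,
                            r_inner=float(r[0]), r_outer=float(r[-1]),
                            pressure=pressure, lam_z=lam_z)
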