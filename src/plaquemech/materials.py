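"""Anisotropic hyperelastic constitutive models for arterial wall layers.

Each layer (intima, media, adventitia) and plaque component (lipid,
calcification) is a modified Mooney-Rivlin solid.  The isotropic energy is

    W_iso = c1 (I1 - 3) + c2 (I2 - 3) + D1 [exp(D2 (I1 - 3)) - 1]

and the layers add a single-fiber-family exponential reinforcement

    W_aniso = W_iso + (K1 / K2) [exp(K2 (I4 - 1)^2) - 1],

where I1, I2 are the invariants of the right Cauchy-Green tensor C = F^T F
and I4 = lambda_theta^2 cos^2(phi) + lambda_z^2 sin^2(phi) is the squared
stretch along a fiber family inclined at phi to the circumferential
direction in the theta-z plane.  Two symmetric families at +/-phi share this
I4 (their cross terms cancel), so the structure tensor used for general
deformation states is H = cos^2(phi) e_c e_c^T + sin^2(phi) e_a e_a^T.

Stress-like constants (c1, c2, D1, K1) are in kPa; D2, K2 are
dimensionless.  The fiber term only acts in tension (I4 > 1), the standard
convention that avoids fictitious compressive fiber support.

Near-incompressibility in the finite-element solver is enforced by a
volumetric penalty kappa (J - 1)^2 / 2 on top of the isochoric
(distortional-invariant) form of the energies; the closed-form uniaxial
stress-stretch curves use exact incompressibility instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MaterialParams", "MaterialRegistry", "DeformationState", "default_registry",
    "strain_energy_iso", "strain_energy_aniso", "fiber_invariant",
    "cauchy_stress", "stress_stretch_curve", "volumetric_penalty",
]

_EXP_GUARD = 50.0


class DeformationOutOfRangeError(FloatingPointError):
    """Exponential argument exceeded the physical-range guard."""


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive constants of one layer or component.

    c1, c2, D1, K1 in kPa; D2, K2 dimensionless; phi_deg is the fiber angle
    from the circumferential direction in degrees.  ``isotropic`` disables
    the fiber term (lipid, calcification).
    """

    name: str
    c1: float
    c2: float
    D1: float
    D2: float
    K1: float = 0.0
    K2: float = 1.0
    phi_deg: float = 0.0
    isotropic: bool = False

    def __post_init__(self):
        if self.D2 < 0:
            raise ValueError(f"{self.name}: D2 must be >= 0")
        if not self.isotropic and self.K1 != 0.0 and self.K2 <= 0:
            raise ValueError(f"{self.name}: K2 must be > 0 when the fiber term is active")
        if not 0.0 <= self.phi_deg <= 90.0:
            raise ValueError(f"{self.name}: phi must lie in [0, 90] degrees")

    @property
    def has_fibers(self) -> bool:
        return (not self.isotropic) and self.K1 != 0.0


# Layer-specific parameter values matched to published layer material curves
# for coronary/iliac arterial tissue; the intima fiber angle is taken as 0
# (circumferential), the convention of the curve source (see docs/methods.md).
_DEFAULTS = {
    "intima": MaterialParams("intima", c1=-169.23, c2=177.40, D1=2.4, D2=13.0,
                             K1=32.0, K2=36.0, phi_deg=0.0),
    "media": MaterialParams("media", c1=-67.25, c2=35.01, D1=17.0, D2=2.0,
                            K1=7.0, K2=4.0, phi_deg=24.9),
    "adventitia": MaterialParams("adventitia", c1=-94.44, c2=102.42, D1=0.8, D2=10.0,
                                 K1=10.0, K2=40.0, phi_deg=75.3),
    "lipid": MaterialParams("lipid", c1=0.5, c2=0.0, D1=0.5, D2=1.5, isotropic=True),
    "calcification": MaterialParams("calcification", c1=920.0, c2=0.0, D1=360.0, D2=2.0,
                                    isotropic=True),
}


class MaterialRegistry:
    """Named parameter sets for the three layers, the plaque components, and
    the combined single-layer wall."""

    def __init__(self, materials: dict[str, MaterialParams] | None = None,
                 single_layer_material: str = "intima"):
        mats = dict(_DEFAULTS) if materials is None else dict(materials)
        if "wall" not in mats:
            base = mats[single_layer_material]
            mats["wall"] = replace(base, name="wall")
        self.materials = mats

    def __getitem__(self, name: str) -> MaterialParams:
        return self.materials[name]

    def __contains__(self, name: str) -> bool:
        return name in self.materials

    def names(self) -> list[str]:
        return sorted(self.materials)

    def for_region(self, region: str, layer_mode: str = "multi") -> MaterialParams:
        """Material for a mesh region label under the given layer treatment."""
        if layer_mode not in ("multi", "single"):
            raise ValueError(f"layer_mode must be 'multi' or 'single', got {layer_mode!r}")
        if region in ("lipid", "calcification"):
            return self.materials[region]
        if layer_mode == "single" or region == "wall":
            return self.materials["wall"]
        return self.materials[region]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {name: asdict(p) for name, p in self.materials.items()}
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaterialRegistry":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls({name: MaterialParams(**entry) for name, entry in doc.items()})


def default_registry(single_layer_material: str = "intima") -> MaterialRegistry:
    """Registry with the published layer/component parameter values."""
    return MaterialRegistry(single_layer_material=single_layer_material)


# ---------------------------------------------------------------------------
# kinematics

@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient with cached invariants.

    ``lam_theta``/``lam_z`` are the circumferential/axial stretches in the
    slice frame when the state comes from a cylinder-type deformation; they
    feed the scalar fiber invariant I4.
    """

    F: np.ndarray
    lam_theta: float | None = None
    lam_z: float | None = None

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        object.__setattr__(self, "F", F)
        if np.linalg.det(F) <= 0:
            raise ValueError("det F must be positive")

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def I1(self) -> float:
        return float(np.trace(self.C))

    @property
    def I2(self) -> float:
        C = self.C
        return float(0.5 * (np.trace(C) ** 2 - np.trace(C @ C)))

    def I4(self, phi_deg: float) -> float:
        if self.lam_theta is None or self.lam_z is None:
            raise ValueError("I4 from stretches requires lam_theta and lam_z")
        return fiber_invariant(self.lam_theta, self.lam_z, phi_deg)

    @classmethod
    def from_stretches(cls, lam_theta: float, lam_r: float, lam_z: float) -> "DeformationState":
        """Diagonal state in the (circumferential, radial, axial) frame."""
        return cls(np.diag([lam_theta, lam_r, lam_z]), lam_theta=lam_theta, lam_z=lam_z)


def fiber_invariant(lam_theta: float, lam_z: float, phi_deg: float) -> float:
    """I4 = lambda_theta^2 cos^2(phi) + lambda_z^2 sin^2(phi)."""
    if lam_theta <= 0 or lam_z <= 0:
        raise ValueError("stretches must be positive")
    phi = np.deg2rad(phi_deg)
    return float(lam_theta**2 * np.cos(phi) ** 2 + lam_z**2 * np.sin(phi) ** 2)


# ---------------------------------------------------------------------------
# energies

def _guard(x, label: str):
    if np.any(np.asarray(x) > _EXP_GUARD):
        raise DeformationOutOfRangeError(
            f"{label} exponent exceeds {_EXP_GUARD}: deformation outside physical range")


def strain_energy_iso(state: DeformationState, p: MaterialParams) -> float:
    """Isotropic modified Mooney-Rivlin energy density (kPa)."""
    I1, I2 = state.I1, state.I2
    _guard(p.D2 * (I1 - 3.0), f"{p.name} D2(I1-3)")
    return float(p.c1 * (I1 - 3.0) + p.c2 * (I2 - 3.0)
                 + p.D1 * (np.exp(p.D2 * (I1 - 3.0)) - 1.0))


def fiber_energy(I4: float, p: MaterialParams) -> float:
    """Exponential fiber reinforcement energy (kPa); tension-only."""
    if not p.has_fibers or I4 <= 1.0:
        return 0.0
    _guard(p.K2 * (I4 - 1.0) ** 2, f"{p.name} K2(I4-1)^2")
    return float(p.K1 / p.K2 * (np.exp(p.K2 * (I4 - 1.0) ** 2) - 1.0))


def strain_energy_aniso(state: DeformationState, p: MaterialParams,
                        I4: float | None = None) -> float:
    """Layer energy: W_iso plus the fiber term (kPa).

    I4 is taken from the state's circumferential/axial stretches unless given
    explicitly.
    """
    if I4 is None:
        I4 = state.I4(p.phi_deg)
    return strain_energy_iso(state, p) + fiber_energy(I4, p)


def volumetric_penalty(p: MaterialParams, floor: float = 5000.0) -> float:
    """Penalty modulus kappa (kPa): 1000x the dominant stress constant, with
    a floor that keeps soft components (lipid) nearly incompressible too."""
    return max(1000.0 * max(abs(p.c1), abs(p.c2), p.D1), floor)


# ---------------------------------------------------------------------------
# stress (vectorized over leading axes; tensors are (..., 3, 3))

def structure_tensor(p: MaterialParams, frame: np.ndarray | None = None) -> np.ndarray:
    """Reference structure tensor H of the +/-phi fiber pair.

    ``frame`` columns are the (circumferential, radial, axial) unit vectors
    in reference coordinates; default is (x, y, z).
    """
    if frame is None:
        frame = np.eye(3)
    e_c, e_a = frame[:, 0], frame[:, 2]
    phi = np.deg2rad(p.phi_deg)
    return (np.cos(phi) ** 2 * np.outer(e_c, e_c)
            + np.sin(phi) ** 2 * np.outer(e_a, e_a))


def _inv_det_3x3(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Explicit cofactor inverse and determinant of (..., 3, 3) tensors
    (faster than np.linalg for the many small matrices in assembly)."""
    c = C
    cof = np.empty_like(c)
    cof[..., 0, 0] = c[..., 1, 1] * c[..., 2, 2] - c[..., 1, 2] * c[..., 2, 1]
    cof[..., 0, 1] = c[..., 1, 2] * c[..., 2, 0] - c[..., 1, 0] * c[..., 2, 2]
    cof[..., 0, 2] = c[..., 1, 0] * c[..., 2, 1] - c[..., 1, 1] * c[..., 2, 0]
    cof[..., 1, 0] = c[..., 0, 2] * c[..., 2, 1] - c[..., 0, 1] * c[..., 2, 2]
    cof[..., 1, 1] = c[..., 0, 0] * c[..., 2, 2] - c[..., 0, 2] * c[..., 2, 0]
    cof[..., 1, 2] = c[..., 0, 1] * c[..., 2, 0] - c[..., 0, 0] * c[..., 2, 1]
    cof[..., 2, 0] = c[..., 0, 1] * c[..., 1, 2] - c[..., 0, 2] * c[..., 1, 1]
    cof[..., 2, 1] = c[..., 0, 2] * c[..., 1, 0] - c[..., 0, 0] * c[..., 1, 2]
    cof[..., 2, 2] = c[..., 0, 0] * c[..., 1, 1] - c[..., 0, 1] * c[..., 1, 0]
    det = (c[..., 0, 0] * cof[..., 0, 0] + c[..., 0, 1] * cof[..., 0, 1]
           + c[..., 0, 2] * cof[..., 0, 2])
    inv = np.swapaxes(cof, -1, -2) / det[..., None, None]
    return inv, det


def pk2_isochoric(C: np.ndarray, p: MaterialParams,
                  H: np.ndarray | None = None) -> np.ndarray:
    """Second Piola-Kirchhoff stress of the isochoric (distortional) energy.

    Evaluates 2 dW_bar/dC with W_bar the energy on the distortional
    invariants I1_bar = J^{-2/3} I1, I2_bar = J^{-4/3} I2,
    I4_bar = J^{-2/3} H:C.  Vectorized over leading axes.
    """
    C = np.asarray(C, dtype=float)
    Cinv, detC = _inv_det_3x3(C)
    if np.any(detC <= 0):
        raise ValueError("non-positive det(C): inverted state")
    J = np.sqrt(detC)
    J23 = J ** (-2.0 / 3.0)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    CC = np.einsum("...ij,...ji->...", C, C)
    I2 = 0.5 * (I1**2 - CC)
    I1b = J23 * I1
    I2b = J23**2 * I2
    _guard(p.D2 * (I1b - 3.0), f"{p.name} D2(I1-3)")
    W1 = p.c1 + p.D1 * p.D2 * np.exp(p.D2 * (I1b - 3.0))
    W2 = p.c2
    eye = np.broadcast_to(np.eye(3), C.shape)
    ex = lambda a: np.asarray(a)[..., None, None]
    # dI1b/dC and dI2b/dC (isochoric projections)
    dI1b = ex(J23) * (eye - ex(I1 / 3.0) * Cinv)
    dI2b = ex(J23**2) * (ex(I1) * eye - C - ex(2.0 * I2 / 3.0) * Cinv)
    S = 2.0 * (ex(W1) * dI1b + W2 * dI2b)
    if p.has_fibers:
        if H is None:
            H = structure_tensor(p)
        H = np.broadcast_to(H, C.shape)
        I4 = np.einsum("...ij,...ij->...", H, C)
        I4b = J23 * I4
        active = I4b > 1.0
        _guard(p.K2 * (np.where(active, I4b - 1.0, 0.0)) ** 2, f"{p.name} K2(I4-1)^2")
        W4 = np.where(active, 2.0 * p.K1 * (I4b - 1.0)
                      * np.exp(p.K2 * (I4b - 1.0) ** 2), 0.0)
        dI4b = ex(J23) * (H - ex(I4 / 3.0) * Cinv)
        S = S + 2.0 * ex(W4) * dI4b
    return S


def pk2_volumetric(C: np.ndarray, kappa: float) -> np.ndarray:
    """Second Piola-Kirchhoff stress of the penalty kappa (J-1)^2 / 2."""
    C = np.asarray(C, dtype=float)
    Cinv, detC = _inv_det_3x3(C)
    J = np.sqrt(detC)
    return (kappa * (J - 1.0) * J)[..., None, None] * Cinv


def cauchy_stress(state: DeformationState | np.ndarray, p: MaterialParams,
                  kappa: float | None = None,
                  frame: np.ndarray | None = None) -> np.ndarray:
    """Cauchy stress (kPa) of the nearly-incompressible material.

    sigma = (1/J) F (S_iso + S_vol) F^T with S = 2 dW/dC evaluated on the
    isochoric energy plus the volumetric penalty.  ``frame`` orients the
    fiber structure tensor (columns: circumferential, radial, axial).
    """
    F = state.F if isinstance(state, DeformationState) else np.asarray(state, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("det F must be positive (inverted element)")
    if kappa is None:
        kappa = volumetric_penalty(p)
    C = np.swapaxes(F, -1, -2) @ F
    H = structure_tensor(p, frame) if p.has_fibers else None
    S = pk2_isochoric(C, p, H) + pk2_volumetric(C, kappa)
    sig = np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / np.asarray(J)[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


# ---------------------------------------------------------------------------
# uniaxial stress-stretch curves (exact incompressibility, plane stress)

def _incompressible_energy(p: MaterialParams, lam_c: float, lam_r: float,
                           lam_z: float) -> float:
    I1 = lam_c**2 + lam_r**2 + lam_z**2
    I2 = lam_c**-2 + lam_r**-2 + lam_z**-2  # J = 1
    _guard(p.D2 * (I1 - 3.0), f"{p.name} D2(I1-3)")
    W = (p.c1 * (I1 - 3.0) + p.c2 * (I2 - 3.0)
         + p.D1 * (np.exp(p.D2 * (I1 - 3.0)) - 1.0))
    if p.has_fibers:
        W += fiber_energy(fiber_invariant(lam_c, lam_z, p.phi_deg), p)
    return float(W)


def _uniaxial_point(p: MaterialParams, lam: float, direction: str) -> float:
    """Cauchy stress at stretch ``lam`` under incompressible uniaxial tension
    with zero lateral stresses (plane-stress protocol)."""
    h = 1e-6

    def stretches(lam_load, lam_lat):
        lam_r = 1.0 / (lam_load * lam_lat)
        if direction == "circumferential":
            return lam_load, lam_r, lam_lat
        return lam_lat, lam_r, lam_load

    def dW(i, lc, lr, lz):
        lams = [lc, lr, lz]
        up, dn = list(lams), list(lams)
        up[i] += h
        dn[i] -= h
        return (_incompressible_energy(p, *up) - _incompressible_energy(p, *dn)) / (2 * h)

    def lateral_stress(lam_lat):
        lc, lr, lz = stretches(lam, lam_lat)
        q = lr * dW(1, lc, lr, lz)  # radial stress-free sets the pressure
        i = 2 if direction == "circumferential" else 0
        return [lc, lr, lz][i] * dW(i, lc, lr, lz) - q

    if abs(lam - 1.0) < 1e-12:
        return 0.0

    def safe(f, x):
        try:
            return f(x)
        except DeformationOutOfRangeError:
            return np.nan

    # Bracket the lateral stretch on a grid (the guard makes extreme
    # candidates invalid for stiff exponential materials).
    grid = np.linspace(0.5, 1.3, 33)
    vals = np.array([safe(lateral_stress, x) for x in grid])
    ok = np.isfinite(vals)
    sign_change = np.where(ok[:-1] & ok[1:] & (vals[:-1] * vals[1:] <= 0))[0]
    if len(sign_change) == 0:
        raise RuntimeError(f"{p.name}: no lateral-stretch bracket at stretch {lam}")
    k = sign_change[0]
    lam_lat = brentq(lateral_stress, grid[k], grid[k + 1], xtol=1e-12)
    lc, lr, lz = stretches(lam, lam_lat)
    q = lr * dW(1, lc, lr, lz)
    i = 0 if direction == "circumferential" else 2
    return float([lc, lr, lz][i] * dW(i, lc, lr, lz) - q)


def stress_stretch_curve(layer: str | MaterialParams, direction: str = "circumferential",
                         stretches: np.ndarray | None = None,
                         registry: MaterialRegistry | None = None) -> np.ndarray:
    """Uniaxial Cauchy stress-stretch curve for a registry material.

    Returns an (n, 2) array of (stretch, stress kPa).  Protocol: exact
    incompressibility, loading along the requested in-plane direction, both
    lateral normal stresses zero; the fiber angle enters through I4.
    """
    if direction not in ("circumferential", "axial"):
        raise ValueError("direction must be 'circumferential' or 'axial'")
    if stretches is None:
        stretches = np.linspace(1.0, 1.3, 31)
    stretches = np.asarray(stretches, dtype=float)
    if stretches.min() < 1.0 - 1e-12 or stretches.max() > 1.5 + 1e-12:
        raise ValueError("stretch grid must lie within [1.0, 1.5]")
    if isinstance(layer, MaterialParams):
        p = layer
    else:
        reg = registry or default_registry()
        if layer not in reg:
            raise KeyError(f"unknown layer {layer!r}")
        p = reg[layer]
    sig = np.array([_uniaxial_point(p, lam, direction) for lam in stretches])
    return np.column_stack([stretches, sig])
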