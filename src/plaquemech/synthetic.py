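"""Synthetic multilayer vessel cross-sections emulating segmented OCT output.

The generator produces nested, smooth, non-intersecting layer contours with
typical coronary dimensions: lumen radius 1.0-2.0 mm, intima 0.05-0.6 mm
(thickened eccentrically over a plaque sector), media 0.1-0.25 mm,
adventitia 0.15-0.35 mm.  A lipid pool with a fibrous cap (cap thickness
0.05-0.3 mm, pool arc 30-120 degrees) is embedded in the thickened intima,
and a calcification may be added with configurable probability.  Ten slices
per synthetic patient mirrors the per-plaque sampling used in image-based
cohort studies; per-patient systolic pressures are drawn from a physiologic
range.

All randomness is routed through a counter-based seed sequence so a slice is
a deterministic function of (seed, patient_index, slice_index).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from .contours import (
    Contour,
    ContourValidationError,
    VesselSliceContours,
    resample_contour,
    write_contours,
)

__all__ = ["SyntheticCohortSpec", "SyntheticPatient", "generate_synthetic_slice",
           "generate_cohort", "write_cohort", "GenerationError"]


class GenerationError(RuntimeError):
    """Random geometry remained invalid after the retry budget."""


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort-level generation parameters (lengths in mm, angles in degrees)."""

    n_patients: int = 20
    slices_per_patient: int = 10
    lumen_radius_range: tuple[float, float] = (1.0, 2.0)
    intima_thickness_range: tuple[float, float] = (0.05, 0.6)
    media_thickness_range: tuple[float, float] = (0.1, 0.25)
    adventitia_thickness_range: tuple[float, float] = (0.15, 0.35)
    eccentricity_range: tuple[float, float] = (0.4, 1.0)
    lipid_arc_range_deg: tuple[float, float] = (30.0, 120.0)
    cap_thickness_range: tuple[float, float] = (0.05, 0.3)
    lipid_probability: float = 1.0
    calcification_probability: float = 0.2
    pressure_range_mmHg: tuple[float, float] = (101.0, 175.0)
    n_points: int = 100
    seed: int = 0
    max_retries: int = 100

    def validate(self) -> "SyntheticCohortSpec":
        if self.n_patients < 1 or self.slices_per_patient < 1:
            raise ValueError("n_patients and slices_per_patient must be >= 1")
        for name in ("lumen_radius_range", "intima_thickness_range",
                     "media_thickness_range", "adventitia_thickness_range",
                     "lipid_arc_range_deg", "cap_thickness_range",
                     "pressure_range_mmHg"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (lo, hi) range, got ({lo}, {hi})")
        if not (0 <= self.lipid_probability <= 1 and 0 <= self.calcification_probability <= 1):
            raise ValueError("component probabilities must lie in [0, 1]")
        return self


@dataclass(frozen=True)
class SyntheticPatient:
    """One synthetic patient: its slices plus the loading pressure."""

    patient_id: str
    slices: tuple[VesselSliceContours, ...]
    pressure_mmHg: float


def _rng_for(spec: SyntheticCohortSpec, patient_index: int, slice_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(patient_index), int(slice_index)]))


def _smooth_periodic(rng: np.random.Generator, theta: np.ndarray,
                     amplitude: float, n_modes: int = 3) -> np.ndarray:
    """Low-order Fourier perturbation (smooth, closed, zero-mean)."""
    out = np.zeros_like(theta)
    for k in range(1, n_modes + 1):
        a, b = rng.normal(scale=amplitude / k, size=2)
        out += a * np.cos(k * theta) + b * np.sin(k * theta)
    return out


def _bump(theta: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Smooth cos^2 angular bump of unit height on |dtheta| < half_width."""
    d = np.angle(np.exp(1j * (theta - center)))
    out = np.zeros_like(theta)
    inside = np.abs(d) < half_width
    out[inside] = np.cos(0.5 * np.pi * d[inside] / half_width) ** 2
    return out


def _polar_contour(theta: np.ndarray, r: np.ndarray, label: str) -> Contour:
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Contour(pts, label)


def generate_synthetic_slice(spec: SyntheticCohortSpec, patient_index: int,
                             slice_index: int) -> VesselSliceContours:
    """Generate one valid synthetic slice, deterministically.

    The lumen is a perturbed circle; the intima carries an eccentric
    thickening bump over a random angular sector; a lipid pool (annular
    sector between the lumen and the IEM) is buried in the thickening with
    at least the configured minimum cap thickness; an optional small
    calcification sits in the thickened intima or media.
    """
    spec.validate()
    rng = _rng_for(spec, patient_index, slice_index)
    last_err: Exception | None = None
    for _ in range(spec.max_retries):
        try:
            return _attempt_slice(spec, rng, patient_index, slice_index)
        except ContourValidationError as err:
            last_err = err
    raise GenerationError(
        f"could not generate a valid slice for patient {patient_index}, "
        f"slice {slice_index} after {spec.max_retries} attempts: {last_err}")


def _attempt_slice(spec: SyntheticCohortSpec, rng: np.random.Generator,
                   patient_index: int, slice_index: int) -> VesselSliceContours:
    n = spec.n_points
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)

    r_lum = rng.uniform(*spec.lumen_radius_range)
    t_int_base = spec.intima_thickness_range[0]
    t_int_peak = rng.uniform(max(t_int_base, 0.25 * spec.intima_thickness_range[1]),
                             spec.intima_thickness_range[1])
    t_med = rng.uniform(*spec.media_thickness_range)
    t_adv = rng.uniform(*spec.adventitia_thickness_range)
    ecc = rng.uniform(*spec.eccentricity_range)
    plaque_center = rng.uniform(0.0, 2 * np.pi)
    plaque_half_width = np.deg2rad(rng.uniform(45.0, 110.0))

    # Lumen: gently perturbed circle.
    r_lumen = r_lum * (1.0 + _smooth_periodic(rng, theta, 0.02))
    # Intima thickness: uniform base + eccentric bump.
    bump = _bump(theta, plaque_center, plaque_half_width)
    t_intima = t_int_base + ecc * (t_int_peak - t_int_base) * bump
    r_iem = r_lumen + t_intima
    r_eem = r_iem + t_med * (1.0 + _smooth_periodic(rng, theta, 0.03))
    r_adv = r_eem + t_adv * (1.0 + _smooth_periodic(rng, theta, 0.03))

    lumen = _polar_contour(theta, r_lumen, "lumen")
    iem = _polar_contour(theta, r_iem, "IEM")
    eem = _polar_contour(theta, r_eem, "EEM")
    adv = _polar_contour(theta, r_adv, "ADV")

    components: list[Contour] = []
    has_lipid = (rng.uniform() < spec.lipid_probability) and ecc > 0
    if has_lipid:
        components.append(_lipid_pool(spec, rng, theta, r_lumen, t_intima,
                                      plaque_center, plaque_half_width))
    if rng.uniform() < spec.calcification_probability:
        calc = _calcification(spec, rng, theta, r_iem, t_med, plaque_center)
        if calc is not None:
            trial = [c.polygon for c in components]
            if not any(calc.polygon.intersection(p).area > 1e-12 for p in trial):
                components.append(calc)

    slc = VesselSliceContours(
        lumen=lumen, iem=iem, eem=eem, adv=adv, components=tuple(components),
        slice_id=f"P{patient_index:03d}S{slice_index:02d}",
    )
    return slc.validate()


def _lipid_pool(spec: SyntheticCohortSpec, rng: np.random.Generator,
                theta: np.ndarray, r_lumen: np.ndarray, t_intima: np.ndarray,
                center: float, plaque_half_width: float) -> Contour:
    """Annular-sector lipid pool under a fibrous cap inside the intima."""
    arc = np.deg2rad(rng.uniform(*spec.lipid_arc_range_deg))
    half = min(arc / 2, 0.8 * plaque_half_width)
    cap_min = spec.cap_thickness_range[0]
    cap = rng.uniform(*spec.cap_thickness_range)
    t_center = float(np.interp(np.mod(center, 2 * np.pi), theta, t_intima, period=2 * np.pi))
    # Effective cap depth: at least 10% above the configured minimum (margin
    # for contour waviness), at most 45% of the peak intima thickness.
    if 0.45 * t_center < 1.1 * cap_min:
        raise ContourValidationError("intima too thin for a capped lipid pool")
    cap_eff = float(np.clip(cap, 1.1 * cap_min, 0.45 * t_center))
    # Pool occupies the intima between the cap depth and 85% of the local
    # thickness; ends taper to zero so the pool closes smoothly.  The arc is
    # shrunk until the pool fits inside the intima over its whole extent.
    m = 24
    for _ in range(20):
        th = center + np.linspace(-half, half, m)
        t_loc = np.interp(np.mod(th, 2 * np.pi), theta, t_intima, period=2 * np.pi)
        if np.all(0.85 * t_loc >= cap_eff + 0.01):
            break
        half *= 0.85
        if half < np.deg2rad(5):
            raise ContourValidationError("no room for a lipid pool under the cap")
    else:
        raise ContourValidationError("no room for a lipid pool under the cap")
    r_in = np.interp(np.mod(th, 2 * np.pi), theta, r_lumen, period=2 * np.pi)
    taper = np.sin(np.linspace(0, np.pi, m)) ** 0.5
    inner = r_in + cap_eff
    outer = inner + np.maximum((0.85 * t_loc - cap_eff) * taper, 1e-3)
    th_all = np.concatenate([th, th[::-1]])
    r_all = np.concatenate([inner, outer[::-1]])
    pts = np.column_stack([r_all * np.cos(th_all), r_all * np.sin(th_all)])
    c = Contour(pts, "lipid")
    if Polygon(pts).area < 1e-3:
        raise ContourValidationError("lipid pool degenerate")
    from .contours import _signed_area
    if _signed_area(pts) < 0:
        c = Contour(pts[::-1], "lipid")
    return resample_contour(c, 48)


def _calcification(spec: SyntheticCohortSpec, rng: np.random.Generator,
                   theta: np.ndarray, r_iem: np.ndarray, t_med: float,
                   plaque_center: float) -> Contour | None:
    """Small ellipse of calcification just outside the IEM (deep intima /
    media border), away from the lipid pool."""
    ang = plaque_center + np.pi + rng.uniform(-0.8, 0.8)
    r_here = np.interp(np.mod(ang, 2 * np.pi), theta, r_iem, period=2 * np.pi)
    a = rng.uniform(0.08, 0.2)          # tangential semi-axis (mm)
    b = min(rng.uniform(0.03, 0.08), 0.35 * t_med)
    r_c = r_here + 0.5 * t_med
    t = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    local = np.column_stack([a * np.cos(t), b * np.sin(t)])
    rot = np.array([[np.cos(ang + np.pi / 2), -np.sin(ang + np.pi / 2)],
                    [np.sin(ang + np.pi / 2), np.cos(ang + np.pi / 2)]])
    pts = (local @ rot.T) + r_c * np.array([np.cos(ang), np.sin(ang)])
    return Contour(pts, "calcification")


def generate_cohort(spec: SyntheticCohortSpec,
                    pressures_mmHg: list[float] | None = None) -> list[SyntheticPatient]:
    """Generate the full synthetic cohort.

    Per-patient systolic pressure is drawn from ``spec.pressure_range_mmHg``
    unless an explicit list (e.g. a clinical pressure table) is supplied.
    """
    spec.validate()
    patients = []
    for p in range(spec.n_patients):
        rng = _rng_for(spec, p, 10_000)  # pressure stream, disjoint from slices
        if pressures_mmHg is not None:
            pressure = float(pressures_mmHg[p % len(pressures_mmHg)])
        else:
            pressure = float(np.round(rng.uniform(*spec.pressure_range_mmHg), 1))
        slices = tuple(generate_synthetic_slice(spec, p, s)
                       for s in range(spec.slices_per_patient))
        patients.append(SyntheticPatient(f"P{p:03d}", slices, pressure))
    return patients


def cohort_manifest(patients: list[SyntheticPatient]) -> dict:
    """JSON-serializable manifest (patients, slices, pressures, digest)."""
    entries = []
    h = hashlib.sha256()
    for pat in patients:
        for slc in pat.slices:
            for c in (slc.lumen, slc.iem, slc.eem, slc.adv, *slc.components):
                h.update(np.ascontiguousarray(np.round(c.points, 12)).tobytes())
            entries.append({"patient": pat.patient_id, "slice": slc.slice_id,
                            "pressure_mmHg": pat.pressure_mmHg,
                            "n_components": len(slc.components)})
    return {"n_patients": len(patients),
            "n_slices": sum(len(p.slices) for p in patients),
            "geometry_sha256": h.hexdigest(),
            "slices": entries}


def write_cohort(patients: list[SyntheticPatient], out_dir: str | Path) -> Path:
    """Write per-slice contour JSON files plus a cohort manifest; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pat in patients:
        for slc in pat.slices:
            write_contours(slc, out / f"{slc.slice_id}.json")
    manifest = cohort_manifest(patients)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
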