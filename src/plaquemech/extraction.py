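"""From solved fields to per-patient scalar summaries.

The lumen (inner wall) and out-wall contours of each slice are split into
four angular quarters about the lumen centroid and each quarter is sampled
at 25 equal arc-length steps (the piecewise equal-step scheme), giving 100
paired inner/outer nodes per slice.  Pairing by (quarter, within-quarter
index) rather than by global angle avoids distortion where an eccentric
plaque makes the wall much thicker on one side.  Cap nodes are the lumen
nodes whose pairing segment crosses a lipid pool.

With 10 slices per patient this yields 1000 nodal values per region, from
which the per-patient maximum and mean, the multilayer-vs-single-layer
relative difference (single-layer as base), and cohort averages (mean and
sample SD over patients) are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

from .contours import Contour, VesselSliceContours, arc_lengths
from .fem import SolutionField

__all__ = [
    "RegionNodeSets", "quarter_divide", "identify_cap_nodes",
    "patient_max", "patient_mean", "relative_difference", "cohort_average",
    "extract_slice_values", "summarize_patient",
]


@dataclass(frozen=True)
class RegionNodeSets:
    """Paired extraction nodes of one slice (coordinates in mm)."""

    lumen_points: np.ndarray     # (n, 2)
    outwall_points: np.ndarray   # (n, 2)
    quarter: np.ndarray          # (n,) in {0, 1, 2, 3}
    centroid: np.ndarray
    cap_mask: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return len(self.lumen_points)

    @property
    def lumen_angles(self) -> np.ndarray:
        rel = self.lumen_points - self.centroid
        return np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)

    @property
    def outwall_angles(self) -> np.ndarray:
        rel = self.outwall_points - self.centroid
        return np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)


def _quarter_samples(c: Contour, centroid: np.ndarray, n_per_quarter: int,
                     anchor_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample n_per_quarter equal-arc points in each angular quarter.

    Returns (points (4*n, 2), quarter index (4*n,)).  Quarter boundaries are
    at anchor, anchor+90, ... degrees from the +x axis about the centroid.
    """
    pts = c.points
    rel = pts - centroid
    theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    dth = np.diff(np.concatenate([theta, [theta[0] + 2 * np.pi]]))
    if np.any(dth < -1e-9) or abs((theta[-1] - theta[0]) + dth[-1] - 2 * np.pi) > 1e-6:
        raise ValueError(f"{c.label}: contour not star-shaped about the lumen centroid")
    s = arc_lengths(pts)                       # cumulative, len n+1
    # theta(s) over two periods so quarter boundaries past the wrap resolve
    theta_ext = np.concatenate([theta, [theta[0] + 2 * np.pi]])
    theta2 = np.concatenate([theta_ext, theta_ext[1:] + 2 * np.pi])
    s2 = np.concatenate([s, s[1:] + s[-1]])
    anchor = np.deg2rad(anchor_deg)
    # shift so the anchor is at theta_ext[0] <= anchor < theta_ext[0] + 2pi
    a0 = theta_ext[0] + np.mod(anchor - theta_ext[0], 2 * np.pi)
    bounds = a0 + np.arange(5) * (np.pi / 2)
    s_bounds = np.interp(bounds, theta2, s2)
    out_pts, out_q = [], []
    per = s[-1]
    pts_ext = np.vstack([pts, pts[:1]])
    for q in range(4):
        s0, s1 = s_bounds[q], s_bounds[q + 1]
        # 25 equal arc steps (mid-step sampling avoids duplicated boundaries)
        si = s0 + (np.arange(n_per_quarter) + 0.5) / n_per_quarter * (s1 - s0)
        si = np.mod(si, per)
        x = np.interp(si, s, pts_ext[:, 0])
        y = np.interp(si, s, pts_ext[:, 1])
        out_pts.append(np.column_stack([x, y]))
        out_q.append(np.full(n_per_quarter, q))
    return np.vstack(out_pts), np.concatenate(out_q)


def quarter_divide(lumen: Contour, outwall: Contour,
                   n_per_quarter: int = 25, anchor_deg: float = 0.0,
                   centroid: np.ndarray | None = None) -> RegionNodeSets:
    """Quarter-dividing pairing of lumen and out-wall contours.

    Both contours are split into four quarters by angle about the lumen
    centroid (boundaries at ``anchor_deg`` + 0/90/180/270 from +x) and
    sampled at ``n_per_quarter`` equal arc-length steps per quarter; nodes
    are paired by (quarter, within-quarter index).
    """
    if centroid is None:
        centroid = lumen.centroid
    lp, lq = _quarter_samples(lumen, centroid, n_per_quarter, anchor_deg)
    op, oq = _quarter_samples(outwall, centroid, n_per_quarter, anchor_deg)
    assert np.array_equal(lq, oq)
    return RegionNodeSets(lumen_points=lp, outwall_points=op, quarter=lq,
                          centroid=np.asarray(centroid, dtype=float))


def identify_cap_nodes(sets: RegionNodeSets, slc: VesselSliceContours) -> np.ndarray:
    """Boolean mask over lumen nodes whose pairing segment crosses a lipid
    pool (calcifications do not define a cap)."""
    lipids = [Polygon(c.points) for c in slc.components if c.label == "lipid"]
    mask = np.zeros(sets.n, dtype=bool)
    if not lipids:
        return mask
    for i in range(sets.n):
        seg = LineString([sets.lumen_points[i], sets.outwall_points[i]])
        if any(seg.intersects(p) for p in lipids):
            mask[i] = True
    return mask


# ---------------------------------------------------------------------------
# scalar summaries

def patient_max(values: np.ndarray) -> float:
    """Patient maximum over all nodal values (typically 10 slices x 100)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("patient_max of an empty node set")
    return float(values.max())


def patient_mean(values: np.ndarray) -> float:
    """Patient mean over all nodal values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("patient_mean of an empty node set")
    return float(values.mean())


def relative_difference(multi: float, single: float) -> float:
    """100 x (multi - single) / single, single-layer as base (percent)."""
    if single == 0:
        raise ZeroDivisionError("relative difference undefined for zero base")
    return 100.0 * (multi - single) / single


def cohort_average(per_patient: np.ndarray) -> tuple[float, float]:
    """(mean, sample SD) over patients; SD uses the n-1 denominator."""
    v = np.asarray(per_patient, dtype=float)
    if v.size < 2:
        raise ValueError("cohort SD undefined for fewer than 2 patients")
    return float(v.mean()), float(v.std(ddof=1))


# ---------------------------------------------------------------------------
# field sampling

def _ring_interp(angles_ring: np.ndarray, values_ring: np.ndarray,
                 query_angles: np.ndarray) -> np.ndarray:
    """Periodic linear interpolation of ring nodal values by angle."""
    order = np.argsort(angles_ring)
    a = angles_ring[order]
    v = values_ring[order]
    a_ext = np.concatenate([a, [a[0] + 2 * np.pi]])
    v_ext = np.concatenate([v, [v[0]]])
    q = np.mod(query_angles - a[0], 2 * np.pi) + a[0]
    return np.interp(q, a_ext, v_ext)


def extract_slice_values(sol: SolutionField, sets: RegionNodeSets,
                         cap_mask: np.ndarray) -> dict[str, np.ndarray]:
    """Sample the solved max-principal stress/strain fields at the
    extraction nodes of one slice.

    The solver's inner and outer node rings are interpolated by angle at the
    quarter-divided extraction angles (stress in kPa, strain dimensionless).
    """
    mesh = sol.mesh
    ring_ang = mesh.ray_angles
    out = {}
    for which, ids, q_ang in (
        ("plaque", mesh.inner_ring, sets.lumen_angles),
        ("outwall", mesh.outer_ring, sets.outwall_angles),
    ):
        out[f"{which}_stress"] = _ring_interp(ring_ang, sol.sigma_max[ids], q_ang)
        out[f"{which}_strain"] = _ring_interp(ring_ang, sol.eps_max[ids], q_ang)
    out["cap_stress"] = out["plaque_stress"][cap_mask]
    out["cap_strain"] = out["plaque_strain"][cap_mask]
    return out


def summarize_patient(slice_values: list[dict[str, np.ndarray]]) -> dict[str, float]:
    """Per-patient max and mean per region from per-slice nodal values."""
    out: dict[str, float] = {}
    for key in ("plaque_stress", "plaque_strain", "cap_stress", "cap_strain",
                "outwall_stress", "outwall_strain"):
        pooled = np.concatenate([sv[key] for sv in slice_values]) if slice_values else np.array([])
        if pooled.size == 0:
            out[f"max_{key}"] = np.nan
            out[f"mean_{key}"] = np.nan
        else:
            out[f"max_{key}"] = patient_max(pooled)
            out[f"mean_{key}"] = patient_mean(pooled)
    return out
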