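"""Structured hexahedral meshing of the 0.5 mm thin-slice vessel model.

Rays from the lumen centroid through each contour partition the wall into
quadrilateral columns (lumen->IEM->EEM->ADV for the multilayer treatment,
lumen->ADV for the single-layer one); columns are subdivided radially and
extruded through the slab thickness into trilinear hexahedra.  Elements
whose centroid falls inside a lipid or calcification contour are relabeled
to that component.  Each element carries a local material frame
(circumferential, radial, axial) that orients the fiber reinforcement.

This ray-based scheme requires contours to be star-shaped about the lumen
centroid, which segmented coronary cross-sections are in practice; a ray
that does not cross a contour exactly once raises a meshing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point
from shapely.prepared import prep

from .contours import VesselSliceContours

__all__ = ["ThinSliceMesh", "MeshingError", "build_mesh"]

WALL_REGIONS_MULTI = ("intima", "media", "adventitia")


class MeshingError(RuntimeError):
    """Ray casting or element quality failure during mesh construction."""


@dataclass
class ThinSliceMesh:
    """Hexahedral mesh of one extruded cross-section.

    nodes are (N, 3) reference coordinates in mm; elements are (E, 8) node
    indices in the canonical trilinear ordering; ``region`` holds one label
    per element; ``frames`` holds per-element material frames with columns
    (circumferential, radial, axial).
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    frames: np.ndarray
    lumen_faces: np.ndarray      # (F, 4) node ids, inner surface quads
    outer_faces: np.ndarray      # (F, 4) node ids, outer surface quads
    zminus_nodes: np.ndarray
    zplus_nodes: np.ndarray
    n_rays: int
    n_radial: int
    n_slabs: int
    thickness: float
    layer_mode: str
    centroid: np.ndarray
    ray_angles: np.ndarray
    inner_ring: np.ndarray       # (n_rays,) node ids on lumen, z=0 face
    outer_ring: np.ndarray       # (n_rays,) node ids on ADV, z=0 face

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        """Exact trilinear element volumes via 2x2x2 quadrature."""
        from .fem import _shape_gradients_ref
        _, wdet = _shape_gradients_ref(self.nodes[self.elements])
        return wdet.sum(axis=1)

    def scaled_inplane(self, factor: float) -> "ThinSliceMesh":
        """Uniform in-plane scaling of node coordinates about the centroid
        (used by the circumferential pre-shrink)."""
        nodes = self.nodes.copy()
        nodes[:, :2] = self.centroid + factor * (nodes[:, :2] - self.centroid)
        out = ThinSliceMesh(**{**self.__dict__})
        out.nodes = nodes
        return out

    def scaled_axial(self, factor: float) -> "ThinSliceMesh":
        """Scale the slab axially (the axial pre-shrink)."""
        nodes = self.nodes.copy()
        nodes[:, 2] *= factor
        out = ThinSliceMesh(**{**self.__dict__})
        out.nodes = nodes
        out.thickness = self.thickness * factor
        return out


def _ray_radius(origin: np.ndarray, angle: float, pts: np.ndarray) -> float:
    """Distance from origin to the unique crossing of the ray at ``angle``
    with the closed polyline ``pts``."""
    d = np.array([np.cos(angle), np.sin(angle)])
    a = pts - origin
    b = np.roll(pts, -1, axis=0) - origin
    e = b - a
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (a[:, 0] * d[1] - a[:, 1] * d[0]) / denom
        t = (a[:, 0] * e[:, 1] - a[:, 1] * e[:, 0]) / denom
    # small slack on the segment parameter so a ray through a shared vertex
    # is seen by at least one adjacent segment; duplicates dedupe by radius
    hit = np.isfinite(u) & (u >= -1e-9) & (u < 1.0 + 1e-9) & (t > 1e-12)
    ts = np.unique(np.round(t[hit], 9))
    if len(ts) != 1:
        raise MeshingError(
            f"ray at {np.rad2deg(angle):.1f} deg crosses contour {len(ts)} times "
            "(slice not star-shaped about the lumen centroid)")
    return float(ts[0])


def build_mesh(slc: VesselSliceContours, thickness: float = 0.5,
               n_rays: int = 48, n_radial_per_layer: int = 3,
               n_slabs: int = 1, layer_mode: str | None = None) -> ThinSliceMesh:
    """Mesh one cross-section into the extruded thin-slice model.

    ``layer_mode`` defaults to 'single' when the slice was produced by
    :func:`plaquemech.contours.merge_to_single_layer`, else 'multi'.
    """
    if n_rays < 32:
        raise ValueError("n_rays must be >= 32")
    slc.validate()
    if layer_mode is None:
        layer_mode = "single" if slc.single_layer else "multi"
    if layer_mode not in ("multi", "single"):
        raise ValueError(f"bad layer_mode {layer_mode!r}")

    origin = slc.lumen.centroid
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    bounds = [slc.lumen, slc.iem, slc.eem, slc.adv]
    radii = np.empty((n_rays, 4))
    for i, ang in enumerate(angles):
        for j, c in enumerate(bounds):
            radii[i, j] = _ray_radius(origin, ang, c.points)
    if np.any(np.diff(radii, axis=1) <= 0):
        raise MeshingError("layer boundaries out of order along a ray")

    nrl = n_radial_per_layer
    if layer_mode == "multi":
        # radial stations: lumen -> IEM -> EEM -> ADV, nrl intervals each
        fracs = np.linspace(0.0, 1.0, nrl + 1)
        stations = []
        for i in range(n_rays):
            r = [radii[i, 0] + fracs[1:] * (radii[i, 1] - radii[i, 0]),
                 radii[i, 1] + fracs[1:] * (radii[i, 2] - radii[i, 1]),
                 radii[i, 2] + fracs[1:] * (radii[i, 3] - radii[i, 2])]
            stations.append(np.concatenate([[radii[i, 0]], *r]))
        band_regions = ([("intima")] * nrl + ["media"] * nrl + ["adventitia"] * nrl)
    else:
        fracs = np.linspace(0.0, 1.0, 3 * nrl + 1)
        stations = [radii[i, 0] + fracs * (radii[i, 3] - radii[i, 0])
                    for i in range(n_rays)]
        band_regions = ["wall"] * (3 * nrl)
    stations = np.asarray(stations)          # (n_rays, n_rad_nodes)
    n_rad_nodes = stations.shape[1]
    n_bands = n_rad_nodes - 1
    n_z = n_slabs + 1

    zs = np.linspace(0.0, thickness, n_z)
    # node id layout: ((ray * n_rad_nodes) + radial) * n_z + z
    nid = (np.arange(n_rays)[:, None, None] * n_rad_nodes
           + np.arange(n_rad_nodes)[None, :, None]) * n_z + np.arange(n_z)[None, None, :]
    xy_dir = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    nodes = np.empty((n_rays * n_rad_nodes * n_z, 3))
    for i in range(n_rays):
        for j in range(n_rad_nodes):
            p = origin + stations[i, j] * xy_dir[i]
            nodes[nid[i, j, :], 0] = p[0]
            nodes[nid[i, j, :], 1] = p[1]
            nodes[nid[i, j, :], 2] = zs

    elements, region, frames = [], [], []
    lumen_faces, outer_faces = [], []
    for i in range(n_rays):
        i2 = (i + 1) % n_rays
        for j in range(n_bands):
            for m in range(n_slabs):
                # canonical ordering: xi -> radial, eta -> circumferential,
                # zeta -> axial; bottom face CCW viewed from +z
                el = [nid[i, j, m], nid[i, j + 1, m], nid[i2, j + 1, m], nid[i2, j, m],
                      nid[i, j, m + 1], nid[i, j + 1, m + 1],
                      nid[i2, j + 1, m + 1], nid[i2, j, m + 1]]
                elements.append(el)
                region.append(band_regions[j])
                if j == 0:
                    lumen_faces.append([nid[i, 0, m], nid[i2, 0, m],
                                        nid[i2, 0, m + 1], nid[i, 0, m + 1]])
                if j == n_bands - 1:
                    outer_faces.append([nid[i, n_bands, m], nid[i2, n_bands, m],
                                        nid[i2, n_bands, m + 1], nid[i, n_bands, m + 1]])
    elements = np.asarray(elements, dtype=np.int64)
    region = np.asarray(region, dtype=object)

    # component relabeling by centroid containment
    cent_xy = nodes[elements][:, :, :2].mean(axis=1)
    for comp in slc.components:
        inside = _contains(comp.points, cent_xy)
        region[inside] = comp.label

    # local material frames from element centroids
    rel = cent_xy - origin
    th = np.arctan2(rel[:, 1], rel[:, 0])
    e_r = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], axis=1)
    e_c = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)], axis=1)
    e_z = np.broadcast_to([0.0, 0.0, 1.0], e_r.shape)
    frames = np.stack([e_c, e_r, e_z], axis=2)   # columns: circ, rad, ax

    zmask = np.isclose(nodes[:, 2], 0.0)
    zpmask = np.isclose(nodes[:, 2], thickness)
    mesh = ThinSliceMesh(
        nodes=nodes, elements=elements, region=region, frames=frames,
        lumen_faces=np.asarray(lumen_faces, dtype=np.int64),
        outer_faces=np.asarray(outer_faces, dtype=np.int64),
        zminus_nodes=np.where(zmask)[0], zplus_nodes=np.where(zpmask)[0],
        n_rays=n_rays, n_radial=n_bands, n_slabs=n_slabs, thickness=thickness,
        layer_mode=layer_mode, centroid=origin, ray_angles=angles,
        inner_ring=nid[:, 0, 0].copy(), outer_ring=nid[:, -1, 0].copy(),
    )
    vols = mesh.element_volumes()
    if np.any(vols <= 0):
        raise MeshingError(f"{int(np.sum(vols <= 0))} non-positive element Jacobians")
    return mesh


def _contains(polygon_pts: np.ndarray, query_xy: np.ndarray) -> np.ndarray:
    from shapely.geometry import Polygon
    poly = prep(Polygon(polygon_pts))
    return np.fromiter((poly.contains(Point(p)) for p in query_xy),
                       dtype=bool, count=len(query_xy))
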