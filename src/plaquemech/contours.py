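"""Segmented vessel cross-section geometry: contours, validation, and I/O.

A cross-section is described by four closed boundary contours — lumen,
internal elastic membrane (IEM, intima/media boundary), external elastic
membrane (EEM, media/adventitia boundary) and the adventitia-periadventitia
interface (ADV) — plus optional plaque component contours (lipid pools,
calcifications) lying inside the wall.  Coordinates are 2D Cartesian in mm;
the slice plane is x-y and all contours are stored counter-clockwise with
implicit closure (the first point is not repeated).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, Point

BOUNDARY_LABELS = ("lumen", "IEM", "EEM", "ADV")
COMPONENT_LABELS = ("lipid", "calcification")
VALID_LABELS = BOUNDARY_LABELS + COMPONENT_LABELS


class ContourValidationError(ValueError):
    """A contour or slice violates a geometric invariant."""


class ContourParseError(ValueError):
    """A contour file does not match the documented schema."""


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Closed 2D polyline (mm), counter-clockwise, first point not repeated."""

    points: np.ndarray
    label: str

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourValidationError(f"{self.label}: points must be (n, 2)")
        object.__setattr__(self, "points", pts)

    def validate(self) -> "Contour":
        if self.label not in VALID_LABELS:
            raise ContourValidationError(f"unknown contour label {self.label!r}")
        pts = self.points
        if len(pts) < 8:
            raise ContourValidationError(f"{self.label}: needs >= 8 points, got {len(pts)}")
        if np.allclose(pts[0], pts[-1]):
            raise ContourValidationError(f"{self.label}: first point duplicated at end")
        poly = Polygon(pts)
        if not poly.is_valid or poly.area <= 0:
            raise ContourValidationError(f"{self.label}: polygon is self-intersecting or degenerate")
        if _signed_area(pts) < 0:
            raise ContourValidationError(f"{self.label}: orientation must be counter-clockwise")
        return self

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def area(self) -> float:
        return abs(_signed_area(self.points))

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.polygon.centroid.coords[0])

    def scaled(self, factor: float, about: np.ndarray) -> "Contour":
        about = np.asarray(about, dtype=float)
        return replace(self, points=about + factor * (self.points - about))


@dataclass(frozen=True)
class VesselSliceContours:
    """One segmented cross-section: nested wall boundaries plus components."""

    lumen: Contour
    iem: Contour
    eem: Contour
    adv: Contour
    components: tuple[Contour, ...] = ()
    slice_id: str = "slice"
    frame_spacing_mm: float = 0.5
    single_layer: bool = False

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def boundaries(self) -> dict[str, Contour]:
        return {"lumen": self.lumen, "IEM": self.iem, "EEM": self.eem, "ADV": self.adv}

    def validate(self) -> "VesselSliceContours":
        for name, c in self.boundaries.items():
            c.validate()
            if c.label != name:
                raise ContourValidationError(f"boundary {name} carries label {c.label!r}")
        chain = [self.lumen, self.iem, self.eem, self.adv]
        for inner, outer in zip(chain[:-1], chain[1:]):
            _require_nested(inner, outer)
        lumen_poly = self.lumen.polygon
        adv_poly = self.adv.polygon
        for comp in self.components:
            comp.validate()
            if comp.label not in COMPONENT_LABELS:
                raise ContourValidationError(f"component label {comp.label!r} not in {COMPONENT_LABELS}")
            cp = comp.polygon
            if not adv_poly.contains(cp):
                raise ContourValidationError(f"nesting: component {comp.label} extends outside ADV")
            if cp.intersects(lumen_poly) and cp.intersection(lumen_poly).area > 1e-12:
                raise ContourValidationError(f"nesting: component {comp.label} overlaps the lumen")
        for i, a in enumerate(self.components):
            for b in self.components[i + 1:]:
                inter = a.polygon.intersection(b.polygon)
                if inter.area > 1e-12:
                    raise ContourValidationError(
                        f"components {a.label} and {b.label} overlap (area {inter.area:.2e})")
        return self

    @property
    def layer_areas(self) -> dict[str, float]:
        """Annular area (mm^2) of each wall layer (ignores components)."""
        a_l, a_i, a_e, a_a = (c.area for c in (self.lumen, self.iem, self.eem, self.adv))
        return {"intima": a_i - a_l, "media": a_e - a_i, "adventitia": a_a - a_e}

    @property
    def wall_area(self) -> float:
        """Total wall annulus area lumen -> ADV (mm^2)."""
        return self.adv.area - self.lumen.area

    def scaled(self, factor: float, about: np.ndarray | None = None) -> "VesselSliceContours":
        """Uniform in-plane scaling of every contour about a common point
        (default: lumen centroid)."""
        if about is None:
            about = self.lumen.centroid
        return replace(
            self,
            lumen=self.lumen.scaled(factor, about),
            iem=self.iem.scaled(factor, about),
            eem=self.eem.scaled(factor, about),
            adv=self.adv.scaled(factor, about),
            components=tuple(c.scaled(factor, about) for c in self.components),
        )


def _require_nested(inner: Contour, outer: Contour) -> None:
    """Strict nesting: every vertex of ``inner`` lies inside ``outer``."""
    outer_poly = outer.polygon
    for p in inner.points:
        if not outer_poly.contains(Point(p)):
            raise ContourValidationError(
                f"nesting: contour {inner.label} is not strictly inside {outer.label}")


def point_in_polygon_winding(point: np.ndarray, polygon: np.ndarray) -> bool:
    """Brute-force winding-number point-in-polygon test (oracle for the
    shapely-based nesting check)."""
    p = np.asarray(point, dtype=float)
    v = np.asarray(polygon, dtype=float) - p
    v2 = np.roll(v, -1, axis=0)
    ang = np.arctan2(
        v[:, 0] * v2[:, 1] - v[:, 1] * v2[:, 0],
        v[:, 0] * v2[:, 0] + v[:, 1] * v2[:, 1],
    )
    return abs(np.sum(ang)) > np.pi  # winding number != 0


# ---------------------------------------------------------------------------
# resampling

def arc_lengths(points: np.ndarray, closed: bool = True) -> np.ndarray:
    """Cumulative arc length at each vertex; final entry is the perimeter."""
    pts = np.vstack([points, points[:1]]) if closed else points
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_contour(c: Contour, n: int) -> Contour:
    """Resample a closed contour to ``n`` points at equal arc-length steps,
    starting from the original first vertex."""
    if n < 8:
        raise ValueError(f"resample target n={n} must be >= 8")
    s = arc_lengths(c.points)
    total = s[-1]
    if total <= 0:
        raise ContourValidationError(f"{c.label}: zero-length contour")
    targets = np.linspace(0.0, total, n, endpoint=False)
    pts = np.vstack([c.points, c.points[:1]])
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return replace(c, points=np.column_stack([x, y]))


def merge_to_single_layer(slc: VesselSliceContours, keep_membranes: bool = False) -> VesselSliceContours:
    """Collapse the three wall layers into one wall spanning lumen -> ADV.

    The returned slice keeps the same lumen and ADV contours; IEM and EEM are
    either dropped (replaced by copies of lumen/ADV interpolants is not
    needed — the single-layer mesh subdivides lumen->ADV uniformly) or kept
    as passive markers when ``keep_membranes`` is true.  Plaque components
    are preserved unchanged.
    """
    slc.validate()
    # Membranes are retained as passive markers (the type requires four
    # boundaries); the single_layer flag tells the mesh builder to subdivide
    # lumen->ADV as one region.  ``keep_membranes`` is accepted for schema
    # symmetry; geometry is identical either way.
    del keep_membranes
    return replace(slc, slice_id=slc.slice_id + "-single", single_layer=True)


# ---------------------------------------------------------------------------
# file I/O

def write_contours(slc: VesselSliceContours, path: str | Path) -> None:
    """Serialize a validated slice to the documented JSON schema."""
    slc.validate()
    doc = {
        "slice_id": slc.slice_id,
        "units": "mm",
        "frame_spacing_mm": slc.frame_spacing_mm,
        "contours": [
            {"label": c.label, "points": np.round(c.points, 12).tolist()}
            for c in (slc.lumen, slc.iem, slc.eem, slc.adv, *slc.components)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_contours(path: str | Path) -> VesselSliceContours:
    """Read and validate a slice from the JSON schema (or CSV, by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_contours_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ContourParseError(f"{path}: not valid JSON ({e})") from e
    for key in ("slice_id", "contours"):
        if key not in doc:
            raise ContourParseError(f"{path}: missing field {key!r}")
    if doc.get("units", "mm") != "mm":
        raise ContourParseError(f"{path}: unsupported units {doc['units']!r}")
    by_label: dict[str, Contour] = {}
    components: list[Contour] = []
    for entry in doc["contours"]:
        if "label" not in entry or "points" not in entry:
            raise ContourParseError(f"{path}: contour entry missing 'label' or 'points'")
        label = entry["label"]
        if label not in VALID_LABELS:
            raise ContourParseError(f"{path}: unknown contour label {label!r}")
        c = Contour(np.asarray(entry["points"], dtype=float), label)
        if label in BOUNDARY_LABELS:
            if label in by_label:
                raise ContourParseError(f"{path}: duplicate boundary contour {label!r}")
            by_label[label] = c
        else:
            components.append(c)
    missing = [lbl for lbl in BOUNDARY_LABELS if lbl not in by_label]
    if missing:
        raise ContourParseError(f"{path}: missing boundary contours {missing}")
    slc = VesselSliceContours(
        lumen=by_label["lumen"], iem=by_label["IEM"], eem=by_label["EEM"],
        adv=by_label["ADV"], components=tuple(components),
        slice_id=str(doc["slice_id"]),
        frame_spacing_mm=float(doc.get("frame_spacing_mm", 0.5)),
    )
    return slc.validate()


def _read_contours_csv(path: Path) -> VesselSliceContours:
    """CSV import: one row per point, columns slice_id,label,idx,x,y."""
    rows = list(csv.DictReader(path.open()))
    if not rows:
        raise ContourParseError(f"{path}: empty CSV")
    need = {"slice_id", "label", "idx", "x", "y"}
    if not need.issubset(rows[0].keys()):
        raise ContourParseError(f"{path}: CSV must have columns {sorted(need)}")
    slice_id = rows[0]["slice_id"]
    groups: dict[str, list[tuple[int, float, float]]] = {}
    order: list[str] = []
    for r in rows:
        key = r["label"]
        if key not in groups:
            groups[key] = []
            order.append(key)
        try:
            groups[key].append((int(r["idx"]), float(r["x"]), float(r["y"])))
        except ValueError as e:
            raise ContourParseError(f"{path}: bad numeric field in row {r} ({e})") from e
    by_label: dict[str, Contour] = {}
    components: list[Contour] = []
    for label in order:
        pts = np.array([(x, y) for _, x, y in sorted(groups[label])])
        c = Contour(pts, label)
        if label in BOUNDARY_LABELS:
            by_label[label] = c
        elif label in COMPONENT_LABELS:
            components.append(c)
        else:
            raise ContourParseError(f"{path}: unknown contour label {label!r}")
    missing = [lbl for lbl in BOUNDARY_LABELS if lbl not in by_label]
    if missing:
        raise ContourParseError(f"{path}: missing boundary contours {missing}")
    slc = VesselSliceContours(
        lumen=by_label["lumen"], iem=by_label["IEM"], eem=by_label["EEM"],
        adv=by_label["ADV"], components=tuple(components), slice_id=slice_id,
    )
    return slc.validate()
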