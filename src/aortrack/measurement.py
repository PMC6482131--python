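"""Landmark planes, cross-sections and maximal diameters.

Seven standardized thoracic-aorta landmarks (sinotubular junction STJ, mid
ascending aorta MAA, proximal arch PROX, mid arch MID_ARCH, proximal
descending DIST, mid descending DESC, and DIAPHRAGM) are annotated as world
points on the baseline scan, projected onto the baseline centerline, and
turned into measurement planes normal to the local centerline tangent.
Each plane is intersected with the subdivided lumen surface of both time
points; the maximal cross-sectional diameter is the diameter of the
intersection polygon (maximum pairwise vertex distance, via convex hull),
and the dilatation is the follow-up minus baseline difference. The same
baseline-defined planes are reused verbatim on the aligned follow-up
surface, so the two measurements are always co-planar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centerline import Centerline
from .errors import (
    AnnotationError,
    BoundaryIntersectionError,
    GeometryError,
    OutOfRangeError,
    SchemaError,
)
from .phantom import LANDMARK_NAMES
from .surface import SurfaceMesh, subdivision_operator

MAX_ANNOTATION_DISTANCE_MM = 30.0


# -- landmark set ------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Seven named measurement planes, ordered by baseline arc length.

    ``entries`` maps name -> dict with keys ``point`` (plane anchor on the
    centerline), ``annotation`` (the original click), ``normal`` (unit plane
    normal = centerline tangent) and ``arc_length`` (mm on the baseline
    centerline).
    """

    entries: dict

    def __post_init__(self):
        names = list(self.entries)
        unknown = set(names) - set(LANDMARK_NAMES)
        if unknown:
            raise SchemaError(f"unknown landmark names: {sorted(unknown)}")
        if len(set(names)) != len(names):
            raise SchemaError("duplicate landmark names")
        # normalize ordering to the anatomical vocabulary order
        self.entries = {
            n: self.entries[n] for n in LANDMARK_NAMES if n in self.entries
        }
        arcs = [self.entries[n]["arc_length"] for n in self.entries]
        if len(arcs) >= 2 and np.any(np.diff(arcs) <= 0):
            raise SchemaError(
                "landmark arc lengths are not increasing in anatomical order "
                f"STJ->DIAPHRAGM: {dict(zip(self.entries, arcs))}"
            )

    def __iter__(self):
        return iter(self.entries.items())

    def __len__(self):
        return len(self.entries)

    def arc_length(self, name: str) -> float:
        return float(self.entries[name]["arc_length"])

    def to_dict(self) -> dict:
        return {
            n: {
                "point": np.asarray(e["point"]).tolist(),
                "annotation": np.asarray(e["annotation"]).tolist(),
                "normal": np.asarray(e["normal"]).tolist(),
                "arc_length": float(e["arc_length"]),
            }
            for n, e in self.entries.items()
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_landmarks(annotations: dict, centerline: Centerline) -> LandmarkSet:
    """Project the seven annotated points onto the centerline.

    Each annotation must be within 30 mm of the centerline; the plane anchor
    is the nearest centerline sample and the plane normal is the tangent
    there. Input order is irrelevant: entries are normalized to anatomical
    order and the ordering along the centerline is enforced.
    """
    missing = set(LANDMARK_NAMES) - set(annotations)
    if missing:
        raise SchemaError(f"missing landmark annotations: {sorted(missing)}")
    unknown = set(annotations) - set(LANDMARK_NAMES)
    if unknown:
        raise SchemaError(f"unknown landmark names: {sorted(unknown)}")
    entries = {}
    for name in LANDMARK_NAMES:
        p = np.asarray(annotations[name], dtype=float).reshape(3)
        d = np.linalg.norm(centerline.points - p, axis=1)
        i = int(np.argmin(d))
        if d[i] > MAX_ANNOTATION_DISTANCE_MM:
            raise AnnotationError(
                f"landmark {name!r} is {d[i]:.1f} mm from the centerline "
                f"(limit {MAX_ANNOTATION_DISTANCE_MM:.0f} mm)"
            )
        entries[name] = {
            "point": centerline.points[i].copy(),
            "annotation": p,
            "normal": centerline.tangents[i].copy(),
            "arc_length": float(centerline.arc_length[i]),
        }
    return LandmarkSet(entries)


# -- cross sections -----------------------------------------------------------


@dataclass
class CrossSection:
    """Closed planar intersection polygon with derived quantities."""

    polygon: np.ndarray            # (n, 3) ordered CCW about the normal, open ring
    normal: np.ndarray
    centroid: np.ndarray = field(init=False)
    area: float = field(init=False)
    max_diameter_mm: float = field(init=False, default=float("nan"))
    diameter_endpoints: np.ndarray | None = field(init=False, default=None)

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        if len(self.polygon) < 3:
            raise GeometryError("cross-section polygon needs >= 3 points")
        u, v = _plane_basis(self.normal)
        origin = self.polygon[0]
        xy = np.stack(
            [(self.polygon - origin) @ u, (self.polygon - origin) @ v], axis=1
        )
        x, y = xy[:, 0], xy[:, 1]
        a2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        self.area = float(abs(a2) / 2.0)
        cx = np.sum((x + np.roll(x, -1)) * (x * np.roll(y, -1) - np.roll(x, -1) * y))
        cy = np.sum((y + np.roll(y, -1)) * (x * np.roll(y, -1) - np.roll(x, -1) * y))
        if abs(a2) > 1e-12:
            cx /= 3.0 * a2
            cy /= 3.0 * a2
            self.centroid = origin + cx * u + cy * v
        else:
            self.centroid = self.polygon.mean(axis=0)


def _plane_basis(normal):
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _chain_segments(segments: np.ndarray, tol: float = 1e-6):
    """Assemble plane-intersection segments into polylines.

    Returns a list of ``(points, closed)`` tuples. Endpoints are merged by
    rounding to ``tol``; open chains arise when the plane crosses one of
    the tube's open boundary rings.
    """
    pts = segments.reshape(-1, 3)
    node_of: dict = {}
    coords: list = []
    ids = np.empty(len(pts), dtype=int)
    for i, k in enumerate(map(tuple, np.round(pts / tol).astype(np.int64))):
        j = node_of.setdefault(k, len(coords))
        if j == len(coords):
            coords.append(pts[i])
        ids[i] = j
    edges = {}
    adj: dict = {}
    for a, b in ids.reshape(-1, 2):
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in edges:
            continue
        edges[key] = True
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    unused = dict(edges)
    chains = []
    # open chains start at odd-degree nodes; remaining edges form cycles
    starts = sorted(n for n in adj if len(adj[n]) % 2 == 1)
    for pool in (starts, sorted(adj)):
        for s in pool:
            while True:
                nxt = [b for b in adj[s]
                       if unused.get((min(s, b), max(s, b)))]
                if not nxt:
                    break
                chain = [s]
                cur = s
                while True:
                    cand = [b for b in adj[cur]
                            if unused.get((min(cur, b), max(cur, b)))]
                    if not cand:
                        break
                    b = cand[0]
                    unused[(min(cur, b), max(cur, b))] = False
                    chain.append(b)
                    cur = b
                closed = chain[0] == chain[-1] and len(chain) > 3
                arr = np.asarray([coords[i] for i in
                                  (chain[:-1] if closed else chain)])
                if len(arr) >= 2:
                    chains.append((arr, closed))
    return chains


def cross_section(mesh: SurfaceMesh, point, normal) -> CrossSection:
    """Intersect the plane with the subdivided surface.

    Of all intersection loops, the one whose centroid is nearest ``point``
    is returned, ordered counterclockwise about ``normal``. A plane that
    misses the mesh raises :class:`OutOfRangeError`; a plane crossing an
    open boundary ring yields an open chain and raises
    :class:`BoundaryIntersectionError`.
    """
    import trimesh.intersections

    point = np.asarray(point, dtype=float).reshape(3)
    normal = np.asarray(normal, dtype=float).reshape(3)
    normal = normal / np.linalg.norm(normal)
    tm = mesh.as_trimesh()
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=normal, plane_origin=point)
    if len(segments) == 0:
        raise OutOfRangeError("measurement plane does not intersect the surface")
    info = [
        (pts, closed, np.linalg.norm(pts.mean(axis=0) - point))
        for pts, closed in _chain_segments(np.asarray(segments))
    ]
    if not info:
        raise OutOfRangeError("measurement plane does not intersect the surface")
    pts, closed, _ = min(info, key=lambda t: t[2])
    if not closed:
        raise BoundaryIntersectionError(
            "measurement plane crosses an open boundary ring of the tube"
        )
    # order CCW about the normal
    u, v = _plane_basis(normal)
    xy = np.stack([(pts - point) @ u, (pts - point) @ v], axis=1)
    x, y = xy[:, 0], xy[:, 1]
    if np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        pts = pts[::-1]
    sec = CrossSection(polygon=pts, normal=normal)
    max_diameter(sec)
    return sec


def max_diameter(section: CrossSection) -> float:
    """Diameter of the polygon vertex set: maximum pairwise distance,
    computed on the convex hull; endpoints are recorded on the section."""
    from scipy.spatial import ConvexHull, QhullError

    pts = section.polygon
    if len(pts) < 3:
        raise GeometryError("need at least 3 polygon points")
    u, v = _plane_basis(section.normal)
    origin = pts[0]
    xy = np.stack([(pts - origin) @ u, (pts - origin) @ v], axis=1)
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise GeometryError(f"degenerate (collinear) cross-section: {exc}") from exc
    hp = pts[hull.vertices]
    d2 = np.sum((hp[:, None, :] - hp[None, :, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    section.max_diameter_mm = float(np.sqrt(d2[i, j]))
    section.diameter_endpoints = np.stack([hp[i], hp[j]])
    return section.max_diameter_mm


# -- reports --------------------------------------------------------------------


@dataclass
class DiameterReport:
    """Per-landmark diameters at both time points plus diameter curves."""

    rows: pd.DataFrame
    curves: dict | None = None
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.3f")

    def to_json(self, path) -> None:
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "curves": {
                k: np.asarray(v).tolist() for k, v in (self.curves or {}).items()
            },
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)

    @staticmethod
    def from_csv(path) -> "DiameterReport":
        return DiameterReport(rows=pd.read_csv(path))


def _section_diameter(mesh, point, normal):
    sec = cross_section(mesh, point, normal)
    return sec.max_diameter_mm


def measure_pair(
    baseline_mesh: SurfaceMesh,
    followup_mesh: SurfaceMesh,
    landmarks: LandmarkSet,
) -> DiameterReport:
    """Maximal diameters on both surfaces at every landmark plane.

    The same baseline-defined plane is used for both meshes; per-landmark
    failures are recorded as missing values with a reason, never fatal.
    """
    records = []
    for name, e in landmarks:
        row = {"landmark": name, "arc_length_mm": e["arc_length"],
               "baseline_mm": np.nan, "followup_mm": np.nan,
               "difference_mm": np.nan, "note": ""}
        notes = []
        try:
            row["baseline_mm"] = _section_diameter(baseline_mesh, e["point"], e["normal"])
        except GeometryError as exc:
            notes.append(f"baseline: {exc}")
        try:
            row["followup_mm"] = _section_diameter(followup_mesh, e["point"], e["normal"])
        except GeometryError as exc:
            notes.append(f"followup: {exc}")
        row["difference_mm"] = row["followup_mm"] - row["baseline_mm"]
        row["note"] = "; ".join(notes)
        records.append(row)
    return DiameterReport(rows=pd.DataFrame.from_records(records))


def diameter_curve(
    mesh: SurfaceMesh,
    centerline: Centerline,
    step: float = 2.0,
    landmarks: LandmarkSet | None = None,
):
    """Max diameter vs arc length along the centerline.

    Arc length is reported relative to the STJ landmark when a landmark set
    is supplied. Positions where the plane crosses a boundary ring (or
    misses the tube) are omitted; at least the two endpoints are attempted.
    """
    if step <= 0:
        raise ValueError("curve step must be positive")
    L = centerline.total_length
    svals = np.unique(np.concatenate([np.arange(0.0, L, step), [L]]))
    s_out, d_out = [], []
    for s in svals:
        try:
            d = _section_diameter(
                mesh, centerline.point_at(s), centerline.tangent_at(s)
            )
        except GeometryError:
            continue
        s_out.append(float(s))
        d_out.append(d)
    s_out = np.asarray(s_out)
    if landmarks is not None and "STJ" in landmarks.entries:
        s_out = s_out - landmarks.arc_length("STJ")
    return s_out, np.asarray(d_out)


def _ring_diameters(mesh: SurfaceMesh):
    """Per-ring (arc length, max pairwise vertex distance) on the near-limit
    surface. Requires ``ring_arc_lengths``."""
    if mesh.ring_arc_lengths is None:
        raise SchemaError("mesh has no ring arc lengths; cannot match rings")
    pos = mesh.near_limit_positions().reshape(mesh.n_rings, mesh.ring_size, 3)
    d2 = np.sum((pos[:, :, None, :] - pos[:, None, :, :]) ** 2, axis=3)
    return mesh.ring_arc_lengths, np.sqrt(d2.reshape(mesh.n_rings, -1).max(axis=1))


def dilatation_field(baseline_mesh: SurfaceMesh, followup_mesh: SurfaceMesh) -> np.ndarray:
    """Per-control-vertex diameter change (mm), stored on the baseline mesh.

    Rings are matched by baseline arc length; baseline rings outside the
    follow-up mesh's arc span get NaN. The field is also attached as the
    baseline mesh's ``vertex_scalar`` channel (the color-coded dilatation
    overlay: 0/5/10 mm differences).
    """
    s_b, d_b = _ring_diameters(baseline_mesh)
    s_f, d_f = _ring_diameters(followup_mesh)
    d_f_at_b = np.interp(s_b, s_f, d_f, left=np.nan, right=np.nan)
    ring_change = d_f_at_b - d_b
    field_vals = np.repeat(ring_change, baseline_mesh.ring_size)
    baseline_mesh.vertex_scalar = field_vals
    return field_vals
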