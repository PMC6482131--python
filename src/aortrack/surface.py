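"""Deformable subdivision-surface segmentation of the aortic lumen.

A coarse control mesh — R rings of K vertices swept along the centerline
with rotation-minimizing frames — is refined by Loop subdivision (cubic
B-spline rules on the two open boundary rings) and deformed so that its
near-limit surface sits on the strongest image-gradient ridge along each
vertex's outward normal. On the baseline scan the tube is initialized from a
per-ring edge-distance estimate; on the aligned follow-up scan the baseline
surface itself is the initial contour, after a centerline-based adaptive
threshold has suppressed bone (bright) and muscle (dark) neighbours.

The accepted ridge along each outward ray is the *first* local maximum, when
scanning outward, that reaches 50% of the ray's global maximum: this lands
on the lumen-wall interface ("inner edge") rather than on outer-wall or
calcification edges.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, identity

from .centerline import Centerline
from .errors import FitFailure, GeometryError
from .image_model import ImageVolume

log = logging.getLogger(__name__)

DEFAULT_SUBDIV_LEVELS = 2
DEFAULT_VERTICES_PER_RING = 16
DEFAULT_RINGS_PER_CM = 2.0
CONVERGENCE_MM = 0.05


# -- mesh type -----------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Closed-tube control mesh (two open end rings) plus its subdivision.

    Control vertex ``r * ring_size + k`` is the vertex with ring index ``r``
    and angular index ``k``. ``ring_arc_lengths`` records, per ring, the
    baseline-centerline arc length the ring was built at (used to match
    rings between time points).
    """

    control_vertices: np.ndarray
    n_rings: int
    ring_size: int
    ring_arc_lengths: np.ndarray | None = None
    levels: int = 0
    subdivided_vertices: np.ndarray | None = None
    subdivided_faces: np.ndarray | None = None
    vertex_scalar: np.ndarray | None = None

    def __post_init__(self):
        self.control_vertices = np.asarray(self.control_vertices, dtype=float)
        if self.control_vertices.shape != (self.n_rings * self.ring_size, 3):
            raise GeometryError("control vertex array does not match ring layout")
        if self.n_rings < 2 or self.ring_size < 3:
            raise GeometryError("tube mesh needs >= 2 rings of >= 3 vertices")
        if self.ring_arc_lengths is not None:
            self.ring_arc_lengths = np.asarray(self.ring_arc_lengths, dtype=float)

    # -- topology ---------------------------------------------------------

    @property
    def control_faces(self) -> np.ndarray:
        return _tube_faces(self.n_rings, self.ring_size)

    def ring_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_rings), self.ring_size)

    def angular_index(self) -> np.ndarray:
        return np.tile(np.arange(self.ring_size), self.n_rings)

    # -- geometry ----------------------------------------------------------

    def ring_centers(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.control_vertices if vertices is None else vertices
        return v.reshape(self.n_rings, self.ring_size, 3).mean(axis=1)

    def control_normals(self, vertices: np.ndarray | None = None) -> np.ndarray:
        """Outward unit normals: from ring centroid through each vertex."""
        v = self.control_vertices if vertices is None else vertices
        centers = np.repeat(self.ring_centers(v), self.ring_size, axis=0)
        n = v - centers
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        if np.any(norms < 1e-12):
            raise GeometryError("degenerate ring: vertex coincides with centroid")
        return n / norms

    def near_limit_positions(self) -> np.ndarray:
        """Positions of the control vertices on the (near-)limit surface."""
        S, _ = subdivision_operator(self, max(self.levels, DEFAULT_SUBDIV_LEVELS))
        return (S @ self.control_vertices)[: len(self.control_vertices)]

    def ring_radii(self) -> np.ndarray:
        """Mean near-limit surface radius per ring (mm)."""
        pos = self.near_limit_positions()
        centers = np.repeat(self.ring_centers(pos), self.ring_size, axis=0)
        r = np.linalg.norm(pos - centers, axis=1)
        return r.reshape(self.n_rings, self.ring_size).mean(axis=1)

    def surface_vertices(self) -> np.ndarray:
        return (
            self.subdivided_vertices
            if self.subdivided_vertices is not None
            else self.control_vertices
        )

    def surface_faces(self) -> np.ndarray:
        return (
            self.subdivided_faces
            if self.subdivided_faces is not None
            else self.control_faces
        )

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.surface_vertices(), faces=self.surface_faces(),
            process=False,
        )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "control_vertices": self.control_vertices.tolist(),
            "n_rings": self.n_rings,
            "ring_size": self.ring_size,
            "levels": self.levels,
        }
        if self.ring_arc_lengths is not None:
            d["ring_arc_lengths"] = self.ring_arc_lengths.tolist()
        if self.vertex_scalar is not None:
            d["vertex_scalar"] = np.asarray(self.vertex_scalar).tolist()
        return d

    @staticmethod
    def from_dict(d: dict) -> "SurfaceMesh":
        mesh = SurfaceMesh(
            control_vertices=np.asarray(d["control_vertices"], dtype=float),
            n_rings=int(d["n_rings"]),
            ring_size=int(d["ring_size"]),
            ring_arc_lengths=(
                np.asarray(d["ring_arc_lengths"], dtype=float)
                if "ring_arc_lengths" in d else None
            ),
            vertex_scalar=(
                np.asarray(d["vertex_scalar"], dtype=float)
                if "vertex_scalar" in d else None
            ),
        )
        if d.get("levels", 0):
            mesh = subdivide(mesh, int(d["levels"]))
        return mesh

    def save_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @staticmethod
    def load_json(path) -> "SurfaceMesh":
        import json

        with open(path) as fh:
            return SurfaceMesh.from_dict(json.load(fh))

    def save_ply(self, path) -> None:
        """Binary little-endian PLY of the subdivided surface; a per-vertex
        scalar channel (the dilatation field) is stored as 'quality'."""
        mesh = self.as_trimesh()
        if self.vertex_scalar is not None:
            S, _ = subdivision_operator(self, self.levels) if self.levels else (None, None)
            scal = (
                S @ np.asarray(self.vertex_scalar, dtype=float)
                if S is not None
                else np.asarray(self.vertex_scalar, dtype=float)
            )
            mesh.vertex_attributes["quality"] = scal.astype(np.float32)
        mesh.export(str(path), file_type="ply", encoding="binary_little_endian")

    def save_vtk(self, path) -> None:
        """Legacy ASCII VTK polydata of the subdivided surface."""
        verts = self.surface_vertices()
        faces = self.surface_faces()
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\naortrack surface\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {len(verts)} float\n")
            for p in verts:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
            if self.vertex_scalar is not None:
                S, _ = (
                    subdivision_operator(self, self.levels)
                    if self.levels else (None, None)
                )
                scal = (
                    S @ np.asarray(self.vertex_scalar, dtype=float)
                    if S is not None
                    else np.asarray(self.vertex_scalar, dtype=float)
                )
                fh.write(f"POINT_DATA {len(verts)}\n")
                fh.write("SCALARS dilatation_mm float 1\nLOOKUP_TABLE default\n")
                for v in scal:
                    fh.write(f"{v:.6f}\n")


def _tube_faces(n_rings: int, ring_size: int) -> np.ndarray:
    faces = []
    K = ring_size
    for r in range(n_rings - 1):
        for k in range(K):
            a = r * K + k
            b = r * K + (k + 1) % K
            c = (r + 1) * K + (k + 1) % K
            d = (r + 1) * K + k
            faces.append((a, b, c))
            faces.append((a, c, d))
    return np.asarray(faces, dtype=int)


# -- Loop subdivision ------------------------------------------------------------


def _loop_step(faces: np.ndarray, n_vert: int):
    """One Loop subdivision step: sparse operator S (new <- old vertices) and
    the refined face array. Boundary edges/vertices use cubic B-spline rules."""
    edge_opp: dict[tuple[int, int], list[int]] = {}
    for a, b, c in faces:
        for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
            key = (u, v) if u < v else (v, u)
            edge_opp.setdefault(key, []).append(int(w))

    rows, cols, vals = [], [], []
    edge_ids = {}
    for i, key in enumerate(sorted(edge_opp)):
        vid = n_vert + i
        edge_ids[key] = vid
        a, b = key
        opp = edge_opp[key]
        if len(opp) == 1:  # boundary edge: midpoint
            rows += [vid, vid]
            cols += [a, b]
            vals += [0.5, 0.5]
        else:
            rows += [vid] * 4
            cols += [a, b, opp[0], opp[1]]
            vals += [0.375, 0.375, 0.125, 0.125]

    neighbors = defaultdict(set)
    boundary_nb = defaultdict(set)
    for (a, b), opp in edge_opp.items():
        neighbors[a].add(b)
        neighbors[b].add(a)
        if len(opp) == 1:
            boundary_nb[a].add(b)
            boundary_nb[b].add(a)

    for v in range(n_vert):
        bnb = boundary_nb[v]
        if bnb:
            if len(bnb) == 2:
                b1, b2 = sorted(bnb)
                rows += [v, v, v]
                cols += [v, b1, b2]
                vals += [0.75, 0.125, 0.125]
            else:  # irregular boundary corner: interpolate
                rows.append(v)
                cols.append(v)
                vals.append(1.0)
        else:
            nb = sorted(neighbors[v])
            n = len(nb)
            beta = (0.625 - (0.375 + 0.25 * np.cos(2 * np.pi / n)) ** 2) / n
            rows += [v] + [v] * n
            cols += [v] + nb
            vals += [1.0 - n * beta] + [beta] * n

    new_faces = []
    for a, b, c in faces:
        eab = edge_ids[(a, b) if a < b else (b, a)]
        ebc = edge_ids[(b, c) if b < c else (c, b)]
        eca = edge_ids[(c, a) if c < a else (a, c)]
        new_faces += [(a, eab, eca), (b, ebc, eab), (c, eca, ebc), (eab, ebc, eca)]

    S = coo_matrix(
        (vals, (rows, cols)), shape=(n_vert + len(edge_ids), n_vert)
    ).tocsr()
    return S, np.asarray(new_faces, dtype=int)


_OPERATOR_CACHE: dict[tuple, tuple] = {}


def subdivision_operator(mesh: SurfaceMesh, levels: int):
    """Composite sparse operator mapping control vertices to the level-
    ``levels`` subdivided vertices, plus the final face array. Even (control)
    vertices keep their indices at every level."""
    key = (mesh.n_rings, mesh.ring_size, levels)
    if key in _OPERATOR_CACHE:
        return _OPERATOR_CACHE[key]
    faces = mesh.control_faces
    n = len(mesh.control_vertices)
    S = identity(n, format="csr")
    for _ in range(levels):
        step, faces = _loop_step(faces, S.shape[0])
        S = step @ S
    _OPERATOR_CACHE[key] = (S, faces)
    return S, faces


def subdivide(mesh: SurfaceMesh, levels: int) -> SurfaceMesh:
    """Apply ``levels`` rounds of Loop subdivision (0 is the identity)."""
    if levels < 0:
        raise ValueError("subdivision levels must be >= 0")
    if levels == 0:
        return replace(
            mesh,
            levels=0,
            subdivided_vertices=mesh.control_vertices.copy(),
            subdivided_faces=mesh.control_faces,
        )
    S, faces = subdivision_operator(mesh, levels)
    return replace(
        mesh,
        levels=levels,
        subdivided_vertices=S @ mesh.control_vertices,
        subdivided_faces=faces,
    )


# -- tube initialization -----------------------------------------------------------


def _rotation_minimizing_frames(points: np.ndarray, tangents: np.ndarray):
    """Double-reflection rotation-minimizing frames along a polyline."""
    n = len(points)
    u = np.zeros((n, 3))
    t0 = tangents[0]
    helper = np.array([0.0, 0.0, 1.0])
    if abs(t0 @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u[0] = np.cross(t0, helper)
    u[0] /= np.linalg.norm(u[0])
    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = v1 @ v1
        if c1 < 1e-14:
            u[i + 1] = u[i]
            continue
        uL = u[i] - (2.0 / c1) * (v1 @ u[i]) * v1
        tL = tangents[i] - (2.0 / c1) * (v1 @ tangents[i]) * v1
        v2 = tangents[i + 1] - tL
        c2 = v2 @ v2
        u[i + 1] = uL if c2 < 1e-14 else uL - (2.0 / c2) * (v2 @ uL) * v2
        u[i + 1] -= (u[i + 1] @ tangents[i + 1]) * tangents[i + 1]
        u[i + 1] /= np.linalg.norm(u[i + 1])
    v = np.cross(tangents, u)
    return u, v


def init_tube_mesh(
    centerline: Centerline,
    radius,
    rings_per_cm: float = DEFAULT_RINGS_PER_CM,
    vertices_per_ring: int = DEFAULT_VERTICES_PER_RING,
) -> SurfaceMesh:
    """Generalized-cylinder control mesh around the centerline.

    ``radius`` may be a scalar or a per-ring array. Rings are spaced at
    equal arc-length intervals; rotation-minimizing frames keep adjacent
    rings untwisted.
    """
    K = int(vertices_per_ring)
    if K < 3:
        raise ValueError("need at least 3 vertices per ring")
    L = centerline.total_length
    n_rings = max(2, int(round(L * rings_per_cm / 10.0)) + 1)
    s = np.linspace(0.0, L, n_rings)
    centers = centerline.point_at(s)
    tangents = centerline.tangent_at(s)
    radii = np.broadcast_to(np.asarray(radius, dtype=float), (n_rings,)).copy()
    if np.any(radii <= 0):
        raise ValueError("tube radius must be positive")
    u, v = _rotation_minimizing_frames(centers, tangents)
    phi = 2.0 * np.pi * np.arange(K) / K
    ring = np.cos(phi)[:, None], np.sin(phi)[:, None]
    verts = (
        centers[:, None, :]
        + radii[:, None, None] * (ring[0][None] * u[:, None, :] + ring[1][None] * v[:, None, :])
    ).reshape(-1, 3)
    return SurfaceMesh(
        control_vertices=verts, n_rings=n_rings, ring_size=K, ring_arc_lengths=s
    )


# -- cost image --------------------------------------------------------------------


@dataclass
class CostImage:
    """Nonnegative scalar field (gradient magnitude, HU/mm) on a volume grid."""

    grid: ImageVolume

    def __post_init__(self):
        if np.any(self.grid.voxels < -1e-6):
            raise ValueError("cost image must be nonnegative")

    def sample(self, points_mm) -> np.ndarray:
        return self.grid.sample_world(points_mm, order=1, background=0.0)


def gradient_cost(volume: ImageVolume, smoothing_sigma: float = 1.0) -> CostImage:
    """Gaussian-smoothed gradient magnitude of the intensity, in HU/mm."""
    if smoothing_sigma < 0:
        raise ValueError("smoothing sigma must be >= 0")
    v = volume.voxels.astype(np.float64)
    sp_zyx = volume.spacing[::-1]
    grads = []
    for axis in range(3):
        if smoothing_sigma > 0:
            sig_vox = smoothing_sigma / sp_zyx
            orders = [0, 0, 0]
            orders[axis] = 1
            # gaussian_filter with sigma in voxels differentiates w.r.t. the
            # voxel index; divide by spacing to get HU/mm
            g = ndimage.gaussian_filter(v, sigma=sig_vox, order=orders)
            g /= sp_zyx[axis]
        else:
            g = np.gradient(v, sp_zyx[axis], axis=axis)
        grads.append(g)
    mag = np.sqrt(grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2).astype(np.float32)
    return CostImage(grid=volume.copy_with(voxels=mag))


def adaptive_threshold(
    volume: ImageVolume,
    centerline: Centerline,
    window: float = 20.0,
    stat_radius: float = 5.0,
    protect_points: np.ndarray | None = None,
    protect_radius: float = 8.0,
) -> ImageVolume:
    """Centerline-based adaptive intensity clamp.

    For each arc-length window, lumen statistics (mean ``m``, SD ``s``) are
    estimated from voxels within ``stat_radius`` of the centerline, and
    every voxel in the window's slab (nearest-centerline assignment) is
    clamped to ``[m - 4 s, m + 2 s]``. The asymmetric bounds suppress bright
    bone harder than dark muscle.

    Clamping through the lumen-wall transition would drag the gradient peak
    inward, so when ``protect_points`` (normally the current surface
    estimate) is given, voxels within ``protect_radius`` mm of those points
    keep their original intensity: the threshold suppresses *surrounding*
    tissue, never the boundary being detected.
    """
    from scipy.spatial import cKDTree

    total = centerline.total_length
    if window > total:
        log.warning(
            "adaptive_threshold window (%.0f mm) exceeds centerline length "
            "(%.0f mm); using a single global window", window, total,
        )
        window = total
    cl = centerline.resampled(step=1.0, smooth_window=1)
    win_id = np.minimum(
        (cl.arc_length / window).astype(int), max(int(np.ceil(total / window)) - 1, 0)
    )
    n_win = win_id.max() + 1

    nz, ny, nx = volume.voxels.shape
    # identity-direction fast path; general case goes through voxel_to_world
    if np.allclose(volume.direction, np.eye(3)):
        xs = np.arange(nx) * volume.spacing[0] + volume.origin[0]
        ys = np.arange(ny) * volume.spacing[1] + volume.origin[1]
        zs = np.arange(nz) * volume.spacing[2] + volume.origin[2]
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        world = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    else:
        idx = np.indices((nz, ny, nx)).reshape(3, -1).T[:, ::-1].astype(float)
        world = volume.voxel_to_world(idx)

    tree = cKDTree(cl.points)
    dist, nearest = tree.query(world)
    flat = volume.voxels.reshape(-1).copy()
    vox_win = win_id[nearest]
    # keep the stat balls away from the tube ends, where the vessel is
    # truncated and the ball would swallow background voxels
    interior = (cl.arc_length >= stat_radius) & (
        cl.arc_length <= total - stat_radius)
    stat_ok = interior[nearest]
    protected = np.zeros(len(flat), dtype=bool)
    if protect_points is not None and len(protect_points):
        d_prot, _ = cKDTree(np.asarray(protect_points, dtype=float)).query(
            world, distance_upper_bound=protect_radius
        )
        protected = np.isfinite(d_prot)
    for w in range(n_win):
        stat_sel = (vox_win == w) & (dist <= stat_radius) & stat_ok
        if not np.any(stat_sel):
            continue
        m = float(flat[stat_sel].mean())
        s = max(float(flat[stat_sel].std()), 1.0)
        sel = (vox_win == w) & ~protected
        flat[sel] = np.clip(flat[sel], m - 4.0 * s, m + 2.0 * s)
    return volume.copy_with(voxels=flat.reshape(volume.voxels.shape))


# -- deformable fit ------------------------------------------------------------------


def _control_adjacency(n_rings: int, K: int):
    """Neighbor index array (n_ctrl, 4) for Laplacian smoothing; ring ends
    reuse themselves for the missing axial neighbor."""
    n = n_rings * K
    idx = np.arange(n)
    r = idx // K
    k = idx % K
    left = r * K + (k - 1) % K
    right = r * K + (k + 1) % K
    up = np.where(r > 0, (r - 1) * K + k, idx)
    down = np.where(r < n_rings - 1, (r + 1) * K + k, idx)
    return np.stack([left, right, up, down], axis=1)


def _select_ridge_offsets(values: np.ndarray, ridge_fraction: float = 0.5,
                          scale: np.ndarray | None = None):
    """Per ray: index of the first local maximum (scanning outward) that
    reaches ``ridge_fraction`` of the reference edge strength.

    The reference is the ray's own maximum unless ``scale`` is given (one
    value per ray). Grouped fits pass the ring-median of per-ray maxima so
    that a single very bright interloper (bone next to the wall) cannot
    raise the bar above the true lumen edge for the rays that graze it.
    """
    n, m = values.shape
    pad = np.pad(values, ((0, 0), (1, 1)), mode="edge")
    local_max = (values >= pad[:, :-2]) & (values >= pad[:, 2:])
    vmax = values.max(axis=1) if scale is None else np.asarray(scale)
    cand = local_max & (values >= ridge_fraction * vmax[:, None])
    cand[np.arange(n), values.argmax(axis=1)] = True  # strongest always valid
    return cand.argmax(axis=1)


def fit_surface(
    mesh: SurfaceMesh,
    cost: CostImage,
    iterations: int = 200,
    step: float = 0.5,
    smooth_weight: float = 0.3,
    search_range: float = 10.0,
    sample_step: float = 0.25,
    ridge_fraction: float = 0.5,
    return_history: bool = False,
):
    """Deform the control mesh so its near-limit surface sits on the cost ridge.

    Each iteration samples the cost along every vertex's outward normal in
    ``[-search_range, +search_range]``, picks the inner-edge ridge offset,
    moves the vertex by ``step`` times that offset (snapped to the sampling
    grid, and only if the sampled cost there is no worse than at the current
    position), then smooths the displacement field over the control lattice
    with weight ``smooth_weight``. Stops when the largest vertex displacement
    falls below 0.05 mm.
    """
    if search_range <= 0:
        raise ValueError("search range must be positive")
    S, _ = subdivision_operator(mesh, max(mesh.levels, DEFAULT_SUBDIV_LEVELS))
    n_ctrl = len(mesh.control_vertices)
    ctrl = mesh.control_vertices.copy()
    adj = _control_adjacency(mesh.n_rings, mesh.ring_size)
    offsets = np.arange(-search_range, search_range + sample_step / 2, sample_step)
    zero_i = int(np.argmin(np.abs(offsets)))
    vol = cost.grid
    history = []

    for _ in range(int(iterations)):
        pos = (S @ ctrl)[:n_ctrl]
        idx = vol.world_to_voxel(pos)
        nx, ny, nzv = vol.shape_xyz
        if np.any(idx < -0.5) or np.any(idx > np.array([nx, ny, nzv]) - 0.5):
            raise FitFailure("surface deformed outside the volume bounds")
        normals = mesh.control_normals(ctrl)
        rays = pos[:, None, :] + offsets[None, :, None] * normals[:, None, :]
        vals = cost.sample(rays.reshape(-1, 3)).reshape(n_ctrl, len(offsets))
        history.append(float(vals[:, zero_i].sum()))

        ray_max = vals.max(axis=1).reshape(mesh.n_rings, mesh.ring_size)
        ring_scale = np.repeat(np.median(ray_max, axis=1), mesh.ring_size)
        sel = _select_ridge_offsets(vals, ridge_fraction, scale=ring_scale)
        t_sel = offsets[sel]
        # snap the damped move to the sampling grid and keep it monotone
        snap = np.clip(
            np.rint(step * t_sel / sample_step).astype(int) + zero_i,
            0, len(offsets) - 1,
        )
        v0 = vals[:, zero_i]
        rows = np.arange(n_ctrl)
        use_snap = vals[rows, snap] >= v0
        use_full = vals[rows, sel] >= v0
        move = np.where(use_snap, offsets[snap], np.where(use_full, t_sel, 0.0))
        disp = move[:, None] * normals

        if smooth_weight > 0:
            disp = (1.0 - smooth_weight) * disp + smooth_weight * disp[adj].mean(axis=1)
            ctrl = ctrl + disp
        else:
            # without smoothing the ascent is kept monotone in the total
            # sampled cost by backtracking (the subdivision operator mixes
            # neighbour displacements, so the per-ray guard alone is not
            # enough near the boundary rings)
            scale = 1.0
            accepted = False
            for _ in range(4):
                trial = ctrl + scale * disp
                tot = float(cost.sample((S @ trial)[:n_ctrl]).sum())
                if tot >= history[-1] - 1e-9:
                    ctrl = trial
                    disp = scale * disp
                    accepted = True
                    break
                scale *= 0.5
            if not accepted:
                break
        if np.max(np.linalg.norm(disp, axis=1)) < CONVERGENCE_MM:
            break

    fitted = replace(mesh, control_vertices=ctrl)
    fitted = subdivide(fitted, max(mesh.levels, DEFAULT_SUBDIV_LEVELS))
    if return_history:
        return fitted, history
    return fitted


# -- high-level segmentation -----------------------------------------------------------


def estimate_ring_radii(
    cost: CostImage,
    centerline: Centerline,
    arc_positions: np.ndarray,
    r_min: float = 4.0,
    r_max: float = 30.0,
    n_dirs: int = 8,
    ridge_fraction: float = 0.5,
) -> np.ndarray:
    """Median cost-ridge distance from the centerline, per arc position."""
    from .centerline import _orthonormal_frame

    radii = np.arange(r_min, r_max + 0.125, 0.25)
    out = np.empty(len(arc_positions))
    for i, s in enumerate(arc_positions):
        p = centerline.point_at(s)
        u, v = _orthonormal_frame(centerline.tangent_at(s))
        phi = np.pi * 2.0 * np.arange(n_dirs) / n_dirs
        dirs = np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v
        pts = p[None, None, :] + radii[None, :, None] * dirs[:, None, :]
        vals = cost.sample(pts.reshape(-1, 3)).reshape(n_dirs, len(radii))
        scale = np.full(n_dirs, np.median(vals.max(axis=1)))
        sel = _select_ridge_offsets(vals, ridge_fraction, scale=scale)
        out[i] = float(np.median(radii[sel]))
    # smooth along the tube
    if len(out) > 5:
        kernel = np.ones(5) / 5.0
        out = np.convolve(np.pad(out, 2, mode="edge"), kernel, mode="valid")
    return out


def segment_baseline(
    volume: ImageVolume,
    centerline: Centerline,
    smoothing_sigma: float = 1.0,
    rings_per_cm: float = DEFAULT_RINGS_PER_CM,
    vertices_per_ring: int = DEFAULT_VERTICES_PER_RING,
    levels: int = DEFAULT_SUBDIV_LEVELS,
    search_range: float = 10.0,
    iterations: int = 200,
    step: float = 0.5,
    smooth_weight: float = 0.3,
    min_quality: float = 0.2,
) -> SurfaceMesh:
    """De-novo lumen surface: ridge-estimated tube, subdivided, fitted.

    Raises :class:`FitFailure` if the converged surface does not sit on a
    coherent gradient ridge (``min_quality`` of the cost image's strong-edge
    scale), which is what happens when the centerline missed the vessel.
    """
    cost = gradient_cost(volume, smoothing_sigma)
    L = centerline.total_length
    n_rings = max(2, int(round(L * rings_per_cm / 10.0)) + 1)
    s = np.linspace(0.0, L, n_rings)
    radii = estimate_ring_radii(cost, centerline, s)
    mesh = init_tube_mesh(centerline, radii, rings_per_cm, vertices_per_ring)
    mesh = subdivide(mesh, levels)
    fitted = fit_surface(
        mesh, cost, iterations=iterations, step=step,
        smooth_weight=smooth_weight, search_range=search_range,
    )
    quality = _fit_quality(fitted, cost)
    if quality < min_quality:
        raise FitFailure(
            f"fitted surface is not on a coherent intensity edge "
            f"(quality {quality:.2f} < {min_quality}); check the centerline"
        )
    fitted.fit_quality = quality
    return fitted


def _fit_quality(mesh: SurfaceMesh, cost: CostImage) -> float:
    """Median vertex cost relative to the strong-edge scale near the mesh.

    The normalization uses the cost distribution inside the mesh's expanded
    bounding box, so unrelated far-away edges (rib cage, unclamped regions)
    do not dilute the score.
    """
    pos = mesh.near_limit_positions()
    vertex_cost = cost.sample(pos)
    vol = cost.grid
    idx = vol.world_to_voxel(pos)
    margin = 15.0 / vol.spacing
    nx, ny, nz = vol.shape_xyz
    lo = np.maximum(np.floor(idx.min(axis=0) - margin).astype(int), 0)
    hi = np.minimum(np.ceil(idx.max(axis=0) + margin).astype(int) + 1, [nx, ny, nz])
    box = vol.voxels[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]]
    scale = float(np.percentile(box, 99.5)) if box.size else 0.0
    return float(np.median(vertex_cost) / max(scale, 1e-9))


def segment_followup(
    aligned_followup: ImageVolume,
    baseline_mesh: SurfaceMesh,
    baseline_centerline: Centerline,
    smoothing_sigma: float = 1.0,
    search_range: float = 6.0,
    iterations: int = 200,
    step: float = 0.5,
    smooth_weight: float = 0.3,
    threshold_window: float = 20.0,
    min_quality: float = 0.2,
) -> SurfaceMesh:
    """Follow-up lumen surface, initialized from the baseline surface.

    The aligned follow-up volume is adaptively thresholded around the
    baseline centerline, its gradient magnitude becomes the cost image, and
    the baseline mesh is deformed onto the new inner edge.
    """
    pre = adaptive_threshold(
        aligned_followup, baseline_centerline, threshold_window,
        protect_points=baseline_mesh.near_limit_positions(),
        protect_radius=search_range + 2.0,
    )
    cost = gradient_cost(pre, smoothing_sigma)
    fitted = fit_surface(
        baseline_mesh, cost, iterations=iterations, step=step,
        smooth_weight=smooth_weight, search_range=search_range,
    )
    quality = _fit_quality(fitted, cost)
    if quality < min_quality:
        raise FitFailure(
            f"follow-up surface is not on a coherent intensity edge "
            f"(quality {quality:.2f} < {min_quality})"
        )
    fitted.fit_quality = quality
    return fitted


def region_grow(volume: ImageVolume, seed_mm, interval) -> np.ndarray:
    """26-connected component of voxels within ``interval`` containing the seed.

    Returned as a binary mask in array layout; intended as a QC overlay for
    the aortic arch and its branches, not as a modification of the fitted
    surface.
    """
    lo, hi = float(interval[0]), float(interval[1])
    idx = np.rint(volume.world_to_voxel(seed_mm)).astype(int)
    if not volume.contains_voxel(idx):
        raise ValueError("seed point is outside the volume")
    seed_val = volume.voxels[idx[2], idx[1], idx[0]]
    if not (lo <= seed_val <= hi):
        raise ValueError(
            f"seed intensity {seed_val:.1f} HU is outside the interval [{lo}, {hi}]"
        )
    in_range = (volume.voxels >= lo) & (volume.voxels <= hi)
    labels, _ = ndimage.label(in_range, structure=np.ones((3, 3, 3), dtype=bool))
    return labels == labels[idx[2], idx[1], idx[0]]


def mean_surface_distance(a: SurfaceMesh, b: SurfaceMesh) -> float:
    """Symmetric mean vertex-to-surface distance between two subdivided meshes."""
    from scipy.spatial import cKDTree

    va, vb = a.surface_vertices(), b.surface_vertices()
    d_ab, _ = cKDTree(vb).query(va)
    d_ba, _ = cKDTree(va).query(vb)
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
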