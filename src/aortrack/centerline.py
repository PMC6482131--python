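"""Aortic centerline extraction.

The lumen is modelled by a Gaussian intensity distribution estimated around a
user seed. Each voxel gets a nonnegative cost equal to the Gaussian negative
log-likelihood of its intensity (shifted so the cost is 0 at the model mean),
and the centerline is the minimum-cost path on the 26-connected voxel grid
between two endpoints — a wave-propagation / Dijkstra scheme. Because
shortest paths hug the inner side of bends, a recentring pass moves each
point to the intensity-weighted centroid of the admissible lumen voxels in
its normal plane.

Voxels with cost above an admissibility ceiling (default: the cost at
mean +/- 3 sigma) are excluded from the search entirely; if no admissible
route exists the extraction fails loudly rather than returning a path
outside the vessel.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

from .errors import EndpointDetectionError, ExtractionFailure
from .image_model import ImageVolume

log = logging.getLogger(__name__)

#: length penalty (cost units per mm) added to every edge so that, in
#: homogeneous lumen where the likelihood cost vanishes, the shortest path
#: is the geometrically shortest admissible route.
LENGTH_PENALTY = 0.01

#: default admissibility ceiling, in standard deviations from the model mean.
ADMISSIBLE_SIGMA = 3.0

RESAMPLE_STEP_MM = 1.0
SMOOTH_WINDOW = 5


# -- types --------------------------------------------------------------------


@dataclass
class LumenIntensityModel:
    """Gaussian model of contrast-filled lumen intensity."""

    mean: float
    std: float

    def __post_init__(self):
        if self.std <= 0:
            raise ValueError("lumen model standard deviation must be positive")


class Centerline:
    """Ordered polyline through the lumen with arc-length parameterization.

    Attributes
    ----------
    points : (n, 3) world mm
    arc_length : (n,) cumulative mm, strictly increasing, starts at 0
    tangents : (n, 3) unit vectors
    """

    def __init__(self, points, arc_length=None, tangents=None):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("centerline needs at least two 3-D points")
        self.points = pts
        if arc_length is None:
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if np.any(seg <= 0):
                raise ValueError("centerline has coincident consecutive points")
            arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        self.arc_length = np.asarray(arc_length, dtype=float)
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc length must be strictly increasing")
        if tangents is None:
            tangents = np.gradient(pts, self.arc_length, axis=0)
            tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        self.tangents = np.asarray(tangents, dtype=float)

    def __len__(self):
        return len(self.points)

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s) -> np.ndarray:
        """Linear interpolation of position at arc length(s) ``s``."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        return np.stack(
            [np.interp(s, self.arc_length, self.points[:, k]) for k in range(3)],
            axis=-1,
        )

    def tangent_at(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        t = np.stack(
            [np.interp(s, self.arc_length, self.tangents[:, k]) for k in range(3)],
            axis=-1,
        )
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def project(self, point_mm) -> float:
        """Arc length of the sample nearest ``point_mm``."""
        d = np.linalg.norm(self.points - np.asarray(point_mm, dtype=float), axis=1)
        return float(self.arc_length[int(np.argmin(d))])

    def distance_to(self, points_mm) -> np.ndarray:
        """Distance of external points to the polyline samples."""
        from scipy.spatial import cKDTree

        tree = cKDTree(self.points)
        d, _ = tree.query(np.atleast_2d(points_mm))
        return d

    def resampled(self, step: float = RESAMPLE_STEP_MM,
                  smooth_window: int = SMOOTH_WINDOW) -> "Centerline":
        """Resample at equal arc steps and smooth with a moving average."""
        n = max(int(round(self.total_length / step)) + 1, 2)
        s = np.linspace(0.0, self.total_length, n)
        pts = self.point_at(s)
        if smooth_window > 1 and len(pts) > smooth_window:
            k = smooth_window
            pad = k // 2
            padded = np.pad(pts, ((pad, pad), (0, 0)), mode="edge")
            kernel = np.ones(k) / k
            pts = np.stack(
                [np.convolve(padded[:, j], kernel, mode="valid") for j in range(3)],
                axis=1,
            )
        return Centerline(pts)

    def to_dict(self) -> dict:
        return {
            "points_mm": self.points.tolist(),
            "arc_length_mm": self.arc_length.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "Centerline":
        return Centerline(np.asarray(d["points_mm"], dtype=float))

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @staticmethod
    def load(path) -> "Centerline":
        import json

        with open(path) as fh:
            return Centerline.from_dict(json.load(fh))


# -- operations ----------------------------------------------------------------


def fit_lumen_model(volume: ImageVolume, seed_mm, sample_radius: float = 5.0) -> LumenIntensityModel:
    """Estimate lumen mean/SD from the ball of ``sample_radius`` mm around a seed.

    The SD is floored at 1 HU so a perfectly homogeneous region still yields
    a usable Gaussian model.
    """
    idx = volume.world_to_voxel(seed_mm)
    if not volume.contains_voxel(idx):
        raise ValueError(f"seed point {seed_mm} is outside the volume")
    r_vox = np.maximum(sample_radius / volume.spacing, 0.0)
    nx, ny, nz = volume.shape_xyz
    lo = np.maximum(np.floor(idx - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(idx + r_vox).astype(int) + 1, [nx, ny, nz])
    sub = volume.voxels[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]]
    zz, yy, xx = np.meshgrid(
        np.arange(lo[2], hi[2]), np.arange(lo[1], hi[1]), np.arange(lo[0], hi[0]),
        indexing="ij",
    )
    d2 = (
        ((xx - idx[0]) * volume.spacing[0]) ** 2
        + ((yy - idx[1]) * volume.spacing[1]) ** 2
        + ((zz - idx[2]) * volume.spacing[2]) ** 2
    )
    vals = sub[d2 <= sample_radius ** 2]
    if vals.size == 0:
        vals = np.asarray([volume.sample_world(seed_mm)[0]])
    return LumenIntensityModel(float(vals.mean()), max(float(vals.std()), 1.0))


def voxel_cost(intensity, model: LumenIntensityModel):
    """Shifted Gaussian negative log-likelihood: 0 at the mean, k^2/2 at k sigma."""
    z = (np.asarray(intensity, dtype=np.float64) - model.mean) / model.std
    return 0.5 * z * z


def _admissible_cost_ceiling(sigma: float = ADMISSIBLE_SIGMA) -> float:
    return 0.5 * sigma * sigma


def _neighbor_offsets():
    """The 13 half-space offsets of 26-connectivity, in (z, y, x) order."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) > (0, 0, 0):
                    offs.append((dz, dy, dx))
    return offs


def extract_path(
    volume: ImageVolume,
    model: LumenIntensityModel,
    start_mm,
    end_mm,
    ceiling_sigma: float = ADMISSIBLE_SIGMA,
    length_penalty: float = LENGTH_PENALTY,
    return_cost: bool = False,
):
    """Minimum-cost 26-connected voxel path between two world points.

    Edge weight is the mean of the endpoint voxel costs (plus a small
    per-mm length penalty) times the Euclidean step length; the optimum is
    found by Dijkstra restricted to admissible voxels, then converted to
    world mm, resampled at 1 mm and smoothed.
    """
    start_idx = np.rint(volume.world_to_voxel(start_mm)).astype(int)
    end_idx = np.rint(volume.world_to_voxel(end_mm)).astype(int)
    for name, idx in (("start", start_idx), ("end", end_idx)):
        if not volume.contains_voxel(idx):
            raise ValueError(f"{name} point is outside the volume")
    if np.array_equal(start_idx, end_idx):
        raise ExtractionFailure("start and end map to the same voxel (degenerate path)")

    cost = voxel_cost(volume.voxels, model)
    ceiling = _admissible_cost_ceiling(ceiling_sigma)
    admissible = cost <= ceiling

    def snap(idx, name):
        # noise can push the single seed voxel past the ceiling; snap to the
        # nearest admissible voxel in a 2-voxel neighbourhood before failing
        if admissible[idx[2], idx[1], idx[0]]:
            return idx
        nx_, ny_, nz_ = volume.shape_xyz
        best, best_d = None, np.inf
        for dz in range(-2, 3):
            for dy in range(-2, 3):
                for dx in range(-2, 3):
                    c = idx + np.array([dx, dy, dz])
                    if not (0 <= c[0] < nx_ and 0 <= c[1] < ny_ and 0 <= c[2] < nz_):
                        continue
                    if admissible[c[2], c[1], c[0]]:
                        d = float(np.linalg.norm(
                            np.array([dx, dy, dz]) * volume.spacing))
                        if d < best_d:
                            best, best_d = c, d
        if best is None:
            raise ExtractionFailure(
                f"{name} voxel intensity is outside the admissible lumen range"
            )
        return best

    start_idx = snap(start_idx, "start")
    end_idx = snap(end_idx, "end")

    # Work inside the admissible bounding box to keep the graph small.
    zs, ys, xs = np.nonzero(admissible)
    lo = np.array([zs.min(), ys.min(), xs.min()])
    hi = np.array([zs.max(), ys.max(), xs.max()]) + 1
    adm = admissible[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    cst = (cost[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] + length_penalty).astype(np.float64)
    shape = adm.shape
    n = int(np.prod(shape))

    sp_zyx = volume.spacing[::-1]
    rows, cols, data = [], [], []
    for dz, dy, dx in _neighbor_offsets():
        step = float(np.linalg.norm(np.array([dz, dy, dx]) * sp_zyx))
        a = adm[max(dz, 0):shape[0] + min(dz, 0),
                max(dy, 0):shape[1] + min(dy, 0),
                max(dx, 0):shape[2] + min(dx, 0)]
        b = adm[max(-dz, 0):shape[0] + min(-dz, 0),
                max(-dy, 0):shape[1] + min(-dy, 0),
                max(-dx, 0):shape[2] + min(-dx, 0)]
        both = a & b
        zz, yy, xx = np.nonzero(both)
        za, ya, xa = zz + max(dz, 0), yy + max(dy, 0), xx + max(dx, 0)
        zb, yb, xb = za - dz, ya - dy, xa - dx
        ia = np.ravel_multi_index((za, ya, xa), shape)
        ib = np.ravel_multi_index((zb, yb, xb), shape)
        w = 0.5 * (cst[za, ya, xa] + cst[zb, yb, xb]) * step
        rows.append(ia)
        cols.append(ib)
        data.append(w)
    graph = coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    s_flat = int(np.ravel_multi_index(
        (start_idx[2] - lo[0], start_idx[1] - lo[1], start_idx[0] - lo[2]), shape))
    e_flat = int(np.ravel_multi_index(
        (end_idx[2] - lo[0], end_idx[1] - lo[1], end_idx[0] - lo[2]), shape))
    dist, pred = csgraph_dijkstra(
        graph, directed=False, indices=s_flat, return_predecessors=True
    )
    if not np.isfinite(dist[e_flat]):
        raise ExtractionFailure(
            "no admissible path between the endpoints; the lumen is not "
            "connected at the chosen admissibility ceiling"
        )

    chain = [e_flat]
    while chain[-1] != s_flat:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    zyx = np.column_stack(np.unravel_index(np.asarray(chain), shape)) + lo
    idx_xyz = zyx[:, ::-1].astype(float)
    points = volume.voxel_to_world(idx_xyz)
    result = Centerline(points).resampled()
    if return_cost:
        return result, float(dist[e_flat])
    return result


def shortest_path_cost(
    volume: ImageVolume,
    model: LumenIntensityModel,
    start_mm,
    end_mm,
    ceiling_sigma: float = ADMISSIBLE_SIGMA,
    length_penalty: float = LENGTH_PENALTY,
) -> float:
    """Total cost of the optimal path (for validation against oracles).

    Uses an independent textbook heap Dijkstra over the full grid; intended
    for tiny volumes only.
    """
    cost = np.asarray(voxel_cost(volume.voxels, model), dtype=float) + length_penalty
    ceiling = _admissible_cost_ceiling(ceiling_sigma) + length_penalty
    start = tuple(np.rint(volume.world_to_voxel(start_mm)).astype(int)[::-1])
    end = tuple(np.rint(volume.world_to_voxel(end_mm)).astype(int)[::-1])
    sp = volume.spacing[::-1]
    shape = cost.shape
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) != (0, 0, 0):
                    offs.append(((dz, dy, dx),
                                 float(np.linalg.norm(np.array([dz, dy, dx]) * sp))))
    dist = {start: 0.0}
    heap = [(0.0, start)]
    seen = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        if u == end:
            return d
        for off, step in offs:
            v = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
            if not all(0 <= v[k] < shape[k] for k in range(3)):
                continue
            if cost[v] > ceiling:
                continue
            nd = d + 0.5 * (cost[u] + cost[v]) * step
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    raise ExtractionFailure("no admissible path between the endpoints")


def _orthonormal_frame(tangent):
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(t @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def recenter(
    centerline: Centerline,
    volume: ImageVolume,
    model: LumenIntensityModel,
    search_radius: float = 25.0,
    grid_step: float = 1.0,
    passes: int = 4,
    node_step: float = 4.0,
    ceiling_sigma: float = ADMISSIBLE_SIGMA,
) -> Centerline:
    """Move each point to the likelihood-weighted centroid of its normal plane.

    Shortest paths cut corners; one or more centroid passes restore the
    medial position. The passes operate on nodes spaced ``node_step`` mm
    apart (stable tangents; no jitter feedback between passes); the result
    is resampled at 1 mm. The two endpoints are pinned — they come from
    endpoint detection or manual seeds, and the half-covered discs at the
    tube ends would otherwise erode them inward. Points whose normal-plane
    disc contains no admissible voxel are left unchanged (with a warning).
    """
    ceiling = _admissible_cost_ceiling(ceiling_sigma)
    a = np.arange(-search_radius, search_radius + 1e-9, grid_step)
    aa, bb = np.meshgrid(a, a, indexing="ij")
    in_disc = aa ** 2 + bb ** 2 <= search_radius ** 2
    offsets_2d = np.column_stack([aa[in_disc], bb[in_disc]])

    current = centerline.resampled(step=node_step, smooth_window=3)
    for _ in range(passes):
        pts = current.points.copy()
        n_empty = 0
        for i in range(1, len(pts) - 1):
            u, v = _orthonormal_frame(current.tangents[i])
            samples = pts[i] + offsets_2d[:, :1] * u + offsets_2d[:, 1:] * v
            vals = volume.sample_world(samples, background=model.mean + 100 * model.std)
            c = voxel_cost(vals, model)
            ok = c <= ceiling
            if not np.any(ok):
                n_empty += 1
                continue
            w = np.exp(-c[ok])
            pts[i] = (samples[ok] * w[:, None]).sum(axis=0) / w.sum()
        if n_empty:
            log.warning("recenter: %d points had no admissible plane voxels", n_empty)
        current = Centerline(pts).resampled(step=node_step, smooth_window=3)
    return current.resampled(step=RESAMPLE_STEP_MM, smooth_window=SMOOTH_WINDOW)


def detect_endpoints(
    volume: ImageVolume,
    model: LumenIntensityModel,
    ceiling_sigma: float = ADMISSIBLE_SIGMA,
    min_equiv_radius: float = 5.0,
    separation_mm: float = 20.0,
):
    """Best-effort automatic detection of descending and aortic-root endpoints.

    On a volume cropped to the thoracic aorta the candy-cane lumen shows, on
    caudal slices, one admissible cross-section (descending aorta) and,
    higher up, a second one (the aortic root / ascending aorta). Scanning
    caudally to cranially: the descending endpoint is the centroid of the
    largest admissible 2-D component on the most caudal slice; the root
    endpoint is the centroid of the largest *new* component on the first
    slice where a second, well-separated component appears.

    Returns ``(root_point_mm, descending_point_mm)``. Both are best-effort:
    callers may always override with manual seeds.
    """
    cost = voxel_cost(volume.voxels, model)
    admissible = cost <= _admissible_cost_ceiling(ceiling_sigma)
    nz = volume.voxels.shape[0]
    # caudal == decreasing world z (LPS superior axis)
    z_axis_world = volume.direction[:, 2]
    z_order = range(nz) if z_axis_world[2] >= 0 else range(nz - 1, -1, -1)
    structure = np.ones((3, 3), dtype=bool)
    vox_area = volume.spacing[0] * volume.spacing[1]
    min_area_vox = np.pi * min_equiv_radius ** 2 / vox_area

    def slice_components(z):
        lab, nlab = ndimage.label(admissible[z], structure=structure)
        comps = []
        for k in range(1, nlab + 1):
            ys, xs = np.nonzero(lab == k)
            if len(xs) < min_area_vox:
                continue
            cx, cy = xs.mean(), ys.mean()
            r_equiv = np.sqrt(len(xs) * vox_area / np.pi)
            comps.append((volume.voxel_to_world((cx, cy, float(z))), r_equiv))
        return comps

    desc_endpoint = None  # first (most caudal) detection is the endpoint
    track = None          # tracked descending centroid for association
    for z in z_order:
        comps = slice_components(z)
        if not comps:
            if desc_endpoint is None:
                continue
            break
        if desc_endpoint is None:
            desc_endpoint = max(comps, key=lambda c: c[1])[0]
            track = desc_endpoint
            continue
        dists = [np.linalg.norm(p[:2] - track[:2]) for p, _ in comps]
        near = int(np.argmin(dists))
        newcomers = [
            (p, r) for j, (p, r) in enumerate(comps)
            if j != near and np.linalg.norm(p[:2] - track[:2]) > separation_mm
        ]
        if newcomers:
            root_point = max(newcomers, key=lambda c: c[1])[0]
            return root_point, desc_endpoint
        track = comps[near][0]
    raise EndpointDetectionError(
        "could not locate two admissible aortic cross-sections; supply manual seeds"
    )
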