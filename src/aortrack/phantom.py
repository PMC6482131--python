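"""Synthetic aortic CTA phantom with exact ground truth.

Generates a candy-cane-shaped, contrast-filled lumen (bright tube), a darker
2 mm wall shell, optional bone-like spherical distractors and optional
supra-aortic branch tubes, then applies partial-volume Gaussian blur and
additive Gaussian noise. The follow-up twin applies a known radius-dilation
profile and a known rigid/affine transform to the whole scene, so every test
in the repository has analytic truth for the centerline, the radius profile,
the seven landmark positions and the applied motion.

Default geometry and intensities emulate a typical thoracic CTA contrast
regime: lumen 300 HU, wall 60 HU, background 20 HU, bone 700 HU, blur sigma
0.6 mm, noise sigma 10 HU. Default lumen radii at the seven landmarks track
typical adult thoracic-aorta calibers (diameters ~37 mm at the sinotubular
junction tapering to ~24 mm at the diaphragm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .centerline import Centerline
from .errors import GeometryError
from .image_model import ImageVolume
from .transforms import AffineTransform

#: fixed anatomical vocabulary, in anatomical order along the aorta.
LANDMARK_NAMES = ("STJ", "MAA", "PROX", "MID_ARCH", "DIST", "DESC", "DIAPHRAGM")

#: default landmark positions as fractions of total centerline arc length
#: (sinotubular junction near the root end, diaphragm near the caudal end of
#: the descending limb).
LANDMARK_FRACTIONS = {
    "STJ": 0.05,
    "MAA": 0.15,
    "PROX": 0.25,
    "MID_ARCH": 0.43,
    "DIST": 0.68,
    "DESC": 0.80,
    "DIAPHRAGM": 0.94,
}

#: default lumen radius (mm) at each landmark fraction; piecewise-linear in
#: between. Chosen to mimic adult thoracic aorta calibers.
DEFAULT_RADIUS_KNOTS = (
    (0.00, 17.5),
    (0.05, 18.5),   # STJ
    (0.15, 22.0),   # MAA
    (0.25, 18.5),   # PROX
    (0.43, 14.5),   # MID_ARCH
    (0.68, 13.5),   # DIST
    (0.80, 13.0),   # DESC
    (0.94, 12.0),   # DIAPHRAGM
    (1.00, 12.0),
)

WALL_THICKNESS_MM = 2.0


# -- specification types -------------------------------------------------------


@dataclass
class AortaPhantomSpec:
    """Geometry, intensities and noise of the synthetic aorta.

    ``radius_knots`` are ``(arc fraction in [0, 1], radius mm)`` pairs,
    interpolated linearly in arc length. ``curve_points`` overrides the
    candy-cane path with an explicit polyline (used e.g. for straight-tube
    fixtures); otherwise the path is two vertical limbs joined by a
    semicircular arch of ``arch_radius``.
    """

    ascending_length: float = 60.0
    arch_radius: float = 35.0
    descending_length: float = 95.0
    radius_knots: Sequence[tuple[float, float]] = DEFAULT_RADIUS_KNOTS
    curve_points: np.ndarray | None = None
    lumen_hu: float = 300.0
    wall_hu: float = 60.0
    background_hu: float = 20.0
    distractors: Sequence[tuple[Sequence[float], float, float]] | None = None
    branches: bool = False
    branch_radius: float = 5.0
    branch_length: float = 30.0
    blur_sigma: float = 0.6
    noise_sigma: float = 10.0
    texture_sigma: float = 80.0    # HU; soft-tissue heterogeneity amplitude
    texture_scale: float = 3.0     # mm; correlation length of the texture
    seed: int = 0

    def __post_init__(self):
        radii = np.asarray([r for _, r in self.radius_knots], dtype=float)
        if np.any(radii <= 0):
            raise ValueError("radius profile must be strictly positive")
        if self.lumen_hu <= self.background_hu:
            raise ValueError("lumen intensity must exceed background intensity")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur and noise sigmas must be nonnegative")
        if self.distractors is None:
            self.distractors = (
                self._default_mediastinum() if self.curve_points is None else ()
            )

    def _default_mediastinum(self):
        """Rigid mediastinal context: a vertebral column posterior to the
        descending limb, a sternum-like column anterior to the ascending
        limb (bright bone the adaptive threshold must suppress), and a
        trachea-like air column between the limbs. This is the anatomy that
        anchors intensity-based registration in real CTA — without it an
        affine transform could absorb part of a diffuse dilation as scale."""
        la, R, ld = self.ascending_length, self.arch_radius, self.descending_length
        z_lo, z_hi = la - ld + 10.0, la + R
        spine = tuple(
            ((2.0 * R, 36.0, z), 12.0, 700.0)
            for z in np.arange(z_lo, z_hi + 1e-9, 26.0)
        )
        sternum = tuple(
            ((5.0, -42.0, z), 8.0, 650.0)
            for z in np.arange(-10.0, la + R + 1e-9, 26.0)
        )
        trachea = tuple(
            ((1.2 * R, 20.0, z), 7.0, -950.0)
            for z in np.arange(-25.0, la + 16.0, 7.0)
        )
        return spine + sternum + trachea

    # -- analytic path -----------------------------------------------------

    def curve(self, step: float = 0.25) -> np.ndarray:
        """Densely sampled path points (mm), root end first."""
        if self.curve_points is not None:
            pts = np.asarray(self.curve_points, dtype=float)
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            n = max(int(round(s[-1] / step)) + 1, 2)
            si = np.linspace(0.0, s[-1], n)
            return np.stack([np.interp(si, s, pts[:, k]) for k in range(3)], axis=1)
        la, R, ld = self.ascending_length, self.arch_radius, self.descending_length
        # ascending limb: straight up from the aortic root
        n_a = max(int(round(la / step)), 2)
        t = np.linspace(0.0, la, n_a, endpoint=False)
        asc = np.stack([np.zeros_like(t), np.zeros_like(t), t], axis=1)
        # arch: semicircle in the x-z plane bulging cranially
        n_arc = max(int(round(np.pi * R / step)), 4)
        theta = np.linspace(np.pi, 0.0, n_arc, endpoint=False)
        arch = np.stack(
            [R + R * np.cos(theta), np.zeros_like(theta), la + R * np.sin(theta)],
            axis=1,
        )
        # descending limb: straight down, extending caudal to the root level
        n_d = max(int(round(ld / step)), 2)
        t = np.linspace(0.0, ld, n_d)
        desc = np.stack([np.full_like(t, 2 * R), np.zeros_like(t), la - t], axis=1)
        return np.concatenate([asc, arch, desc], axis=0)

    def radius_profile(self, total_length: float) -> Callable[[np.ndarray], np.ndarray]:
        fr = np.asarray([f for f, _ in self.radius_knots], dtype=float)
        rr = np.asarray([r for _, r in self.radius_knots], dtype=float)

        def radius_at(s):
            return np.interp(np.asarray(s, dtype=float), fr * total_length, rr)

        return radius_at


@dataclass(frozen=True)
class GridSpec:
    """Output grid geometry: shape in ``(nx, ny, nz)``, isotropic axes in LPS."""

    shape_xyz: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @staticmethod
    def fit(spec: AortaPhantomSpec, spacing: float = 1.0, margin: float = 12.0) -> "GridSpec":
        """Grid that encloses the tube (plus wall and distractors) with margin."""
        pts = spec.curve()
        rmax = max(r for _, r in spec.radius_knots) + WALL_THICKNESS_MM
        extra = margin + rmax + (spec.branch_length if spec.branches else 0.0)
        lo = pts.min(axis=0) - extra
        hi = pts.max(axis=0) + extra
        for center, r, _ in spec.distractors:
            c = np.asarray(center, dtype=float)
            lo = np.minimum(lo, c - r - margin)
            hi = np.maximum(hi, c + r + margin)
        shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
        return GridSpec(shape, (spacing,) * 3, tuple(lo))

    def empty_volume(self, fill: float = 0.0) -> ImageVolume:
        nx, ny, nz = self.shape_xyz
        return ImageVolume(
            voxels=np.full((nz, ny, nx), fill, dtype=np.float32),
            spacing=np.asarray(self.spacing),
            origin=np.asarray(self.origin),
        )


@dataclass
class PhantomGroundTruth:
    """Exact truth for a generated phantom."""

    centerline: Centerline
    radius_at: Callable[[np.ndarray], np.ndarray]
    landmarks: dict  # name -> {"arc_length": s, "point": (3,) world mm}
    applied_transform: AffineTransform | None = None
    dilation_at: Callable[[np.ndarray], np.ndarray] | None = None

    def landmark_points(self) -> dict:
        return {k: np.asarray(v["point"]) for k, v in self.landmarks.items()}

    def diameter_at(self, s) -> np.ndarray:
        d = 2.0 * self.radius_at(s)
        if self.dilation_at is not None:
            d = d + 2.0 * self.dilation_at(s)
        return d


# -- dilation profiles -----------------------------------------------------------


def uniform_dilation(amount_mm: float) -> Callable[[np.ndarray], np.ndarray]:
    """Constant radius increment along the whole aorta."""

    def dilation(s):
        return np.full_like(np.asarray(s, dtype=float), float(amount_mm))

    return dilation


def localized_dilation(center_s: float, span_mm: float, amount_mm: float,
                       ramp_mm: float = 10.0) -> Callable[[np.ndarray], np.ndarray]:
    """Trapezoidal radius increment: full ``amount_mm`` over ``span_mm`` of
    arc centered at ``center_s``, with linear ramps of ``ramp_mm`` on each side."""

    half = span_mm / 2.0

    def dilation(s):
        d = np.abs(np.asarray(s, dtype=float) - center_s)
        w = np.clip((half + ramp_mm - d) / ramp_mm, 0.0, 1.0)
        return float(amount_mm) * w

    return dilation


# -- rasterization ----------------------------------------------------------------


def _branch_curves(spec: AortaPhantomSpec, curve: np.ndarray, arc: np.ndarray):
    """Three thin vertical tubes leaving the upper arch (brachiocephalic,
    left carotid, left subclavian stand-ins)."""
    total = arc[-1]
    curves = []
    for frac in (0.36, 0.42, 0.48):
        base = curve[np.searchsorted(arc, frac * total)]
        top = base + np.array([0.0, 0.0, spec.branch_length])
        t = np.linspace(0.0, 1.0, max(int(spec.branch_length / 0.5), 2))
        curves.append(base[None, :] + t[:, None] * (top - base)[None, :])
    return curves


def _check_margin(points: np.ndarray, radii, grid: GridSpec, margin: float = 5.0):
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape_xyz) - 1) * np.asarray(grid.spacing)
    rmax = np.max(radii) + WALL_THICKNESS_MM
    if np.any(points.min(axis=0) - rmax < lo + margin) or np.any(
        points.max(axis=0) + rmax > hi - margin
    ):
        raise GeometryError(
            f"tube (max outer radius {rmax:.1f} mm) does not fit inside the "
            f"grid with a {margin:.0f} mm margin"
        )


def _rasterize(
    spec: AortaPhantomSpec,
    grid: GridSpec,
    radius_fn: Callable,
    world_to_scene: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
) -> ImageVolume:
    """Paint the scene. ``world_to_scene`` maps grid world coordinates into the
    (baseline) scene frame where the analytic tube lives."""
    vol = grid.empty_volume(fill=spec.background_hu)
    nx, ny, nz = grid.shape_xyz
    curve = spec.curve()
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    radii_all = radius_fn(arc)

    # candidate voxels: those within (max radius + wall + blur support) of the tube
    rmax = float(np.max(radii_all)) + WALL_THICKNESS_MM + 3.0 * spec.blur_sigma + 1.0
    xs = np.arange(nx) * grid.spacing[0] + grid.origin[0]
    ys = np.arange(ny) * grid.spacing[1] + grid.origin[1]
    zs = np.arange(nz) * grid.spacing[2] + grid.origin[2]
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    world = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    scene = world_to_scene(world)

    # background soft-tissue texture: a fixed smooth random field evaluated
    # in *scene* coordinates, so it is rigid anatomy that moves with the
    # applied transform (seeded by spec.seed, shared by baseline/follow-up)
    if spec.texture_sigma > 0:
        from scipy.ndimage import map_coordinates

        rng_tex = np.random.default_rng([spec.seed, 0x7E2])
        pad = 40.0
        lat_origin = np.asarray(grid.origin) - pad
        extent = (np.asarray(grid.shape_xyz) - 1) * np.asarray(grid.spacing) + 2 * pad
        lat_shape = (np.ceil(extent / spec.texture_scale).astype(int) + 2)[::-1]
        lat = rng_tex.normal(0.0, 1.0, lat_shape)
        lat = ndimage.gaussian_filter(lat, 1.0)
        lat *= spec.texture_sigma / max(lat.std(), 1e-9)
        coords = ((scene - lat_origin) / spec.texture_scale)[:, ::-1].T
        flat_tex = map_coordinates(lat, coords, order=1, mode="nearest")
        vol.voxels = (vol.voxels.reshape(-1) + flat_tex).reshape(vol.voxels.shape)
        vol.voxels = vol.voxels.astype(np.float32)

    tree = cKDTree(curve)
    # coarse pre-filter on the tube's bounding box to limit the KD query
    lo_b = curve.min(axis=0) - rmax
    hi_b = curve.max(axis=0) + rmax
    cand = np.all((scene >= lo_b) & (scene <= hi_b), axis=1)
    dist = np.full(len(scene), np.inf)
    idx = np.zeros(len(scene), dtype=int)
    if np.any(cand):
        d, i = tree.query(scene[cand], distance_upper_bound=rmax)
        dist[cand] = d
        idx[cand] = np.where(np.isfinite(d), i, 0)

    r_here = radius_fn(arc[np.minimum(idx, len(arc) - 1)])
    # flat tube ends: cut by the end-tangent planes, like a vessel truncated
    # by the scan's field-of-view crop
    t0 = curve[1] - curve[0]
    t0 /= np.linalg.norm(t0)
    t1 = curve[-1] - curve[-2]
    t1 /= np.linalg.norm(t1)
    end_zone = 2.0 * float(np.max(radii_all)) + WALL_THICKNESS_MM
    s_near = arc[np.minimum(idx, len(arc) - 1)]
    cut_start = (s_near < end_zone) & ((scene - curve[0]) @ t0 < 0.0)
    cut_end = (s_near > arc[-1] - end_zone) & ((scene - curve[-1]) @ t1 > 0.0)
    in_span = ~cut_start & ~cut_end
    flat = vol.voxels.reshape(-1)
    wall_mask = (dist <= r_here + WALL_THICKNESS_MM) & in_span
    flat[wall_mask] = spec.wall_hu
    lumen_mask = (dist <= r_here) & in_span
    flat[lumen_mask] = spec.lumen_hu

    if spec.branches:
        for bc in _branch_curves(spec, curve, arc):
            btree = cKDTree(bc)
            bb = np.all(
                (scene >= bc.min(axis=0) - spec.branch_radius - 3)
                & (scene <= bc.max(axis=0) + spec.branch_radius + 3),
                axis=1,
            )
            if np.any(bb):
                bd, _ = btree.query(scene[bb], distance_upper_bound=spec.branch_radius + 3)
                sel = np.where(bb)[0]
                flat[sel[bd <= spec.branch_radius + WALL_THICKNESS_MM]] = np.maximum(
                    flat[sel[bd <= spec.branch_radius + WALL_THICKNESS_MM]], spec.wall_hu
                )
                flat[sel[bd <= spec.branch_radius]] = spec.lumen_hu

    for center, radius, hu in spec.distractors:
        c = np.asarray(center, dtype=float)
        d2 = np.sum((scene - c) ** 2, axis=1)
        flat[d2 <= radius ** 2] = hu

    vol.voxels = flat.reshape(vol.voxels.shape)
    if spec.blur_sigma > 0:
        sig_vox = spec.blur_sigma / np.asarray(grid.spacing)[::-1]
        vol.voxels = ndimage.gaussian_filter(vol.voxels, sigma=sig_vox).astype(np.float32)
    if spec.noise_sigma > 0:
        vol.voxels = (
            vol.voxels + rng.normal(0.0, spec.noise_sigma, vol.voxels.shape)
        ).astype(np.float32)
    return vol


def _ground_truth(spec: AortaPhantomSpec, transform: AffineTransform | None,
                  dilation: Callable | None) -> PhantomGroundTruth:
    curve = spec.curve(step=0.5)
    cl = Centerline(curve)
    total = cl.total_length
    radius_at = spec.radius_profile(total)
    landmarks = {}
    for name, frac in LANDMARK_FRACTIONS.items():
        s = frac * total
        p = cl.point_at(s)
        if transform is not None:
            p = transform.apply(p)
        landmarks[name] = {"arc_length": float(s), "point": np.asarray(p).reshape(3)}
    if transform is not None:
        cl = Centerline(transform.apply(cl.points))
    return PhantomGroundTruth(
        centerline=cl,
        radius_at=radius_at,
        landmarks=landmarks,
        applied_transform=transform,
        dilation_at=dilation,
    )


# -- public operations -------------------------------------------------------------


def generate_baseline(spec: AortaPhantomSpec, grid: GridSpec):
    """Rasterize the baseline phantom; returns ``(ImageVolume, PhantomGroundTruth)``."""
    curve = spec.curve(step=0.5)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    radius_fn = spec.radius_profile(arc[-1])
    _check_margin(curve, radius_fn(arc), grid)
    rng = np.random.default_rng(spec.seed)
    vol = _rasterize(spec, grid, radius_fn, lambda p: p, rng)
    return vol, _ground_truth(spec, None, None)


def generate_followup(
    spec: AortaPhantomSpec,
    dilation: Callable[[np.ndarray], np.ndarray] | None,
    transform: AffineTransform | None,
    noise_seed: int | None = None,
    grid: GridSpec | None = None,
):
    """Rasterize the follow-up twin: dilated radii, whole scene mapped by
    ``transform`` before rasterization; ground-truth landmarks mapped too.

    With zero dilation, identity transform and ``noise_seed == spec.seed``
    the output is bit-identical to the baseline.
    """
    if grid is None:
        grid = GridSpec.fit(spec)
    curve = spec.curve(step=0.5)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    base_radius = spec.radius_profile(arc[-1])

    if dilation is None:
        dilation_fn = None

        def radius_fn(s):
            return base_radius(s)
    else:
        dilation_fn = dilation
        d = np.asarray(dilation(arc), dtype=float)
        if np.any(d < -1e-12):
            raise ValueError("dilation profile must be nonnegative")

        def radius_fn(s):
            return base_radius(s) + dilation(s)

    tf = transform
    if tf is None:
        tf = AffineTransform.identity()
    inv = tf.inverse()

    mapped_curve = tf.apply(curve)
    _check_margin(mapped_curve, radius_fn(arc), grid)

    rng = np.random.default_rng(spec.seed if noise_seed is None else noise_seed)
    vol = _rasterize(spec, grid, radius_fn, inv.apply, rng)
    truth = _ground_truth(spec, None if transform is None else tf, dilation_fn)
    return vol, truth
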