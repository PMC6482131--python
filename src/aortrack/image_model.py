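"""Volume data model, world/voxel geometry, file I/O and z-cropping.

The in-memory container is :class:`ImageVolume`: a regular 3-D scalar grid of
Hounsfield units with spacing, origin and a 3x3 orthonormal direction matrix
defining an LPS (left-posterior-superior, DICOM convention) world frame.
NIfTI files, which are RAS-native, are converted to LPS on read (SimpleITK
does this conversion internally).

Voxel indices are 0-based ``(x, y, z)`` triples, x fastest-varying as stored;
the numpy array is kept in ``[z, y, x]`` axis order so that
``voxels[z, y, x]`` addresses voxel ``(x, y, z)``. All index ranges are
half-open. Intensities are stored as float32 HU regardless of on-disk type.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import AmbiguousSeriesError, FormatError, GeometryError
from .transforms import AffineTransform

_VOLUME_EXTENSIONS = (".mhd", ".mha", ".nii", ".nii.gz")


def _matched_extension(path: str) -> str | None:
    low = str(path).lower()
    for ext in (".nii.gz",) + _VOLUME_EXTENSIONS:
        if low.endswith(ext):
            return ext
    return None


@dataclass
class ImageVolume:
    """A 3-D CT(A) volume in a world coordinate frame.

    Parameters
    ----------
    voxels
        Scalar grid, shape ``(nz, ny, nx)``, float32 HU.
    spacing
        Per-axis voxel size in mm, ``(sx, sy, sz)``, all > 0.
    origin
        World coordinates (mm, LPS) of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal matrix; column j is the world direction of voxel
        axis j (x, y, z).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-6):
            raise GeometryError("direction matrix must be orthonormal (1e-6)")

    # -- geometry -----------------------------------------------------------

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.voxels.shape
        return (nx, ny, nz)

    @property
    def size(self) -> int:
        return int(self.voxels.size)

    def voxel_to_world(self, index_xyz) -> np.ndarray:
        """Map (continuous) voxel indices ``(x, y, z)`` to world mm."""
        idx = np.asarray(index_xyz, dtype=float)
        return (idx * self.spacing) @ self.direction.T + self.origin

    def world_to_voxel(self, point_mm) -> np.ndarray:
        """Map world mm points to continuous voxel indices ``(x, y, z)``."""
        p = np.asarray(point_mm, dtype=float)
        return ((p - self.origin) @ self.direction) / self.spacing

    def contains_voxel(self, index_xyz) -> bool:
        idx = np.asarray(index_xyz, dtype=float)
        nx, ny, nz = self.shape_xyz
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array([nx, ny, nz]) - 0.5))

    def contains_world(self, point_mm) -> bool:
        return self.contains_voxel(self.world_to_voxel(point_mm))

    def sample_world(self, points_mm, order: int = 1, background: float = 0.0) -> np.ndarray:
        """Trilinearly (order=1) or nearest (order=0) sample at world points."""
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = self.world_to_voxel(pts)  # (n, 3) xyz
        coords = idx[:, ::-1].T  # zyx for the array layout
        return map_coordinates(
            self.voxels, coords, order=order, mode="constant",
            cval=background, prefilter=False,
        )

    def copy_with(self, voxels=None, origin=None) -> "ImageVolume":
        return ImageVolume(
            voxels=self.voxels.copy() if voxels is None else voxels,
            spacing=self.spacing.copy(),
            origin=self.origin.copy() if origin is None else origin,
            direction=self.direction.copy(),
        )


@dataclass(frozen=True)
class VoxelRegion:
    """Half-open axis-aligned index box: ``lower`` inclusive, ``upper`` exclusive."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=int)
        hi = np.asarray(self.upper, dtype=int)
        if np.any(lo >= hi):
            raise GeometryError(f"empty region: lower={self.lower} upper={self.upper}")

    def clipped(self, shape_xyz) -> "VoxelRegion":
        lo = np.maximum(np.asarray(self.lower), 0)
        hi = np.minimum(np.asarray(self.upper), np.asarray(shape_xyz))
        return VoxelRegion(tuple(int(v) for v in lo), tuple(int(v) for v in hi))

    def to_mask(self, shape_xyz) -> np.ndarray:
        """Binary mask in array ``[z, y, x]`` layout."""
        nx, ny, nz = shape_xyz
        m = np.zeros((nz, ny, nx), dtype=bool)
        (x0, y0, z0), (x1, y1, z1) = self.lower, self.upper
        m[z0:z1, y0:y1, x0:x1] = True
        return m

    @staticmethod
    def from_mask(mask_zyx: np.ndarray) -> "VoxelRegion":
        nz_idx = np.nonzero(mask_zyx)
        if len(nz_idx[0]) == 0:
            raise GeometryError("empty mask has no bounding region")
        z, y, x = nz_idx
        return VoxelRegion(
            (int(x.min()), int(y.min()), int(z.min())),
            (int(x.max()) + 1, int(y.max()) + 1, int(z.max()) + 1),
        )


# -- SimpleITK conversion -----------------------------------------------------


def _from_sitk(img: sitk.Image) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).astype(np.float32)  # (z, y, x)
    if arr.ndim == 4:  # single-component vector image edge case
        arr = arr[..., 0]
    return ImageVolume(
        voxels=arr,
        spacing=np.asarray(img.GetSpacing()),
        origin=np.asarray(img.GetOrigin()),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
    )


def _to_sitk(volume: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(volume.voxels)
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.direction.ravel()))
    return img


# -- operations ---------------------------------------------------------------


def read_volume(path) -> ImageVolume:
    """Read a MetaImage / NIfTI file or a single-series DICOM directory.

    DICOM slices are sorted along the slice normal and rescale
    slope/intercept are applied, so intensities come back in HU.
    """
    path = str(path)
    if os.path.isdir(path):
        reader = sitk.ImageSeriesReader()
        series = reader.GetGDCMSeriesIDs(path)
        if len(series) == 0:
            raise FormatError(f"no DICOM series found in directory {path!r}")
        if len(series) > 1:
            raise AmbiguousSeriesError(series)
        reader.SetFileNames(reader.GetGDCMSeriesFileNames(path, series[0]))
        return _from_sitk(reader.Execute())
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path!r}")
    if _matched_extension(path) is None:
        raise FormatError(
            f"unsupported volume format {path!r}; expected one of {_VOLUME_EXTENSIONS}"
        )
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise FormatError(f"could not read volume {path!r}: {exc}") from exc
    return _from_sitk(img)


def write_volume(volume: ImageVolume, path) -> None:
    """Write to .mhd/.mha or .nii/.nii.gz; readable back losslessly."""
    path = str(path)
    if _matched_extension(path) is None:
        raise FormatError(
            f"unsupported output extension for {path!r}; expected one of "
            f"{_VOLUME_EXTENSIONS}"
        )
    try:
        sitk.WriteImage(_to_sitk(volume), path)
    except RuntimeError as exc:
        raise OSError(f"could not write volume to {path!r}: {exc}") from exc


def crop_z(volume: ImageVolume, z_lo: int, z_hi: int) -> ImageVolume:
    """Keep slices ``[z_lo, z_hi)``; world positions of kept voxels unchanged."""
    n = volume.voxels.shape[0]
    if not (0 <= z_lo < z_hi <= n):
        raise ValueError(f"invalid z crop range [{z_lo}, {z_hi}) for {n} slices")
    new_origin = volume.voxel_to_world((0.0, 0.0, float(z_lo)))
    return volume.copy_with(
        voxels=volume.voxels[z_lo:z_hi].copy(), origin=new_origin
    )


def resample_to_reference(
    moving: ImageVolume,
    transform: AffineTransform,
    reference: ImageVolume,
    interpolation: str = "linear",
    background: float = -1024.0,
) -> ImageVolume:
    """Resample ``moving`` onto the grid of ``reference``.

    The output intensity at world point ``p`` (in the reference frame) is the
    moving image sampled at ``transform(p)``; points mapping outside the
    moving grid receive ``background``.
    """
    from scipy.ndimage import affine_transform as ndi_affine

    if abs(np.linalg.det(transform.matrix)) < 1e-12:
        raise ValueError("transform is singular and cannot be used for resampling")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0

    # Compose: reference voxel index (xyz) -> world -> transform -> moving index.
    A_ref = reference.direction @ np.diag(reference.spacing)
    A_mov_inv = np.diag(1.0 / moving.spacing) @ moving.direction.T
    T_lin, T_off = transform.matrix, transform.offset()
    M = A_mov_inv @ T_lin @ A_ref
    off = A_mov_inv @ (T_lin @ reference.origin + T_off - moving.origin)

    # Convert the xyz index map to the zyx array layout.
    P = np.eye(3)[::-1]
    M_zyx = P @ M @ P
    off_zyx = off[::-1]

    out = ndi_affine(
        moving.voxels, M_zyx, offset=off_zyx,
        output_shape=reference.voxels.shape, order=order,
        mode="constant", cval=background, prefilter=False,
    )
    return ImageVolume(
        voxels=out.astype(np.float32),
        spacing=reference.spacing.copy(),
        origin=reference.origin.copy(),
        direction=reference.direction.copy(),
    )
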