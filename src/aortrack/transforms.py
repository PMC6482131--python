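"""3-D affine and rigid transforms in world (LPS, mm) coordinates.

A transform maps a point ``p`` to ``A @ (p - c) + c + t`` where ``A`` is the
3x3 linear part, ``c`` the center of rotation and ``t`` the translation.
The rigid subtype constrains ``A`` to a proper rotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class AffineTransform:
    matrix: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine transform must be invertible")

    # -- algebra ------------------------------------------------------------

    def offset(self) -> np.ndarray:
        """Constant term so that ``p -> matrix @ p + offset``."""
        return self.center + self.translation - self.matrix @ self.center

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.matrix.T + self.offset()

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset(), np.zeros(3))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the transform ``p -> self(other(p))``."""
        return AffineTransform(
            self.matrix @ other.matrix,
            self.matrix @ other.offset() + self.offset(),
            np.zeros(3),
        )

    def is_rigid(self, tol: float = 1e-6) -> bool:
        ortho = np.allclose(self.matrix.T @ self.matrix, np.eye(3), atol=tol)
        return ortho and np.linalg.det(self.matrix) > 0

    # -- constructors -------------------------------------------------------

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.eye(3))

    @staticmethod
    def rigid_from_euler(angles_deg, translation, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        """Rotation about x, y then z axes (degrees) about ``center`` plus translation."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", np.asarray(angles_deg, dtype=float), degrees=True)
        return AffineTransform(R.as_matrix(), np.asarray(translation, dtype=float),
                               np.asarray(center, dtype=float))

    @staticmethod
    def scaling(factor: float, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return AffineTransform(np.eye(3) * float(factor), np.zeros(3),
                               np.asarray(center, dtype=float))

    # -- decomposition / metrics ---------------------------------------------

    def rotation_angle_deg(self) -> float:
        """Rotation angle of the orthogonal polar factor of the linear part."""
        U, _, Vt = np.linalg.svd(self.matrix)
        R = U @ Vt
        if np.linalg.det(R) < 0:  # reflection guard
            U[:, -1] *= -1
            R = U @ Vt
        c = (np.trace(R) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def scale_factors(self) -> np.ndarray:
        """Singular values of the linear part (1,1,1 for rigid)."""
        return np.linalg.svd(self.matrix, compute_uv=False)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
            "frame": "LPS",
            "units": "mm",
        }

    @staticmethod
    def from_dict(d: dict) -> "AffineTransform":
        return AffineTransform(
            np.asarray(d["matrix"], dtype=float),
            np.asarray(d.get("translation", [0, 0, 0]), dtype=float),
            np.asarray(d.get("center", [0, 0, 0]), dtype=float),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def load(path) -> "AffineTransform":
        with open(path) as fh:
            return AffineTransform.from_dict(json.load(fh))
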