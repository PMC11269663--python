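"""Projective transforms in pixel coordinates.

Convention: homogeneous points are (x, y, 1) with x = column and y = row,
matching :class:`skimage.transform.ProjectiveTransform`.  A transform maps
input-image coordinates to output-image coordinates (forward warp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class HomographyTransform:
    """3x3 projective map, normalized so the bottom-right entry is 1."""

    matrix: np.ndarray
    inlier_count: int | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InputError(f"homography must be 3x3, got {m.shape}")
        if abs(np.linalg.det(m)) < 1e-12:
            raise InputError("homography is singular")
        if abs(m[2, 2]) < 1e-12:
            raise InputError("cannot normalize: bottom-right entry is 0")
        self.matrix = m / m[2, 2]

    @classmethod
    def identity(cls) -> "HomographyTransform":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "HomographyTransform":
        m = np.eye(3)
        m[0, 2] = dx
        m[1, 2] = dy
        return cls(m)

    @classmethod
    def from_params(cls, rotation_deg: float = 0.0, dx: float = 0.0, dy: float = 0.0,
                    center: tuple[float, float] = (0.0, 0.0), scale: float = 1.0,
                    projective: tuple[float, float] = (0.0, 0.0)) -> "HomographyTransform":
        """Rotation (about ``center``) + scale + translation + mild projective terms."""
        t = np.deg2rad(rotation_deg)
        cx, cy = center
        rot = np.array([
            [scale * np.cos(t), -scale * np.sin(t), 0.0],
            [scale * np.sin(t), scale * np.cos(t), 0.0],
            [0.0, 0.0, 1.0],
        ])
        to_origin = cls.translation(-cx, -cy).matrix
        back = cls.translation(cx + dx, cy + dy).matrix
        m = back @ rot @ to_origin
        m[2, 0] = projective[0]
        m[2, 1] = projective[1]
        return cls(m)

    def inverse(self) -> "HomographyTransform":
        return HomographyTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "HomographyTransform") -> "HomographyTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return HomographyTransform(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=tol))

    def flat(self) -> np.ndarray:
        """Row-major 9-vector (h11..h33), for manifests."""
        return self.matrix.ravel().copy()
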