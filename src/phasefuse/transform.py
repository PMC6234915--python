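"""Homogeneous 2-D similarity/affine transforms.

The transform maps FLU pixel coordinates into VIS pixel coordinates. The
matrix acts on column vectors ``(x, y, 1)^T`` with ``x`` the column index and
``y`` the row index:

    [x']   [a  b  tx] [x]
    [y'] = [c  d  ty] [y]
    [1 ]   [0  0   1] [1]

For reporting, the classic row-vector component names are exposed as
properties: ``t11`` (diagonal, = a), ``t12`` (off-diagonal, = c) and the
translational components ``t31`` (= tx), ``t32`` (= ty). A positive rotation
angle turns the +x axis toward the +y axis, i.e. clockwise on screen with
rows increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import TransformError

_DET_TOL = 1e-9


@dataclass(frozen=True)
class AffineTransform2D:
    """3x3 homogeneous transform with a similarity decomposition."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise TransformError(f"matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise TransformError("matrix entries must be finite")
        if not np.allclose(m[2], (0.0, 0.0, 1.0), atol=1e-12):
            raise TransformError("bottom row must be (0, 0, 1)")
        m = m.copy()
        m[2] = (0.0, 0.0, 1.0)
        object.__setattr__(self, "matrix", m)

    # ---- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(3))

    @classmethod
    def from_params(
        cls,
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        shift_x: float = 0.0,
        shift_y: float = 0.0,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Similarity transform: rotate/scale about ``center`` then translate.

        ``p -> s R (p - c) + c + t`` with ``p = (x, y)``.
        """
        th = math.radians(rotation_deg)
        a = scale * math.cos(th)
        b = -scale * math.sin(th)
        cx, cy = center
        lin = np.array([[a, b], [-b, a]])
        t = np.array([cx + shift_x, cy + shift_y]) - lin @ np.array([cx, cy])
        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = t
        return cls(m)

    @classmethod
    def scaling(cls, factor: float) -> "AffineTransform2D":
        return cls(np.diag((factor, factor, 1.0)))

    @classmethod
    def translation(cls, shift_x: float, shift_y: float) -> "AffineTransform2D":
        m = np.eye(3)
        m[0, 2] = shift_x
        m[1, 2] = shift_y
        return cls(m)

    # ---- component access ---------------------------------------------
    @property
    def t11(self) -> float:
        return float(self.matrix[0, 0])

    @property
    def t12(self) -> float:
        return float(self.matrix[1, 0])

    @property
    def t31(self) -> float:
        return float(self.matrix[0, 2])

    @property
    def t32(self) -> float:
        return float(self.matrix[1, 2])

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix[:2, :2]))

    @property
    def scale(self) -> float:
        """Isotropic scale factor (sqrt of |det| of the linear part)."""
        return math.sqrt(abs(self.determinant))

    @property
    def rotation_deg(self) -> float:
        return math.degrees(math.atan2(self.matrix[1, 0], self.matrix[0, 0]))

    @property
    def shift_x(self) -> float:
        return self.t31

    @property
    def shift_y(self) -> float:
        return self.t32

    @property
    def is_invertible(self) -> bool:
        return abs(self.determinant) > _DET_TOL

    # ---- algebra -------------------------------------------------------
    def inverse(self) -> "AffineTransform2D":
        if not self.is_invertible:
            raise TransformError("transform is singular")
        return AffineTransform2D(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "AffineTransform2D") -> "AffineTransform2D":
        return AffineTransform2D(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` array of (x, y) points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out if np.asarray(points).ndim == 2 else out[0]

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "matrix": [float(v) for v in self.matrix.ravel()],
            "rotation_deg": self.rotation_deg,
            "scale": self.scale,
            "shift_x": self.shift_x,
            "shift_y": self.shift_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(np.asarray(d["matrix"], dtype=np.float64).reshape(3, 3))
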