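"""World-space spatial transforms (rigid, affine, displacement field, composed).

All transforms map world coordinates (RAS, mm) to world coordinates and expose
both a forward map (:meth:`SpatialTransform.apply`) and an inverse transform
(:meth:`SpatialTransform.inverse`).  Matrix transforms invert exactly;
displacement-style transforms invert numerically by fixed-point iteration to a
stated tolerance (default 1e-3 mm, 50 iterations), and non-convergence raises.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod

import numpy as np

__all__ = [
    "SpatialTransform",
    "RigidTransform",
    "AffineTransform",
    "DisplacementFieldTransform",
    "ComposedTransform",
    "FunctionDisplacementTransform",
    "InverseTransform",
    "transform_to_json",
    "transform_from_json",
]

#: tolerance (mm) for numerical inverses of displacement-style transforms
INVERSE_TOL_MM = 1e-3
INVERSE_MAX_ITER = 50


def _as_points(points) -> tuple[np.ndarray, bool]:
    """Coerce to an (N, 3) float array; report whether input was a single point."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ValueError(f"points must have 3 coordinates, got shape {pts.shape}")
    return pts, single


class SpatialTransform(ABC):
    """A world->world (mm) spatial map with a forward and an inverse."""

    kind: str

    @abstractmethod
    def apply(self, points):
        """Map world points (3,) or (N, 3) forward through the transform."""

    @abstractmethod
    def inverse(self) -> "SpatialTransform":
        """Return the inverse transform."""


class _MatrixTransform(SpatialTransform):
    """Shared behaviour for transforms representable as a 4x4 homogeneous matrix."""

    def __init__(self, matrix):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(matrix[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row of a homogeneous matrix must be [0, 0, 0, 1]")
        if abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
            raise ValueError("transform matrix is singular")
        self.matrix = matrix

    def apply(self, points):
        pts, single = _as_points(points)
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out

    def inverse(self):
        return type(self)(np.linalg.inv(self.matrix))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"{type(self).__name__}(matrix={self.matrix!r})"


class AffineTransform(_MatrixTransform):
    """General invertible affine world map."""

    kind = "affine"


class RigidTransform(_MatrixTransform):
    """Rotation (det +1) plus translation."""

    kind = "rigid"

    def __init__(self, matrix):
        super().__init__(matrix)
        R = self.matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rigid rotation block is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rigid rotation must have determinant +1 (no reflection)")

    @classmethod
    def from_rotation_translation(cls, rotation, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    def inverse(self):
        R = self.matrix[:3, :3]
        inv = np.eye(4)
        inv[:3, :3] = R.T
        inv[:3, 3] = -R.T @ self.matrix[:3, 3]
        return RigidTransform(inv)


class _DisplacementBase(SpatialTransform):
    """Forward map x -> x + d(x); inverse solved by fixed-point iteration."""

    tol_mm = INVERSE_TOL_MM
    max_iter = INVERSE_MAX_ITER

    @abstractmethod
    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Displacement d(x) in world mm at (N, 3) world points."""

    def apply(self, points):
        pts, single = _as_points(points)
        out = pts + self.displacement(pts)
        return out[0] if single else out

    def inverse(self):
        return InverseTransform(self)

    def solve_inverse_points(self, targets: np.ndarray) -> np.ndarray:
        """Solve y = x + d(x) for x given y, via x_{k+1} = y - d(x_k)."""
        y = np.atleast_2d(np.asarray(targets, dtype=float))
        x = y.copy()
        for _ in range(self.max_iter):
            x_new = y - self.displacement(x)
            step = np.max(np.linalg.norm(x_new - x, axis=-1)) if x.size else 0.0
            x = x_new
            if step < self.tol_mm:
                return x
        raise RuntimeError(
            f"displacement-field inverse did not converge to {self.tol_mm} mm "
            f"in {self.max_iter} iterations (last step {step:.3g} mm)"
        )


class DisplacementFieldTransform(_DisplacementBase):
    """Dense displacement field sampled on a voxel grid.

    The field stores world-mm displacement vectors at voxel centers of the grid
    described by ``affine``; displacements are interpolated trilinearly between
    voxel centers and extended by their edge values outside the grid.
    """

    kind = "displacement_field"

    def __init__(self, field, affine, tol_mm: float = INVERSE_TOL_MM, max_iter: int = INVERSE_MAX_ITER):
        field = np.asarray(field, dtype=float)
        if field.ndim != 4 or field.shape[-1] != 3:
            raise ValueError("displacement field must have shape (X, Y, Z, 3)")
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        self.field = field
        self.affine = affine
        self._inv_affine = np.linalg.inv(affine)
        self.tol_mm = tol_mm
        self.max_iter = max_iter

    def displacement(self, points):
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vox = pts @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]
        coords = vox.T
        out = np.empty_like(pts)
        for c in range(3):
            out[:, c] = map_coordinates(self.field[..., c], coords, order=1, mode="nearest")
        return out


class FunctionDisplacementTransform(_DisplacementBase):
    """Analytic displacement field given by a callable d(points) -> (N, 3) mm.

    Used for synthetic smooth warps whose displacement is known in closed form;
    the inverse is still numerical (fixed point) but the forward map is exact.
    """

    kind = "displacement_field"

    def __init__(self, func, tol_mm: float = INVERSE_TOL_MM, max_iter: int = INVERSE_MAX_ITER):
        self.func = func
        self.tol_mm = tol_mm
        self.max_iter = max_iter

    def displacement(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.asarray(self.func(pts), dtype=float)
        if d.shape != pts.shape:
            raise ValueError("displacement function must return one 3-vector per point")
        return d


class InverseTransform(SpatialTransform):
    """Numerical inverse of a displacement-style transform."""

    kind = "displacement_field_inverse"

    def __init__(self, base: _DisplacementBase):
        self.base = base

    def apply(self, points):
        pts, single = _as_points(points)
        out = self.base.solve_inverse_points(pts)
        return out[0] if single else out

    def inverse(self):
        return self.base


class ComposedTransform(SpatialTransform):
    """Composition applied left to right: apply(x) = t_n(...t_2(t_1(x)))."""

    kind = "composed"

    def __init__(self, transforms):
        transforms = list(transforms)
        if not transforms:
            raise ValueError("composed transform needs at least one component")
        self.transforms = transforms

    def apply(self, points):
        out = points
        for t in self.transforms:
            out = t.apply(out)
        return out

    def inverse(self):
        return ComposedTransform([t.inverse() for t in reversed(self.transforms)])


def transform_to_json(t: SpatialTransform) -> str:
    """Serialize a matrix or composed-of-matrix transform to JSON."""
    return json.dumps(_to_obj(t), indent=2)


def _to_obj(t: SpatialTransform):
    if isinstance(t, _MatrixTransform):
        return {"kind": t.kind, "matrix": [float(v) for v in t.matrix.ravel()]}
    if isinstance(t, ComposedTransform):
        return {"kind": "composed", "transforms": [_to_obj(c) for c in t.transforms]}
    raise TypeError(
        f"cannot serialize {type(t).__name__} to JSON; save displacement fields as NIfTI"
    )


def transform_from_json(text: str) -> SpatialTransform:
    return _from_obj(json.loads(text))


def _from_obj(obj) -> SpatialTransform:
    kind = obj.get("kind")
    if kind == "rigid":
        return RigidTransform(np.array(obj["matrix"], dtype=float).reshape(4, 4))
    if kind == "affine":
        return AffineTransform(np.array(obj["matrix"], dtype=float).reshape(4, 4))
    if kind == "composed":
        return ComposedTransform([_from_obj(c) for c in obj["transforms"]])
    raise ValueError(f"unknown transform kind {kind!r}")
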