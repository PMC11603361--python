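"""Volumes, masks, affine geometry, resampling, and geometric helpers.

Conventions
-----------
World space is RAS in millimetres.  Voxel indices are 0-based and a voxel's
world position is the position of its *center* under the 4x4 voxel-to-world
affine.  Sampling outside a volume's support yields 0 ("no signal / no
connectivity"), never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .transforms import RigidTransform, SpatialTransform

__all__ = [
    "GridSpec",
    "Volume3D",
    "Mask3D",
    "resample",
    "mask_volume_mm3",
    "center_of_mass_mm",
    "estimate_rigid_from_landmarks",
    "stereotactic_target",
    "grids_match",
]


@dataclass(frozen=True)
class GridSpec:
    """Shape + voxel-to-world affine of a sampling grid."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("grid shape must be 3 positive integers")
        if abs(np.linalg.det(affine[:3, :3])) <= 0:
            raise ValueError("affine upper-left 3x3 must be invertible")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "_inv_affine", np.linalg.inv(affine))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def vox_to_world(self, indices):
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        out = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if np.asarray(indices).ndim == 1 else out

    def world_to_vox(self, points):
        inv = self._inv_affine
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def all_voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (prod(shape), 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T.astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


class Volume3D:
    """A 3-D scalar volume with a voxel-to-world affine (RAS mm)."""

    def __init__(self, data, affine):
        data = np.asarray(data, dtype=float)
        if data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume values must be finite")
        self.data = data
        self.grid = GridSpec(data.shape, affine)

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    @property
    def shape(self):
        return self.data.shape


class Mask3D:
    """A binary 3-D mask with a voxel-to-world affine (RAS mm)."""

    def __init__(self, data, affine):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError("mask data must be 3-D")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.data = data.astype(np.uint8)
        self.grid = GridSpec(data.shape, affine)

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    @property
    def shape(self):
        return self.data.shape

    def nonzero_world(self) -> np.ndarray:
        """World coordinates of nonzero voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.data > 0).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def grids_match(a, b, atol: float = 1e-6) -> bool:
    """True when two volumes/masks/grids share shape and affine."""
    ga = a if isinstance(a, GridSpec) else a.grid
    gb = b if isinstance(b, GridSpec) else b.grid
    return ga.shape == gb.shape and np.allclose(ga.affine, gb.affine, atol=atol)


def resample(vol, xform: SpatialTransform, target: GridSpec, interp: str = "trilinear"):
    """Pull-resample a volume or mask onto a target grid.

    ``xform`` maps *source* world coordinates to *target* world coordinates.
    Each target voxel center is mapped back through ``xform.inverse()`` and the
    source is sampled there (trilinear for volumes, nearest for masks);
    locations outside the source support read as 0.
    """
    is_mask = isinstance(vol, Mask3D)
    if is_mask and interp != "nearest":
        raise ValueError("masks must be resampled with nearest-neighbour interpolation")
    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")

    tgt_world = target.all_voxel_centers_world()
    src_world = xform.inverse().apply(tgt_world)
    inv_src_affine = np.linalg.inv(vol.affine)
    src_vox = src_world @ inv_src_affine[:3, :3].T + inv_src_affine[:3, 3]

    order = 0 if interp == "nearest" else 1
    sampled = map_coordinates(
        vol.data.astype(float), src_vox.T, order=order, mode="constant", cval=0.0
    )
    out = sampled.reshape(target.shape)
    if is_mask:
        return Mask3D((out > 0.5).astype(np.uint8), target.affine)
    return Volume3D(out, target.affine)


def mask_volume_mm3(mask: Mask3D) -> float:
    """Volume of the mask: nonzero voxel count times voxel volume (mm^3)."""
    return float(np.count_nonzero(mask.data)) * mask.grid.voxel_volume_mm3


def center_of_mass_mm(mask: Mask3D) -> np.ndarray:
    """Mean world coordinate of nonzero voxel centers; empty mask raises."""
    pts = mask.nonzero_world()
    if pts.shape[0] == 0:
        raise ValueError("center of mass of an empty mask is undefined")
    return pts.mean(axis=0)


def estimate_rigid_from_landmarks(src, dst) -> RigidTransform:
    """Closed-form orthogonal Procrustes (no scaling) from paired landmarks.

    Finds the rotation R (det +1) and translation t minimizing
    ``sum || R src_i + t - dst_i ||^2`` by SVD of the cross-covariance.
    Requires at least 3 non-collinear pairs.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("rigid estimation needs at least 3 landmark pairs")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    if np.linalg.matrix_rank(src_c, tol=1e-9) < 2 or np.linalg.matrix_rank(dst_c, tol=1e-9) < 2:
        raise ValueError("landmarks are collinear; rotation is not identifiable")
    H = src_c.T @ dst_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform.from_rotation_translation(R, t)


def stereotactic_target(ac, pc, third_ventricle_wall_x: float, side: str) -> np.ndarray:
    """Canonical VIM stereotactic coordinate from AC/PC landmarks.

    The target sits 11 mm lateral to the third-ventricle wall (itself
    ``third_ventricle_wall_x`` mm from the midline) on the chosen side, one
    quarter of the AC-PC distance anterior to PC along the PC->AC axis, and
    2 mm superior to the intercommissural plane.  The superior axis is world
    +z made orthogonal to the AC-PC axis; lateral completes the right-handed
    frame.
    """
    ac = np.asarray(ac, dtype=float)
    pc = np.asarray(pc, dtype=float)
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    acpc = ac - pc
    dist = np.linalg.norm(acpc)
    if dist < 1e-9:
        raise ValueError("AC and PC coincide; AC-PC axis undefined")
    y_hat = acpc / dist
    z_world = np.array([0.0, 0.0, 1.0])
    z_perp = z_world - np.dot(z_world, y_hat) * y_hat
    nz = np.linalg.norm(z_perp)
    if nz < 1e-9:
        raise ValueError("AC-PC axis is parallel to the superior axis; frame degenerate")
    z_hat = z_perp / nz
    x_hat = np.cross(y_hat, z_hat)
    sign = 1.0 if side == "right" else -1.0
    lateral_mm = float(third_ventricle_wall_x) + 11.0
    return pc + 0.25 * dist * y_hat + 2.0 * z_hat + sign * lateral_mm * x_hat
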