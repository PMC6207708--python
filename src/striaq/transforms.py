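"""Spatial transforms: rigid, affine, dense displacement fields, and composition.

All transforms map world coordinates (mm, RAS+) to world coordinates and are
used in the *pull* direction for resampling: a transform passed to
:func:`striaq.imaging.resample` maps points of the target grid into the
coordinate frame of the source volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "AffineTransform",
    "RigidTransform",
    "DisplacementTransform",
    "ComposedTransform",
    "identity",
    "compose",
    "rigid_matrix",
    "affine_matrix_from_params",
]


def rigid_matrix(params: np.ndarray) -> np.ndarray:
    """4x4 matrix for 6-DOF params (tx, ty, tz mm, rx, ry, rz degrees).

    Rotations are applied about the world origin in the order Rz @ Ry @ Rx,
    translation last.
    """
    tx, ty, tz, rx, ry, rz = np.asarray(params, dtype=float)
    rx, ry, rz = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rz @ Ry @ Rx
    M[:3, 3] = (tx, ty, tz)
    return M


def affine_matrix_from_params(params: np.ndarray) -> np.ndarray:
    """4x4 matrix for 12-DOF params.

    Layout: (tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz, hyz) —
    translation mm, rotation degrees, per-axis scales, shears.
    M = T @ R @ Shear @ Scale.
    """
    p = np.asarray(params, dtype=float)
    M = rigid_matrix(p[:6])
    sh = np.eye(3)
    sh[0, 1], sh[0, 2], sh[1, 2] = p[9], p[10], p[11]
    M[:3, :3] = M[:3, :3] @ sh @ np.diag(p[6:9])
    return M


class _Transform:
    """Base: subclasses implement apply(points) on (3, N) world arrays."""

    def apply(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        if single:
            pts = pts[:, None]
        out = self.apply(pts)
        return out[:, 0] if single else out


@dataclass
class AffineTransform(_Transform):
    """12-DOF linear map, stored as a 4x4 homogeneous matrix (mm)."""

    matrix: np.ndarray
    kind: str = "affine"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.matrix[:3, :3] @ points + self.matrix[:3, 3:4]

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return type(self)(inv) if self.kind != "rigid" else RigidTransform(inv)

    def to_json_dict(self) -> dict:
        return {"kind": self.kind, "matrix": self.matrix.tolist(), "units": "mm"}


class RigidTransform(AffineTransform):
    """6-DOF rotation + translation; rotation block orthonormal, det +1."""

    def __init__(self, matrix: np.ndarray):
        super().__init__(matrix, kind="rigid")
        R = self.matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rigid rotation block must be orthonormal with det +1")

    @classmethod
    def from_params(cls, params) -> "RigidTransform":
        return cls(rigid_matrix(params))


def identity() -> RigidTransform:
    return RigidTransform(np.eye(4))


@dataclass
class DisplacementTransform(_Transform):
    """Dense displacement field d on a voxel grid: x -> x + d(x), in mm.

    ``field`` has shape (3,) + grid shape and stores world-space displacement
    vectors at each voxel of the grid defined by ``affine``. Off-grid points
    are displaced by the trilinearly interpolated field (zero outside).
    """

    field: np.ndarray
    affine: np.ndarray
    kind: str = field(default="deformation", init=False)

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.field.ndim != 4 or self.field.shape[0] != 3:
            raise ValueError("displacement field must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("displacement field contains non-finite values")

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        vox = inv[:3, :3] @ points + inv[:3, 3:4]
        return np.stack(
            [map_coordinates(self.field[i], vox, order=1, mode="constant", cval=0.0)
             for i in range(3)]
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points + self.displacement_at(points)

    def max_displacement(self) -> float:
        return float(np.sqrt((self.field ** 2).sum(axis=0)).max())

    def save(self, path: str) -> None:
        """Write as a NIfTI volume with 3 components (world displacement, mm)."""
        import nibabel as nib

        nib.save(nib.Nifti1Image(
            np.moveaxis(self.field, 0, -1).astype(np.float32), self.affine), path)

    @classmethod
    def load(cls, path: str) -> "DisplacementTransform":
        import nibabel as nib

        img = nib.load(path)
        return cls(np.moveaxis(np.asarray(img.get_fdata()), -1, 0), img.affine)

    def inverse(self) -> "DisplacementTransform":
        """Approximate inverse by fixed-point iteration d_inv(x) = -d(x + d_inv(x))."""
        inv_field = -self.field.copy()
        shape = self.field.shape[1:]
        ii = np.indices(shape, dtype=float).reshape(3, -1)
        world = self.affine[:3, :3] @ ii + self.affine[:3, 3:4]
        for _ in range(8):
            disp = inv_field.reshape(3, -1)
            inv_field = -self.displacement_at(world + disp).reshape(self.field.shape)
        return DisplacementTransform(inv_field, self.affine)


@dataclass
class ComposedTransform(_Transform):
    """Lazy chain: apply(points) maps through transforms right-to-left.

    Keeping the chain lazy lets a multi-stage registration result be applied
    with a single interpolation of the image, with no intermediate field
    resampling error.
    """

    transforms: tuple
    kind: str = field(default="composed", init=False)

    def apply(self, points: np.ndarray) -> np.ndarray:
        for t in reversed(self.transforms):
            points = t(points)
        return points


def compose(*transforms) -> _Transform:
    """Compose transforms; the result applies the rightmost first.

    ``compose(a, b)(x) == a(b(x))`` — matrix-product order. Chains of purely
    linear transforms collapse to a single exact matrix (rigid if all rigid).
    """
    if not transforms:
        return identity()
    if all(isinstance(t, AffineTransform) for t in transforms):
        M = np.eye(4)
        for t in transforms:
            M = M @ t.matrix
        if all(t.kind == "rigid" for t in transforms):
            return RigidTransform(M)
        return AffineTransform(M)
    flat = []
    for t in transforms:
        flat.extend(t.transforms if isinstance(t, ComposedTransform) else [t])
    return ComposedTransform(tuple(flat))
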