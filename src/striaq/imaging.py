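"""Volume data model, NIfTI I/O, resampling, smoothing, ROI statistics, flipping.

A :class:`Volume` is a 3-D scalar grid plus a 4x4 grid-to-world affine in mm
(RAS+ orientation). The default study grid is 64x64x54 voxels at 3 mm
isotropic, centred so that the midsagittal plane is world x = 0; that makes
left-right flipping an exact axis reversal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .transforms import _Transform

__all__ = [
    "Volume",
    "ROIAtlas",
    "GridSpec",
    "default_grid",
    "FWHM_TO_SIGMA",
    "roi_mean",
    "flip_lateral",
    "gaussian_smooth",
    "resample",
    "resample_mask",
]

#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

PHASES = ("early", "late", "structural", "template")


@dataclass(frozen=True)
class GridSpec:
    """Shape + grid-to-world affine of a sampling grid."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (3, N)."""
        ii = np.indices(self.shape, dtype=float).reshape(3, -1)
        return self.affine[:3, :3] @ ii + self.affine[:3, 3:4]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        if single:
            pts = pts[:, None]
        inv = np.linalg.inv(self.affine)
        out = inv[:3, :3] @ pts + inv[:3, 3:4]
        return out[:, 0] if single else out

    @property
    def spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def default_grid(shape=(64, 64, 54), spacing_mm=3.0) -> GridSpec:
    """Study grid: axis-aligned, isotropic, centred on the world origin."""
    shape = tuple(shape)
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * spacing_mm
    aff[:3, 3] = [-spacing_mm * (n - 1) / 2.0 for n in shape]
    return GridSpec(shape, aff)


@dataclass
class Volume:
    """3-D scalar image with world geometry and an acquisition-phase tag."""

    data: np.ndarray
    affine: np.ndarray
    phase: str = "late"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("Volume data contains non-finite values")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data.shape, self.affine)

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data))

    def save(self, path: str) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, path)

    @classmethod
    def load(cls, path: str, phase: str = "late") -> "Volume":
        img = nib.load(path)
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine, phase)


def _grids_match(a: GridSpec, b: GridSpec, atol=1e-6) -> bool:
    return a.shape == b.shape and np.allclose(a.affine, b.affine, atol=atol)


# ---------------------------------------------------------------------------
# ROI atlas


ROI_SIDES = ("left", "right", "midline")
ROI_ROLES = ("target", "reference_early", "reference_late")

#: composite basal-ganglia mask = union of caudate + anterior/posterior putamen
BASAL_GANGLIA_STRUCTURES = ("caudate", "anterior_putamen", "posterior_putamen")


class ROIAtlas:
    """Integer label volume plus a label table (label, name, side, role).

    Names follow ``<structure>_<side>`` for bilateral target ROIs (e.g.
    ``posterior_putamen_left``) and plain names for midline reference regions
    (``pons``, ``occipital``). The basal-ganglia composite is the union of
    the caudate and putamen labels and is exposed via :meth:`mask`.
    """

    def __init__(self, labels: np.ndarray, affine: np.ndarray, table: pd.DataFrame):
        labels = np.asarray(labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise TypeError("atlas labels must be an integer volume")
        self.labels = labels
        self.affine = np.asarray(affine, dtype=float)
        required = {"label", "name", "side", "role"}
        if not required.issubset(table.columns):
            raise ValueError(f"label table must have columns {sorted(required)}")
        self.table = table.reset_index(drop=True)
        self._by_name = {r["name"]: r for _, r in self.table.iterrows()}

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.labels.shape, self.affine)

    def names(self, role: str | None = None) -> list:
        t = self.table if role is None else self.table[self.table["role"] == role]
        return list(t["name"])

    def side_of(self, name: str) -> str:
        return self._by_name[name]["side"]

    def structure_of(self, name: str) -> str:
        """Structure name with any trailing _left/_right stripped."""
        for suffix in ("_left", "_right"):
            if name.endswith(suffix):
                return name[: -len(suffix)]
        return name

    def reference_roi(self, phase: str) -> str:
        role = {"early": "reference_early", "late": "reference_late"}.get(phase)
        if role is None:
            raise ValueError(f"no reference region defined for phase {phase!r}")
        names = self.names(role)
        if len(names) != 1:
            raise ValueError(f"expected exactly one {role} ROI, found {names}")
        return names[0]

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask for a named ROI or the 'basal_ganglia' composite."""
        if name == "basal_ganglia":
            out = np.zeros(self.labels.shape, dtype=bool)
            for roi in self.names("target"):
                if self.structure_of(roi) in BASAL_GANGLIA_STRUCTURES:
                    out |= self.labels == self._by_name[roi]["label"]
            if not out.any():
                raise ValueError("basal ganglia composite mask is empty")
            return out
        if name not in self._by_name:
            raise KeyError(f"unknown ROI name {name!r}")
        return self.labels == self._by_name[name]["label"]

    def counterpart(self, name: str) -> str:
        """Name of the mirror ROI (left<->right); midline ROIs map to themselves."""
        side = self.side_of(name)
        if side == "midline":
            return name
        other = "right" if side == "left" else "left"
        return f"{self.structure_of(name)}_{other}"

    # -- I/O: NIfTI labels + TSV sidecar ------------------------------------
    def save(self, nii_path: str, tsv_path: str | None = None) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.affine)
        nib.save(img, nii_path)
        if tsv_path is None:
            base = nii_path[: -len(".nii.gz")] if nii_path.endswith(".nii.gz") else os.path.splitext(nii_path)[0]
            tsv_path = base + "_labels.tsv"
        self.table.to_csv(tsv_path, sep="\t", index=False)

    @classmethod
    def load(cls, nii_path: str, tsv_path: str) -> "ROIAtlas":
        img = nib.load(nii_path)
        table = pd.read_csv(tsv_path, sep="\t")
        return cls(np.asarray(img.dataobj).astype(np.int32), img.affine, table)


# ---------------------------------------------------------------------------
# Operations


def roi_mean(vol: Volume, atlas: ROIAtlas, label: str) -> float:
    """Arithmetic mean of the image over the voxels carrying ``label``.

    The atlas must live on the volume's grid; an empty ROI is an error.
    """
    if not _grids_match(vol.grid, atlas.grid):
        raise ValueError("atlas grid does not match volume grid")
    m = atlas.mask(label)
    if not m.any():
        raise ValueError(f"ROI {label!r} is empty on this grid")
    return float(vol.data[m].mean())


def _flip_axis_info(affine: np.ndarray, shape) -> int:
    """Return the voxel axis aligned with world x, validating flippability.

    Requires an axis-aligned affine whose x-axis voxel centers are symmetric
    about world x = 0 so that reversing that axis is an exact mirror.
    """
    lin = affine[:3, :3]
    col = np.flatnonzero(np.abs(lin[0]) > 1e-9)
    if len(col) != 1 or np.abs(lin[1:, col[0]]).max() > 1e-9:
        raise ValueError("flip requires an axis-aligned grid (one voxel axis along world x)")
    ax = int(col[0])
    sx = lin[0, ax]
    # symmetry: t_x must equal -sx*(n-1)/2 so centers mirror onto centers
    expected = -sx * (shape[ax] - 1) / 2.0
    if not np.isclose(affine[0, 3], expected, atol=1e-6):
        raise ValueError("grid is not symmetric about the midsagittal plane x=0")
    return ax


def flip_lateral(vol: Volume) -> Volume:
    """Mirror the image about the midsagittal plane (world x = 0).

    The voxel at world (x, y, z) takes the value formerly at (-x, y, z). On
    the symmetric study grid this is an exact axis reversal, so the operation
    is a bit-exact involution. Works on intensity images and (integer) label
    volumes alike.
    """
    ax = _flip_axis_info(vol.affine, vol.data.shape)
    return vol.with_data(np.flip(vol.data, axis=ax).copy())


def flip_label_volume(labels: np.ndarray, affine: np.ndarray) -> np.ndarray:
    ax = _flip_axis_info(affine, labels.shape)
    return np.flip(labels, axis=ax).copy()


def gaussian_smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Isotropic Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma (voxels, per axis) = fwhm * FWHM_TO_SIGMA / spacing. Zero FWHM is
    the identity. Boundary handling is zero-padding, so the total image sum
    is preserved up to truncation of kernel tails at the field edge.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.grid.spacing
    out = gaussian_filter(np.asarray(vol.data, dtype=float), sigma=sigma_vox,
                          mode="constant", cval=0.0)
    return vol.with_data(out)


_INTERP_ORDERS = {"trilinear": 1, "nearest": 0}


def resample(
    vol: Volume,
    xform: _Transform,
    target: GridSpec,
    interp: str = "trilinear",
) -> Volume:
    """Resample ``vol`` onto ``target``; ``xform`` maps target world -> vol world.

    Out-of-field voxels are filled with 0 (use :func:`resample_mask` for the
    validity mask). Trilinear interpolation on an integer label volume is
    refused: fractional labels are meaningless — resample atlases with
    ``interp='nearest'``.
    """
    if interp not in _INTERP_ORDERS:
        raise ValueError(f"unknown interpolation mode {interp!r}")
    if interp == "trilinear" and np.issubdtype(vol.data.dtype, np.integer):
        raise ValueError("trilinear interpolation of a label volume; use 'nearest'")
    world = xform(target.voxel_centers())
    vox = vol.grid.world_to_voxel(world)
    out = map_coordinates(
        np.asarray(vol.data, dtype=float),
        vox,
        order=_INTERP_ORDERS[interp],
        mode="constant",
        cval=0.0,
    ).reshape(target.shape)
    if interp == "nearest":
        out = out.astype(vol.data.dtype)
    return Volume(out, target.affine.copy(), vol.phase)


def resample_mask(vol: Volume, xform: _Transform, target: GridSpec) -> np.ndarray:
    """Boolean mask of target voxels that land inside the source field of view."""
    world = xform(target.voxel_centers())
    vox = vol.grid.world_to_voxel(world)
    shape = np.asarray(vol.data.shape, dtype=float)
    ok = np.all((vox >= 0) & (vox <= shape[:, None] - 1), axis=0)
    return ok.reshape(target.shape)
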