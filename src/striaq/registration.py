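"""Image registration by sum-of-squared-differences minimization.

Rigid (6 DOF) and affine (12 DOF) alignment use a multi-resolution strategy:
at each pyramid level both images are Gaussian-smoothed and the cost is
evaluated on a strided subset of fixed-grid voxels, and the parameters are
refined with a bounded trust-region least-squares solver on the masked,
unit-mean-normalized intensity residuals. A simplified demons-style stage
with Gaussian (fluid + elastic) regularization provides nonlinear refinement;
it deliberately does not reproduce any particular high-dimensional
normalization algorithm — the pipeline contract only requires images to land
in the standard space.

All recovered transforms map fixed-image world coordinates into moving-image
world coordinates (the pull direction used by resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize._numdiff import approx_derivative

from .imaging import FWHM_TO_SIGMA, Volume
from .transforms import (
    AffineTransform,
    DisplacementTransform,
    RigidTransform,
    affine_matrix_from_params,
    compose,
    rigid_matrix,
)

__all__ = [
    "RegistrationOptions",
    "RegistrationResult",
    "ssd_cost",
    "register_rigid",
    "register_affine",
    "register_nonlinear",
]


@dataclass
class RegistrationResult:
    """Outcome of one registration: transform plus cost bookkeeping.

    Costs are mean squared intensity differences over valid (in-field)
    voxels after unit-mean normalization; ``final_cost <= initial_cost`` is
    enforced by construction (the best-seen parameters are kept).
    """

    transform: object
    initial_cost: float
    final_cost: float
    iterations: int
    converged: bool
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.final_cost > self.initial_cost + 1e-12:
            raise ValueError("final_cost exceeds initial_cost")


@dataclass(frozen=True)
class RegistrationOptions:
    """Tunable registration settings.

    ``levels`` is a coarse-to-fine tuple of (stride, smoothing FWHM mm): the
    cost at each level is sampled every ``stride`` fixed voxels after both
    images are smoothed. ``max_nfev`` bounds solver cost evaluations per
    level; convergence is a relative cost change below ``ftol``.
    """

    levels: tuple = ((4, 10.0), (2, 4.0))
    ftol: float = 1e-6
    max_nfev: int = 200
    translation_bound_mm: float = 40.0
    rotation_bound_deg: float = 30.0
    scale_bounds: tuple = (0.8, 1.25)
    shear_bound: float = 0.2
    init_params: tuple | None = None
    centroid_init: bool = True
    # nonlinear (demons) stage
    demons_iterations: int = 40
    demons_stride: int = 2
    demons_smoothing_fwhm_mm: float = 3.0
    demons_step_cap_mm: float = 2.0
    demons_sigma_fluid_mm: float = 2.0
    demons_sigma_elastic_mm: float = 1.5
    max_displacement_mm: float = 10.0
    demons_ftol: float = 1e-4
    affine_prefit: bool = True


def _smoothed(vol: Volume, fwhm_mm: float) -> np.ndarray:
    data = np.asarray(vol.data, dtype=np.float32)
    if fwhm_mm <= 0:
        return data
    sigma = fwhm_mm * FWHM_TO_SIGMA / vol.grid.spacing
    return gaussian_filter(data, sigma=sigma, mode="constant", cval=0.0)


class _SSDEvaluator:
    """Masked, normalized SSD between a fixed sample set and a moving image."""

    def __init__(self, fixed: Volume, moving: Volume, stride: int = 1,
                 fwhm_mm: float = 0.0):
        fdata = _smoothed(fixed, fwhm_mm)
        sl = (slice(None, None, stride),) * 3
        grid = fixed.grid
        ii = np.indices(grid.shape, dtype=np.float32)[(slice(None),) + sl]
        ii = ii.reshape(3, -1)
        self.fixed_world = (grid.affine[:3, :3].astype(np.float32) @ ii
                            + grid.affine[:3, 3:4].astype(np.float32))
        self.fixed_vals = fdata[sl].reshape(-1)
        self.moving_data = _smoothed(moving, fwhm_mm)
        inv = np.linalg.inv(moving.affine)
        self.m_inv_lin = inv[:3, :3].astype(np.float32)
        self.m_inv_off = inv[:3, 3:4].astype(np.float32)
        self.m_shape = np.asarray(self.moving_data.shape, dtype=np.float32)

    def _sample(self, xform) -> tuple[np.ndarray, np.ndarray]:
        world = xform(self.fixed_world)
        vox = self.m_inv_lin @ np.asarray(world, dtype=np.float32) + self.m_inv_off
        valid = np.all((vox >= 0) & (vox <= self.m_shape[:, None] - 1), axis=0)
        vals = map_coordinates(self.moving_data, vox, order=1,
                               mode="constant", cval=0.0)
        return vals, valid

    def residuals(self, xform) -> np.ndarray:
        vals, valid = self._sample(xform)
        n = int(valid.sum())
        if n == 0:
            raise ValueError("empty valid mask: images do not overlap under this transform")
        fm = float(self.fixed_vals[valid].mean())
        mm = float(vals[valid].mean())
        if fm <= 0 or mm <= 0:
            raise ValueError("non-positive mean intensity in valid mask")
        r = (self.fixed_vals / fm - vals / mm) * valid
        return r / np.sqrt(n)

    def cost(self, xform) -> float:
        r = self.residuals(xform)
        return float((r ** 2).sum())


def ssd_cost(fixed: Volume, moving: Volume, xform) -> float:
    """Mean squared intensity difference over valid voxels.

    ``xform`` maps fixed world coordinates into moving world coordinates.
    Both images are normalized to unit mean over the valid (in-field) mask
    before differencing, so a global intensity scaling of either image does
    not change the cost.
    """
    return _SSDEvaluator(fixed, moving).cost(xform)


def _centroid(vol: Volume) -> np.ndarray:
    d = np.clip(np.asarray(vol.data, dtype=float), 0, None)
    tot = d.sum()
    if tot <= 0:
        return np.zeros(3)
    ii = np.indices(d.shape, dtype=float).reshape(3, -1)
    com = (ii * d.reshape(1, -1)).sum(axis=1) / tot
    return vol.affine[:3, :3] @ com + vol.affine[:3, 3]


def _param_transform(params: np.ndarray, dof: int):
    if dof == 6:
        return RigidTransform(rigid_matrix(params))
    return AffineTransform(affine_matrix_from_params(params))


def _register_linear(fixed: Volume, moving: Volume, dof: int,
                     opts: RegistrationOptions) -> RegistrationResult:
    if opts.init_params is not None:
        x0 = np.asarray(opts.init_params, dtype=float)
    else:
        x0 = np.zeros(6)
        if opts.centroid_init:
            x0[:3] = _centroid(moving) - _centroid(fixed)
    if dof == 12 and x0.size == 6:
        x0 = np.concatenate([x0, [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]])
    tb, rb = opts.translation_bound_mm, opts.rotation_bound_deg
    lo = [-tb] * 3 + [-rb] * 3
    hi = [tb] * 3 + [rb] * 3
    if dof == 12:
        lo += [opts.scale_bounds[0]] * 3 + [-opts.shear_bound] * 3
        hi += [opts.scale_bounds[1]] * 3 + [opts.shear_bound] * 3
    x0 = np.clip(x0, lo, hi)

    full = _SSDEvaluator(fixed, moving)
    x_init = x0.copy()
    initial_cost = full.cost(_param_transform(x0, dof))
    n_iter = 0
    statuses = []
    for stride, fwhm in opts.levels:
        ev = _SSDEvaluator(fixed, moving, stride=stride, fwhm_mm=fwhm)

        def fun(p):
            return ev.residuals(_param_transform(p, dof))

        # absolute finite-difference steps sized to move the image by a
        # resolvable fraction of a voxel (mm / degrees / scale+shear units);
        # relative steps would vanish for parameters sitting exactly at 0
        steps = np.array([0.25] * 6 + ([0.01] * 6 if dof == 12 else []))

        def jac(p):
            return approx_derivative(fun, p, method="2-point", abs_step=steps,
                                     bounds=(lo, hi))

        sol = optimize.least_squares(
            fun, x0, jac=jac, bounds=(lo, hi), method="trf",
            x_scale=[1.0] * 3 + [0.5] * 3 + ([0.02] * 6 if dof == 12 else []),
            ftol=opts.ftol, xtol=1e-8, max_nfev=opts.max_nfev,
        )
        x0 = sol.x
        n_iter += int(sol.nfev)
        statuses.append(int(sol.status))
    final_cost = full.cost(_param_transform(x0, dof))
    converged = all(s > 0 for s in statuses)
    if final_cost > initial_cost:
        # no-worse-than-start guarantee: fall back to the starting estimate
        # (can trigger when the init is already at the full-resolution optimum)
        x0, final_cost = x_init, initial_cost
    return RegistrationResult(
        transform=_param_transform(x0, dof),
        initial_cost=initial_cost, final_cost=final_cost,
        iterations=n_iter, converged=converged,
        flags={"params": np.asarray(x0, dtype=float)},
    )


def register_rigid(fixed: Volume, moving: Volume,
                   opts: RegistrationOptions | None = None) -> RegistrationResult:
    """6-DOF alignment minimizing normalized SSD over a resolution pyramid.

    Deterministic given inputs and options; non-convergence is reported via
    ``converged=False`` on the result, never as an exception.
    """
    return _register_linear(fixed, moving, 6, opts or RegistrationOptions())


def register_affine(fixed: Volume, moving: Volume,
                    opts: RegistrationOptions | None = None) -> RegistrationResult:
    """12-DOF alignment, initialized from a rigid pre-fit."""
    opts = opts or RegistrationOptions()
    if opts.init_params is None:
        pre = register_rigid(fixed, moving, opts)
        opts = replace(opts, init_params=tuple(pre.flags["params"]))
    return _register_linear(fixed, moving, 12, opts)


def register_nonlinear(fixed: Volume, moving: Volume,
                       opts: RegistrationOptions | None = None,
                       initial_transform=None) -> RegistrationResult:
    """Affine pre-fit plus a demons-style regularized displacement field.

    The recovered transform maps a fixed-grid world point x to
    ``A(x + d(x))`` where A is the (given or fitted) affine and d is a dense
    displacement field on the fixed grid, smoothed at each iteration
    (fluid regularization of the update, elastic regularization of the
    field) and clamped to ``max_displacement_mm``. ``final_cost`` never
    exceeds the affine-only cost because the best-seen field is kept.
    """
    opts = opts or RegistrationOptions()
    if initial_transform is not None:
        A = initial_transform
        pre_iters = 0
    elif opts.affine_prefit:
        pre = register_affine(fixed, moving, opts)
        A, pre_iters = pre.transform, pre.iterations
    else:
        A, pre_iters = AffineTransform(np.eye(4)), 0

    grid = fixed.grid
    stride = opts.demons_stride
    sl = (slice(None, None, stride),) * 3
    sub_affine = grid.affine.copy()
    sub_affine[:3, :3] *= stride
    fdata = _smoothed(fixed, opts.demons_smoothing_fwhm_mm)[sl]
    spacing = grid.spacing * stride
    shape = fdata.shape
    ii = np.indices(shape, dtype=np.float32).reshape(3, -1)
    world = (sub_affine[:3, :3].astype(np.float32) @ ii
             + sub_affine[:3, 3:4].astype(np.float32))
    mdata = _smoothed(moving, opts.demons_smoothing_fwhm_mm)
    minv = np.linalg.inv(moving.affine)
    m_lin, m_off = minv[:3, :3].astype(np.float32), minv[:3, 3:4].astype(np.float32)
    m_shape = np.asarray(mdata.shape, dtype=np.float32)

    def warp(disp_flat):
        w = np.asarray(A(world + disp_flat), dtype=np.float32)
        vox = m_lin @ w + m_off
        valid = np.all((vox >= 0) & (vox <= m_shape[:, None] - 1), axis=0)
        vals = map_coordinates(mdata, vox, order=1, mode="constant", cval=0.0)
        return vals, valid

    # unit-mean normalization fixed once, from the affine-aligned state
    vals0, valid0 = warp(np.zeros_like(world))
    if not valid0.any():
        raise ValueError("empty valid mask after affine pre-alignment")
    f = (fdata.reshape(-1) / max(float(fdata.reshape(-1)[valid0].mean()), 1e-12))
    m_scale = max(float(vals0[valid0].mean()), 1e-12)

    def cost_of(vals, valid):
        diff = (f - vals / m_scale) * valid
        return float((diff ** 2).sum() / max(int(valid.sum()), 1))

    sig_fluid = opts.demons_sigma_fluid_mm / spacing
    sig_elastic = opts.demons_sigma_elastic_mm / spacing
    d = np.zeros((3,) + shape, dtype=np.float32)
    best_d = d.copy()
    best_cost = initial_cost = cost_of(vals0, valid0)
    clamped = False
    n_iter = 0
    prev_cost = initial_cost
    for n_iter in range(1, opts.demons_iterations + 1):
        vals, valid = warp(d.reshape(3, -1))
        mw = (vals / m_scale).reshape(shape)
        diff = (f.reshape(shape) - mw) * valid.reshape(shape)
        g = np.stack(np.gradient(mw, *spacing))
        g2 = (g ** 2).sum(axis=0)
        denom = g2 + (diff / spacing.mean()) ** 2
        denom = np.maximum(denom, 1e-9)
        u = diff * g / denom
        # fluid: smooth the update; cap the per-iteration step
        for i in range(3):
            u[i] = gaussian_filter(u[i], sigma=sig_fluid, mode="constant")
        umag = np.sqrt((u ** 2).sum(axis=0))
        cap = opts.demons_step_cap_mm
        scale = np.where(umag > cap, cap / np.maximum(umag, 1e-12), 1.0)
        d = d + u * scale
        # elastic: smooth the accumulated field
        for i in range(3):
            d[i] = gaussian_filter(d[i], sigma=sig_elastic, mode="constant")
        dmag = np.sqrt((d ** 2).sum(axis=0))
        if dmag.max() > opts.max_displacement_mm:
            clamped = True
            over = dmag > opts.max_displacement_mm
            d[:, over] *= opts.max_displacement_mm / dmag[over]
        vals, valid = warp(d.reshape(3, -1))
        c = cost_of(vals, valid)
        if c < best_cost:
            best_cost, best_d = c, d.copy()
        if abs(prev_cost - c) <= opts.demons_ftol * max(prev_cost, 1e-12):
            break
        prev_cost = c
    disp = DisplacementTransform(best_d.astype(float), sub_affine)
    transform = compose(A, disp)
    converged = n_iter < opts.demons_iterations or best_cost <= initial_cost
    return RegistrationResult(
        transform=transform,
        initial_cost=initial_cost, final_cost=best_cost,
        iterations=pre_iters + n_iter, converged=converged,
        flags={"affine": A, "displacement": disp, "clamped": clamped},
    )
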