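"""SSD cost behaviour and transform recovery on known misalignments."""

import numpy as np
import pytest

import striaq as sq
from striaq.imaging import Volume, default_grid, resample
from striaq.registration import (
    RegistrationOptions,
    RegistrationResult,
    register_affine,
    register_nonlinear,
    register_rigid,
    ssd_cost,
)
from striaq.transforms import (
    AffineTransform,
    DisplacementTransform,
    RigidTransform,
    affine_matrix_from_params,
    identity,
    rigid_matrix,
)


def _rotation_angle_deg(M):
    return np.degrees(np.arccos(np.clip((np.trace(M[:3, :3]) - 1) / 2, -1, 1)))


class TestSSDCost:
    def test_identical_images_zero(self, std_phantoms):
        _, late = std_phantoms
        assert ssd_cost(late, late, identity()) == 0.0

    def test_constant_offset_cancelled_by_normalization(self):
        grid = default_grid((16, 16, 14))
        a = Volume(np.full(grid.shape, 2.0), grid.affine, "late")
        b = Volume(np.full(grid.shape, 5.0), grid.affine, "late")
        assert ssd_cost(a, b, identity()) == pytest.approx(0.0, abs=1e-12)

    def test_misaligned_delta_positive(self):
        grid = default_grid((16, 16, 14))
        a = np.zeros(grid.shape)
        a[8, 8, 7] = 1.0
        b = np.zeros(grid.shape)
        b[9, 8, 7] = 1.0
        cost = ssd_cost(Volume(a, grid.affine, "late"),
                        Volume(b, grid.affine, "late"), identity())
        assert cost > 0

    def test_disjoint_fields_of_view_error(self, std_phantoms):
        _, late = std_phantoms
        far = RigidTransform(rigid_matrix([1000.0, 0, 0, 0, 0, 0]))
        with pytest.raises(ValueError, match="valid mask"):
            ssd_cost(late, late, far)


class TestRigidRecovery:
    def test_identical_images_identity(self, std_phantoms):
        _, late = std_phantoms
        res = register_rigid(late, late)
        assert np.linalg.norm(res.transform.matrix[:3, 3]) < 0.1
        assert _rotation_angle_deg(res.transform.matrix) < 0.1
        assert res.final_cost <= res.initial_cost

    def test_translation_recovered(self, std_phantoms):
        _, late = std_phantoms
        t = np.array([4.5, -3.0, 6.0])
        moving = resample(late, RigidTransform(rigid_matrix(list(-t) + [0, 0, 0])),
                          late.grid)
        res = register_rigid(late, moving)
        assert np.abs(res.transform.matrix[:3, 3] - t).max() < 1.5  # 0.5 voxel

    def test_rotation_recovered(self, std_phantoms):
        _, late = std_phantoms
        moving = resample(late, RigidTransform(rigid_matrix([0, 0, 0, 0, 0, -5.0])),
                          late.grid)
        res = register_rigid(late, moving)
        assert abs(_rotation_angle_deg(res.transform.matrix) - 5.0) < 0.5

    def test_median_error_over_random_transforms(self, std_phantoms):
        _, late = std_phantoms
        rng = np.random.default_rng(7)
        terr, rerr = [], []
        for _ in range(20):
            p = np.concatenate([rng.uniform(-6, 6, 3), rng.uniform(-6, 6, 3)])
            T = RigidTransform(rigid_matrix(p))
            moving = resample(late, T.inverse(), late.grid)
            res = register_rigid(late, moving)
            M = res.transform.matrix @ np.linalg.inv(T.matrix)
            terr.append(np.linalg.norm(M[:3, 3]))
            rerr.append(_rotation_angle_deg(M))
        assert np.median(terr) < 1.5  # 0.5 voxel at 3 mm
        assert np.median(rerr) < 0.5

    def test_forward_and_backward_runs_are_inverse(self, std_phantoms):
        _, late = std_phantoms
        T = RigidTransform(rigid_matrix([3.0, -2.0, 4.0, 2.0, 3.0, -4.0]))
        moving = resample(late, T.inverse(), late.grid)
        ab = register_rigid(late, moving).transform
        ba = register_rigid(moving, late).transform
        pts = late.grid.voxel_centers()[:, ::97]
        err = np.linalg.norm(ab(ba(pts)) - pts, axis=0)
        assert err.mean() < 1.0  # mm


class TestAffineRecovery:
    def test_identity(self, std_phantoms):
        _, late = std_phantoms
        res = register_affine(late, late)
        assert np.abs(res.transform.matrix - np.eye(4)).max() < 0.02

    def test_uniform_scale_recovered(self, std_phantoms):
        _, late = std_phantoms
        sc = AffineTransform(affine_matrix_from_params(
            [0, 0, 0, 0, 0, 0, 1 / 1.08, 1 / 1.08, 1 / 1.08, 0, 0, 0]))
        moving = resample(late, sc, late.grid)
        res = register_affine(late, moving)
        scales = np.linalg.svd(res.transform.matrix[:3, :3])[1]
        assert np.abs(scales - 1.08).max() < 0.02

    def test_cross_contrast_alignment_dice(self, atlas, control_truth):
        """Early-phase vs structural phantom: striatal overlap after affine."""
        import dataclasses

        from skimage.exposure import match_histograms
        import striaq.synthetic as syn

        T = AffineTransform(affine_matrix_from_params(
            [4.0, -3.0, 2.0, 3.0, -2.0, 4.0, 1.03, 0.97, 1.01, 0, 0, 0]))
        truth = dataclasses.replace(control_truth, transform=T)
        early, _ = syn.make_subject_images(truth, atlas)
        structural = syn.make_structural_image(truth, atlas)  # own frame = early
        matched = structural.with_data(match_histograms(
            structural.data.astype(float), early.data.astype(float)))
        res = register_affine(matched, early)
        # map the standard-space striatal mask into both native frames
        mask = Volume(atlas.mask("basal_ganglia").astype(float), atlas.affine,
                      "late")
        m_struct = resample(mask, truth.transform, atlas.grid).data > 0.5
        m_early_via_reg = resample(
            resample(mask, truth.transform, atlas.grid),  # early-frame mask
            res.transform, atlas.grid).data > 0.5
        dice = 2 * (m_struct & m_early_via_reg).sum() / (
            m_struct.sum() + m_early_via_reg.sum())
        assert dice >= 0.85


class TestNonlinear:
    def _bump(self, grid, seed=3, amp=4.0, scale=25.0):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        f = rng.normal(0, 1, (3,) + grid.shape)
        for i in range(3):
            f[i] = gaussian_filter(f[i], sigma=scale / grid.spacing, mode="constant")
        f *= amp / np.sqrt((f ** 2).sum(axis=0)).max()
        return DisplacementTransform(f, grid.affine)

    def test_identical_images_tiny_displacement(self, std_phantoms):
        _, late = std_phantoms
        res = register_nonlinear(late, late)
        assert res.flags["displacement"].max_displacement() < 0.5

    def test_known_bump_recovered(self, atlas, std_phantoms):
        """Recovered map composed with the truth warp is close to identity."""
        from striaq.transforms import compose

        _, late = std_phantoms
        D = self._bump(late.grid)
        moving = resample(late, D, late.grid)  # true fixed->moving map is D^-1
        res = register_nonlinear(late, moving)
        assert res.final_cost <= 0.5 * res.initial_cost
        mask = atlas.mask("basal_ganglia")
        pts = late.grid.voxel_centers()[:, mask.reshape(-1)]
        resid = np.linalg.norm(compose(D, res.transform)(pts) - pts, axis=0)
        assert resid.mean() < 1.5

    def test_putamen_dice_after_recovery(self, atlas, std_phantoms):
        from striaq.transforms import compose

        _, late = std_phantoms
        D = self._bump(late.grid, seed=9)
        moving = resample(late, D, late.grid)
        res = register_nonlinear(late, moving)
        lab = Volume(atlas.labels, atlas.affine, "late")
        roundtrip = resample(lab, compose(D, res.transform), late.grid,
                             interp="nearest")
        for name in ("posterior_putamen_left", "posterior_putamen_right"):
            lid = atlas._by_name[name]["label"]
            a, b = roundtrip.data == lid, atlas.mask(name)
            dice = 2 * (a & b).sum() / (a.sum() + b.sum())
            assert dice >= 0.8

    def test_displacement_cap_flagged(self, std_phantoms):
        _, late = std_phantoms
        D = self._bump(late.grid, amp=9.0, scale=12.0)
        moving = resample(late, D, late.grid)
        opts = RegistrationOptions(max_displacement_mm=1.0,
                                   demons_iterations=10)
        res = register_nonlinear(late, moving, opts)
        assert res.flags["displacement"].max_displacement() <= 1.0 + 1e-6
        assert res.flags["clamped"]


def test_result_invariant_enforced():
    with pytest.raises(ValueError, match="final_cost"):
        RegistrationResult(identity(), initial_cost=1.0, final_cost=2.0,
                           iterations=1, converged=True)


def test_agreement_with_simpleitk_oracle(atlas, std_phantoms):
    """Striatal Dice after rigid alignment within 0.05 of SimpleITK's.

    Both toolkits solve the same task (mean-squares rigid alignment of a
    translated+rotated phantom); agreement is compared purely through the
    overlap each achieves, so no transform-convention conversion is needed.
    """
    sitk = pytest.importorskip("SimpleITK")
    _, late = std_phantoms
    T = RigidTransform(rigid_matrix([4.0, -2.0, 3.0, 3.0, -2.0, 2.0]))
    moving = resample(late, T.inverse(), late.grid)
    mask_fixed = atlas.mask("basal_ganglia")
    mask_vol = Volume(mask_fixed.astype(float), atlas.affine, "late")
    mask_moving = resample(mask_vol, T.inverse(), late.grid)  # follows moving

    def dice(arr):
        a = arr > 0.5
        return 2 * (a & mask_fixed).sum() / (a.sum() + mask_fixed.sum())

    ours_arr = resample(mask_moving, register_rigid(late, moving).transform,
                        late.grid).data
    ours = dice(ours_arr)

    def to_sitk(data, spacing):
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T, dtype=np.float64))
        img.SetSpacing(tuple(float(s) for s in spacing))
        return img

    sp = late.grid.spacing
    fixed_img = to_sitk(late.data, sp)
    moving_img = to_sitk(moving.data, sp)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=300)
    reg.SetInitialTransform(sitk.CenteredTransformInitializer(
        fixed_img, moving_img, sitk.Euler3DTransform()), inPlace=False)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([4.0, 2.0, 1.0])
    out = reg.Execute(fixed_img, moving_img)
    warped = sitk.Resample(to_sitk(mask_moving.data, sp), fixed_img, out,
                           sitk.sitkLinear, 0.0)
    theirs = dice(sitk.GetArrayFromImage(warped).T)
    assert ours >= theirs - 0.05
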