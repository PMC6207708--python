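"""Atlas construction, phantom identity, and cohort generators."""

import numpy as np
import pandas as pd
import pytest

import striaq as sq
import striaq.synthetic as syn
from striaq.imaging import default_grid, flip_label_volume
from striaq.quantify import extract_surs


class TestMakeAtlas:
    def test_label_census(self, atlas):
        assert len(atlas.names("target")) == 10
        assert atlas.names("reference_early") == ["pons"]
        assert atlas.names("reference_late") == ["occipital"]
        structures = {atlas.structure_of(n) for n in atlas.names("target")}
        assert structures == set(syn.ROI_STRUCTURES)

    def test_mirrored_voxel_counts(self, atlas):
        for s in syn.ROI_STRUCTURES:
            assert atlas.mask(f"{s}_left").sum() == atlas.mask(f"{s}_right").sum()

    def test_flip_maps_left_putamen_onto_right(self, atlas):
        flipped = flip_label_volume(atlas.labels, atlas.affine)
        left = atlas._by_name["posterior_putamen_left"]["label"]
        assert np.array_equal(flipped == left, atlas.mask("posterior_putamen_right"))

    def test_basal_ganglia_composite(self, atlas):
        bg = atlas.mask("basal_ganglia")
        expected = np.zeros_like(bg)
        for s in ("caudate", "anterior_putamen", "posterior_putamen"):
            expected |= atlas.mask(f"{s}_left") | atlas.mask(f"{s}_right")
        assert np.array_equal(bg, expected)

    def test_deterministic_and_optional_gp(self):
        a1 = sq.make_atlas()
        a2 = sq.make_atlas()
        assert np.array_equal(a1.labels, a2.labels)
        gp = sq.make_atlas(include_globus_pallidus=True)
        assert len(gp.names("target")) == 12

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            sq.make_atlas(default_grid((10, 10, 8)))


class TestSubjectImages:
    def test_construction_identity_noiseless(self, atlas, control_truth):
        early, late = syn.make_subject_images(control_truth, atlas)
        for vol, truth in ((early, control_truth.sur_early),
                           (late, control_truth.sur_late)):
            t = extract_surs(vol, atlas)
            err = max(abs(r.sur - truth[r.roi_name]) for r in t.itertuples())
            assert err < 1e-10

    def test_posterior_putamen_control_value(self, atlas, control_truth):
        _, late = syn.make_subject_images(control_truth, atlas)
        t = extract_surs(late, atlas).set_index("roi_name")
        assert t.loc["posterior_putamen_left", "sur"] == pytest.approx(5.21, abs=1e-9)

    def test_reference_regions_have_zero_sur(self, atlas, control_truth):
        from striaq.imaging import roi_mean
        from striaq.quantify import compute_sur

        _, late = syn.make_subject_images(control_truth, atlas)
        occ = roi_mean(late, atlas, "occipital")
        assert compute_sur(occ, occ) == 0.0
        bg = roi_mean(late, atlas, "occipital")
        assert late.data[atlas.mask("basal_ganglia")].mean() > bg  # control truth

    def test_negative_noise_rejected(self, control_truth):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(control_truth, noise_sd=-0.1)

    def test_rigid_offset_recovered(self, atlas, control_truth):
        import dataclasses

        from striaq.registration import register_rigid
        from striaq.transforms import RigidTransform, rigid_matrix

        off = RigidTransform(rigid_matrix([2.5, -1.5, 3.0, 2.0, -1.0, 1.5]))
        truth = dataclasses.replace(control_truth, late_offset=off)
        early, late = syn.make_subject_images(truth, atlas)
        res = register_rigid(early, late)
        # recovered early->late map should invert the late->early offset
        M = res.transform.matrix @ off.matrix
        assert np.linalg.norm(M[:3, 3]) < 1.5  # 0.5 voxel


class TestScalarCohort:
    def test_seed_determinism(self):
        a = syn.simulate_cohort_scalars(syn.CohortSpec(seed=3))
        b = syn.simulate_cohort_scalars(syn.CohortSpec(seed=3))
        pd.testing.assert_frame_equal(a.surs, b.surs)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        c = syn.simulate_cohort_scalars(syn.CohortSpec(seed=4))
        assert not a.surs["sur"].equals(c.surs["sur"])

    def test_moments_match_published_tables(self):
        spec = syn.CohortSpec(n_control=10000, n_pd=10000, seed=0)
        surs = syn.simulate_cohort_scalars(spec).surs
        for phase, table in (("early", syn.EARLY_PHASE_GROUP_SUR),
                             ("late", syn.LATE_PHASE_GROUP_SUR)):
            for group in ("control", "pd"):
                sub = surs[(surs.phase == phase) & (surs.group == group)]
                for (roi, side_label), (mean, sd) in table[group].items():
                    x = sub[(sub.roi == roi) & (sub.side_label == side_label)]["sur"]
                    assert abs(x.mean() - mean) < 3 * sd / np.sqrt(len(x))
                    assert abs(x.std(ddof=1) - sd) < 0.05 * sd

    def test_degenerate_sd_gives_constant_draws(self):
        group_sur = {
            phase: {g: {k: (m, 0.0) for k, (m, s) in t.items()}
                    for g, t in tables.items()}
            for phase, tables in (("early", syn.EARLY_PHASE_GROUP_SUR),
                                  ("late", syn.LATE_PHASE_GROUP_SUR))}
        spec = syn.CohortSpec(n_control=5, n_pd=5, group_sur=group_sur, seed=1)
        surs = syn.simulate_cohort_scalars(spec).surs
        late_c = surs[(surs.phase == "late") & (surs.group == "control")
                      & (surs.roi == "posterior_putamen")
                      & (surs.side_label == "contralateral")]
        assert np.allclose(late_c["sur"], 5.21)

    def test_unknown_roi_rejected(self):
        bad = {"early": {"control": {("thalamus", "contralateral"): (1.0, 0.1)},
                         "pd": {}}, "late": {"control": {}, "pd": {}}}
        with pytest.raises(ValueError, match="thalamus"):
            syn.CohortSpec(group_sur=bad)

    def test_updrs_only_for_patients(self):
        sc = syn.simulate_cohort_scalars(syn.CohortSpec(seed=2))
        subj = sc.subjects
        assert subj[subj.group == "pd"]["updrs3"].ge(1).all()
        assert subj[subj.group == "control"]["updrs3"].isna().all()


class TestImageCohort:
    def test_default_cohort_size(self, atlas):
        cohort = syn.simulate_cohort_images(syn.CohortSpec(seed=5), atlas)
        assert len(cohort) == 65
        groups = cohort.subjects_frame()["group"].value_counts()
        assert groups["control"] == 26 and groups["pd"] == 39

    def test_realize_is_deterministic(self, atlas):
        spec = syn.CohortSpec(n_control=1, n_pd=1, seed=6)
        c1 = syn.simulate_cohort_images(spec, atlas)
        c2 = syn.simulate_cohort_images(spec, atlas)
        e1, l1, s1 = c1.realize(c1.subjects[1])
        e2, l2, s2 = c2.realize(c2.subjects[1])
        assert np.array_equal(l1.data, l2.data)
        assert np.array_equal(e1.data, e2.data)
        assert np.array_equal(s1.data, s2.data)

    def test_seeds_change_transforms_not_distributions(self, atlas):
        spec_a = syn.CohortSpec(seed=10)
        spec_b = syn.CohortSpec(seed=11)
        ca = syn.simulate_cohort_images(spec_a, atlas)
        cb = syn.simulate_cohort_images(spec_b, atlas)
        ta = np.array([r.truth.transform.matrix[:3, 3] for r in ca.subjects])
        tb = np.array([r.truth.transform.matrix[:3, 3] for r in cb.subjects])
        assert not np.allclose(ta, tb)
        # same sampling distributions: translations uniform within +/-6 mm
        from scipy.stats import ks_2samp

        assert ks_2samp(ta.ravel(), tb.ravel()).pvalue > 0.01
        sa = ca.truth_table().query("phase=='late' and roi=='posterior_putamen'")
        sb = cb.truth_table().query("phase=='late' and roi=='posterior_putamen'")
        assert abs(sa.sur.mean() - sb.sur.mean()) < 0.5

    def test_out_of_field_transforms_rejected(self, atlas):
        ranges = syn.TransformRanges(max_translation_mm=80.0)
        spec = syn.CohortSpec(n_control=2, n_pd=2, ranges=ranges, seed=0)
        with pytest.raises(ValueError, match="out of field"):
            syn.simulate_cohort_images(spec, atlas)

    def test_contralateral_hemisphere_opposite_symptomatic_side(self, atlas):
        cohort = syn.simulate_cohort_images(syn.CohortSpec(seed=12), atlas)
        rec = next(r for r in cohort.subjects if r.symptomatic_side == "left")
        # left-onset: right hemisphere is contralateral
        key = ("posterior_putamen", "contralateral")
        drawn = rec.truth.sur_late["posterior_putamen_right"]
        tab = cohort.truth_table()
        row = tab[(tab.subject_id == rec.subject_id) & (tab.phase == "late")
                  & (tab.roi == key[0]) & (tab.side_label == key[1])]
        assert row["sur"].iloc[0] == pytest.approx(drawn)


def test_write_cohort_roundtrip(tmp_path, atlas):
    spec = syn.CohortSpec(n_control=1, n_pd=1, seed=8)
    cohort = syn.simulate_cohort_images(spec, atlas)
    syn.write_cohort(cohort, str(tmp_path))
    import json

    subj = pd.read_csv(tmp_path / "subjects.tsv", sep="\t")
    assert len(subj) == 2
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert set(truth) == set(subj["subject_id"])
    vol = sq.Volume.load(str(tmp_path / "P001_late.nii.gz"))
    assert vol.data.shape == atlas.grid.shape
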