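import numpy as np
import pytest

import striaq as sq
import striaq.synthetic as syn


@pytest.fixture(scope="session")
def atlas():
    return sq.make_atlas()


@pytest.fixture(scope="session")
def control_truth(atlas):
    """One noiseless control-like subject truth with identity transform."""
    sur_late, sur_early = {}, {}
    for name in atlas.names("target"):
        key = (atlas.structure_of(name),
               "contralateral" if atlas.side_of(name) == "left" else "ipsilateral")
        sur_late[name] = syn.LATE_PHASE_GROUP_SUR["control"][key][0]
        sur_early[name] = syn.EARLY_PHASE_GROUP_SUR["control"][key][0]
    return syn.SubjectTruth(sur_late=sur_late, sur_early=sur_early)


@pytest.fixture(scope="session")
def std_phantoms(atlas, control_truth):
    """Noise-free standard-space (early, late) images for the control truth."""
    return syn.truth_phantoms(control_truth, atlas)


@pytest.fixture(scope="session")
def study65():
    """The full 65-subject simulated image cohort through both pathways.

    Built once per session (it is the expensive fixture): default cohort
    conditions (26 controls + 39 PD, misalignment <= 6 mm / 6 deg, scale
    0.95-1.05, 5% noise) at the default 64x64x54 grid, fixed seed.
    """
    from striaq.pipeline import run_study

    spec = syn.CohortSpec(seed=7)
    atlas = sq.make_atlas()
    cohort = syn.simulate_cohort_images(spec, atlas)
    result = run_study(cohort)
    return cohort, result
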