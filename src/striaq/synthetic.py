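"""Synthetic phantom cohorts with known ground truth.

This module builds everything the quantification pipeline consumes, at desk
scale: a parametric ellipsoid ROI atlas (bilateral caudate, anterior and
posterior putamen, nucleus accumbens and substantia nigra, plus pons and
occipital reference regions), per-subject early/late/structural phantom image
triplets warped by known transforms, and scalar SUR cohorts drawn from the
published group distributions (26 controls, 39 Parkinson patients).

Uptake model: in standard space every ROI is piecewise constant with
``uptake = reference x (1 + SUR)``, so the specific uptake ratio of the
painted value against the phase's reference region is the ground truth by
construction. Images are warped to native space by a per-subject affine
(plus small rigid offsets between the early, late and structural frames),
then independent Gaussian noise with standard deviation expressed as a
fraction of the reference uptake is added.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import GridSpec, ROIAtlas, Volume, default_grid
from .transforms import (
    AffineTransform,
    DisplacementTransform,
    RigidTransform,
    affine_matrix_from_params,
    compose,
    identity,
    rigid_matrix,
)

__all__ = [
    "ROI_STRUCTURES",
    "EARLY_PHASE_GROUP_SUR",
    "LATE_PHASE_GROUP_SUR",
    "PhaseParams",
    "UpdrsLink",
    "TransformRanges",
    "CohortSpec",
    "SubjectTruth",
    "SubjectRecord",
    "Cohort",
    "ScalarCohort",
    "make_atlas",
    "paint_phantom",
    "make_subject_images",
    "make_structural_image",
    "make_standard_structural",
    "truth_phantoms",
    "simulate_cohort_scalars",
    "simulate_cohort_images",
    "write_cohort",
]

#: the five bilateral target structures
ROI_STRUCTURES = (
    "caudate",
    "anterior_putamen",
    "posterior_putamen",
    "nucleus_accumbens",
    "substantia_nigra",
)

# Ellipsoid placements (right-hemisphere center, semi-axes; mm, world RAS+).
# Left counterparts are exact mirrors about x=0. Placements are this
# package's own parametric anatomy, sized so all regions are disjoint on the
# default 3 mm grid while keeping roughly plausible relative positions.
_TARGET_ELLIPSOIDS = {
    "caudate": ((12.0, 12.0, 8.0), (4.0, 9.0, 8.0)),
    "anterior_putamen": ((23.0, 6.0, 0.0), (5.5, 7.5, 6.5)),
    "posterior_putamen": ((28.0, -10.0, 0.0), (5.5, 8.0, 6.5)),
    "nucleus_accumbens": ((9.0, 12.0, -8.0), (3.5, 4.5, 4.0)),
    "substantia_nigra": ((10.0, -18.0, -12.0), (3.5, 5.0, 4.0)),
}
_GLOBUS_PALLIDUS = ((14.0, -2.0, -2.0), (3.5, 5.0, 4.5))
_MIDLINE_ELLIPSOIDS = {
    "pons": ((0.0, -30.0, -28.0), (9.0, 11.0, 10.0)),
    "occipital": ((0.0, -68.0, 8.0), (38.0, 16.0, 22.0)),
}
_BRAIN_ELLIPSOID = ((0.0, -5.0, 0.0), (72.0, 88.0, 68.0))

#: painted uptake regions extend this far beyond the measurement labels, so
#: interpolation partial-volume at structure boundaries stays outside the ROI
DEFAULT_PAINT_MARGIN_MM = 4.0


def _ndist2(points: np.ndarray, center, axes) -> np.ndarray:
    """Squared normalized ellipsoid distance; <= 1 means inside."""
    c = np.asarray(center, dtype=float)[:, None]
    a = np.asarray(axes, dtype=float)[:, None]
    return (((points - c) / a) ** 2).sum(axis=0)


def atlas_ellipsoids(include_globus_pallidus: bool = False) -> dict:
    """ROI name -> (center, semi-axes) in mm, both hemispheres + midline."""
    out = {}
    structures = dict(_TARGET_ELLIPSOIDS)
    if include_globus_pallidus:
        structures["globus_pallidus"] = _GLOBUS_PALLIDUS
    for name, (c, a) in structures.items():
        out[f"{name}_right"] = ((c[0], c[1], c[2]), a)
        out[f"{name}_left"] = ((-c[0], c[1], c[2]), a)
    for name, (c, a) in _MIDLINE_ELLIPSOIDS.items():
        out[name] = (c, a)
    return out


def make_atlas(grid: GridSpec | None = None,
               include_globus_pallidus: bool = False) -> ROIAtlas:
    """Build the parametric ROI atlas on ``grid`` (default study grid).

    Ten mirrored target labels plus pons (early-phase reference) and
    occipital (late-phase reference). Construction is deterministic; any
    voxel claimed by two ellipsoids raises (guards against bad placements).
    An optional globus pallidus pair can be added; it is off by default
    because the quantified target set excludes it.
    """
    grid = grid or default_grid()
    pts = grid.voxel_centers()
    ellipsoids = atlas_ellipsoids(include_globus_pallidus)
    labels = np.zeros(int(np.prod(grid.shape)), dtype=np.int16)
    rows = []
    for i, (name, (c, a)) in enumerate(ellipsoids.items(), start=1):
        inside = _ndist2(pts, c, a) <= 1.0
        if not inside.any():
            raise ValueError(f"ROI {name!r} contains no voxels on this grid")
        clash = inside & (labels != 0)
        if clash.any():
            other = int(labels[clash][0])
            raise ValueError(f"ROI ellipsoids overlap: {name!r} and label {other}")
        labels[inside] = i
        if name in _MIDLINE_ELLIPSOIDS:
            side = "midline"
            role = "reference_early" if name == "pons" else "reference_late"
        else:
            side = "left" if name.endswith("_left") else "right"
            role = "target"
        rows.append({"label": i, "name": name, "side": side, "role": role})
    atlas = ROIAtlas(labels.reshape(grid.shape), grid.affine,
                     pd.DataFrame(rows))
    atlas.geometry = {
        "rois": ellipsoids,
        "brain": _BRAIN_ELLIPSOID,
        "paint_margin_mm": DEFAULT_PAINT_MARGIN_MM,
    }
    return atlas


def paint_phantom(atlas: ROIAtlas, roi_values: dict, background: float,
                  outside: float = 0.0, phase: str = "late") -> Volume:
    """Piecewise-constant phantom: brain background plus per-ROI values.

    Values are painted over slightly dilated ellipsoids (margin from the
    atlas geometry), with ties between adjacent dilated regions resolved by
    nearest normalized distance; measurement-label voxels always receive
    their own ROI's exact value, so ROI means over atlas labels reproduce
    the painted values exactly.
    """
    geom = getattr(atlas, "geometry", None)
    if geom is None:
        raise ValueError("atlas carries no ellipsoid geometry; build it with make_atlas")
    missing = [n for n in atlas.names() if n not in roi_values]
    if missing:
        raise KeyError(f"no painted value for ROIs: {missing}")
    grid = atlas.grid
    pts = grid.voxel_centers()
    bc, ba = geom["brain"]
    data = np.where(_ndist2(pts, bc, ba) <= 1.0, float(background), float(outside))
    margin = geom["paint_margin_mm"]
    names = atlas.names()
    best = np.full(data.shape, np.inf)
    claim = np.full(data.shape, -1, dtype=np.int32)
    for i, name in enumerate(names):
        c, a = geom["rois"][name]
        nd = _ndist2(pts, c, np.asarray(a) + margin)
        take = (nd <= 1.0) & (nd < best)
        best[take] = nd[take]
        claim[take] = i
    for i, name in enumerate(names):
        data[claim == i] = float(roi_values[name])
    # exact core: measurement labels override any dilation tie-break
    flat_labels = atlas.labels.reshape(-1)
    for _, row in atlas.table.iterrows():
        data[flat_labels == row["label"]] = float(roi_values[row["name"]])
    return Volume(data.reshape(grid.shape), grid.affine.copy(), phase)


# ---------------------------------------------------------------------------
# Phase parameters and subject truth


@dataclass(frozen=True)
class PhaseParams:
    """Reference uptakes and non-target tissue SURs for phantom painting.

    ``ref_early``/``ref_late`` are the absolute uptakes (arbitrary units) of
    the pons and occipital reference regions. Background and non-reference
    tissue are expressed as SURs against the phase reference: the early
    perfusion-like image has diffuse brain uptake, the late transporter
    image has background at the reference level (specific binding confined
    to the striatum and midbrain).
    """

    ref_early: float = 1.0
    ref_late: float = 1.0
    background_sur_early: float = 0.25
    occipital_sur_early: float = 0.2
    background_sur_late: float = 0.0
    pons_sur_late: float = 0.0
    structural_background: float = 1.0
    structural_nuclei: float = 1.35
    structural_pons: float = 1.1
    structural_occipital: float = 1.0


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject.

    ``transform`` maps native (early-frame) world coordinates to standard
    space; ``late_offset`` and ``struct_offset`` are small rigid maps from
    the late/structural frames into the early frame (inter-scan motion).
    Reference regions have true SUR 0 by construction.
    """

    sur_late: dict
    sur_early: dict
    transform: object = field(default_factory=identity)
    late_offset: RigidTransform = field(default_factory=identity)
    struct_offset: RigidTransform = field(default_factory=identity)
    symptomatic_side: str | None = None
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for d in (self.sur_late, self.sur_early):
            bad = {k: v for k, v in d.items() if v < -1}
            if bad:
                raise ValueError(f"SUR below -1 for {sorted(bad)}")


def _phase_values(atlas: ROIAtlas, surs: dict, phase: str,
                  params: PhaseParams) -> tuple[dict, float, float]:
    """(roi -> uptake, background uptake, reference uptake) for one phase."""
    if phase == "early":
        ref = params.ref_early
        bg = ref * (1 + params.background_sur_early)
        extra = {"pons": ref,
                 "occipital": ref * (1 + params.occipital_sur_early)}
    else:
        ref = params.ref_late
        bg = ref * (1 + params.background_sur_late)
        extra = {"pons": ref * (1 + params.pons_sur_late), "occipital": ref}
    values = dict(extra)
    for name in atlas.names("target"):
        values[name] = ref * (1 + surs[name])
    # any extra labels (e.g. optional globus pallidus) default to background
    for name in atlas.names():
        values.setdefault(name, bg)
    return values, bg, ref


def truth_phantoms(truth: SubjectTruth, atlas: ROIAtlas,
                   params: PhaseParams | None = None) -> tuple[Volume, Volume]:
    """Noise-free standard-space (early, late) images encoding the true SURs."""
    params = params or PhaseParams()
    ve, bg_e, _ = _phase_values(atlas, truth.sur_early, "early", params)
    vl, bg_l, _ = _phase_values(atlas, truth.sur_late, "late", params)
    early = paint_phantom(atlas, ve, bg_e, phase="early")
    late = paint_phantom(atlas, vl, bg_l, phase="late")
    return early, late


def make_subject_images(truth: SubjectTruth, atlas: ROIAtlas,
                        params: PhaseParams | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[Volume, Volume]:
    """Native-space (early, late) images for one subject.

    Standard-space truth phantoms are warped to the subject's native frames
    with a single trilinear resampling each (late frame differs from the
    early frame by the known rigid ``late_offset``), then Gaussian noise
    with sd = ``noise_sd x reference uptake`` is added voxelwise.
    """
    from .imaging import resample  # local import to avoid cycle at module load

    params = params or PhaseParams()
    std_early, std_late = truth_phantoms(truth, atlas, params)
    grid = atlas.grid
    early = resample(std_early, truth.transform, grid)
    late = resample(std_late, compose(truth.transform, truth.late_offset), grid)
    early.phase, late.phase = "early", "late"
    if truth.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        early = early.with_data(
            early.data + rng.normal(0, truth.noise_sd * params.ref_early, grid.shape))
        late = late.with_data(
            late.data + rng.normal(0, truth.noise_sd * params.ref_late, grid.shape))
    return early, late


def make_standard_structural(atlas: ROIAtlas,
                             params: PhaseParams | None = None) -> Volume:
    """Noise-free tissue-contrast phantom in standard space (the MRI stand-in
    normalization target, playing the role of the standard-space anatomy)."""
    params = params or PhaseParams()
    values = {"pons": params.structural_pons,
              "occipital": params.structural_occipital}
    for name in atlas.names():
        values.setdefault(name, params.structural_nuclei)
    vol = paint_phantom(atlas, values, params.structural_background,
                        phase="structural")
    return vol


def make_structural_image(truth: SubjectTruth, atlas: ROIAtlas,
                          params: PhaseParams | None = None) -> Volume:
    """Native-space structural image (noise-free, same anatomy)."""
    from .imaging import resample

    std = make_standard_structural(atlas, params)
    out = resample(std, compose(truth.transform, truth.struct_offset), atlas.grid)
    out.phase = "structural"
    return out


# ---------------------------------------------------------------------------
# Published group SUR distributions (mean, SD) per structure and laterality


EARLY_PHASE_GROUP_SUR = {
    "control": {
        ("caudate", "contralateral"): (1.35, 0.18),
        ("caudate", "ipsilateral"): (1.36, 0.18),
        ("anterior_putamen", "contralateral"): (1.78, 0.18),
        ("anterior_putamen", "ipsilateral"): (1.74, 0.18),
        ("posterior_putamen", "contralateral"): (1.71, 0.20),
        ("posterior_putamen", "ipsilateral"): (1.68, 0.20),
        ("nucleus_accumbens", "contralateral"): (1.54, 0.15),
        ("nucleus_accumbens", "ipsilateral"): (1.61, 0.16),
        ("substantia_nigra", "contralateral"): (1.25, 0.14),
        ("substantia_nigra", "ipsilateral"): (1.27, 0.13),
    },
    "pd": {
        ("caudate", "contralateral"): (1.18, 0.26),
        ("caudate", "ipsilateral"): (1.19, 0.24),
        ("anterior_putamen", "contralateral"): (1.57, 0.15),
        ("anterior_putamen", "ipsilateral"): (1.62, 0.16),
        ("posterior_putamen", "contralateral"): (1.17, 0.14),
        ("posterior_putamen", "ipsilateral"): (1.51, 0.14),
        ("nucleus_accumbens", "contralateral"): (1.62, 0.19),
        ("nucleus_accumbens", "ipsilateral"): (1.61, 0.17),
        ("substantia_nigra", "contralateral"): (1.16, 0.13),
        ("substantia_nigra", "ipsilateral"): (1.19, 0.13),
    },
}

LATE_PHASE_GROUP_SUR = {
    "control": {
        ("caudate", "contralateral"): (4.03, 0.64),
        ("caudate", "ipsilateral"): (4.08, 0.66),
        ("anterior_putamen", "contralateral"): (4.99, 0.73),
        ("anterior_putamen", "ipsilateral"): (4.89, 0.74),
        ("posterior_putamen", "contralateral"): (5.21, 0.92),
        ("posterior_putamen", "ipsilateral"): (5.11, 0.89),
        ("nucleus_accumbens", "contralateral"): (3.80, 0.54),
        ("nucleus_accumbens", "ipsilateral"): (3.96, 0.52),
        ("substantia_nigra", "contralateral"): (2.58, 0.29),
        ("substantia_nigra", "ipsilateral"): (2.63, 0.33),
    },
    "pd": {
        ("caudate", "contralateral"): (2.67, 0.94),
        ("caudate", "ipsilateral"): (3.11, 1.04),
        ("anterior_putamen", "contralateral"): (2.29, 0.46),
        ("anterior_putamen", "ipsilateral"): (2.77, 0.76),
        ("posterior_putamen", "contralateral"): (1.76, 0.33),
        ("posterior_putamen", "ipsilateral"): (2.06, 0.70),
        ("nucleus_accumbens", "contralateral"): (3.66, 0.73),
        ("nucleus_accumbens", "ipsilateral"): (3.87, 0.74),
        ("substantia_nigra", "contralateral"): (2.03, 0.30),
        ("substantia_nigra", "ipsilateral"): (2.17, 0.35),
    },
}


@dataclass(frozen=True)
class UpdrsLink:
    """Log-linear link from contralateral anterior-putamen late SUR to UPDRS-III.

    UPDRS-III = round(exp(intercept - slope*SUR + eps)), eps ~ N(0, noise_sd),
    clipped to >= 1. Defaults are calibrated so the simulated R^2 between
    log-UPDRS-III and the linked SUR is ~0.3 while the UPDRS-III marginal
    distribution roughly matches the published cohort (16.2 +/- 14.1).
    """

    slope: float = 1.07
    intercept: float = 4.85
    noise_sd: float = 0.75
    linked_structure: str = "anterior_putamen"

    def sample_updrs3(self, sur: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        sur = np.asarray(sur, dtype=float)
        eps = rng.normal(0.0, self.noise_sd, sur.shape)
        u = np.exp(self.intercept - self.slope * sur + eps)
        return np.maximum(np.rint(u), 1.0).astype(int)


@dataclass(frozen=True)
class TransformRanges:
    """Per-subject misalignment sampling ranges (uniform, symmetric)."""

    max_translation_mm: float = 6.0
    max_rotation_deg: float = 6.0
    scale_range: tuple = (0.95, 1.05)
    offset_translation_mm: float = 3.0
    offset_rotation_deg: float = 3.0
    deformation_amp_mm: float = 0.0  # optional smooth truth warp, off by default
    deformation_scale_mm: float = 15.0


@dataclass
class CohortSpec:
    """Study-cohort description: sizes, group SUR distributions, links, seed."""

    n_control: int = 26
    n_pd: int = 39
    group_sur: dict = field(default_factory=lambda: {
        "early": EARLY_PHASE_GROUP_SUR, "late": LATE_PHASE_GROUP_SUR})
    updrs_link: UpdrsLink = field(default_factory=UpdrsLink)
    noise_sd: float = 0.05
    ranges: TransformRanges = field(default_factory=TransformRanges)
    control_pseudo_side: str = "right"  # controls' nominal symptomatic side
    phase_params: PhaseParams = field(default_factory=PhaseParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_control <= 0 or self.n_pd <= 0:
            raise ValueError("group sizes must be positive")
        for phase, groups in self.group_sur.items():
            for group, table in groups.items():
                for (structure, side_label), (mean, sd) in table.items():
                    if structure not in ROI_STRUCTURES:
                        raise ValueError(
                            f"unknown ROI structure {structure!r} in spec ({phase}/{group})")
                    if sd < 0:
                        raise ValueError("SUR standard deviation must be >= 0")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    symptomatic_side: str
    updrs1: float | None
    updrs2: float | None
    updrs3: float | None
    hoehn_yahr: float | None
    truth: SubjectTruth


@dataclass
class ScalarCohort:
    """Scalar SUR draws plus the subject table (no images)."""

    surs: pd.DataFrame
    subjects: pd.DataFrame


def _draw_subject_surs(spec: CohortSpec, group: str, phase: str,
                       rng: np.random.Generator) -> dict:
    """(structure, side_label) -> one Gaussian SUR draw."""
    table = spec.group_sur[phase][group]
    return {
        key: float(np.maximum(rng.normal(mean, sd), -0.999))
        for key, (mean, sd) in table.items()
    }


def _clinical_scores(group: str, sur_contra_ap: float, link: UpdrsLink,
                     rng: np.random.Generator) -> dict:
    if group != "pd":
        return {"updrs1": None, "updrs2": None, "updrs3": None, "hoehn_yahr": None}
    u3 = int(link.sample_updrs3(np.array([sur_contra_ap]), rng)[0])
    u2 = int(np.clip(np.rint(0.45 * u3 + rng.normal(0, 2.0)), 0, None))
    u1 = int(np.clip(np.rint(rng.normal(1.2, 1.4)), 0, None))
    hy = int(np.clip(1 + (u3 > 10) + (u3 > 25) + (u3 > 40) + (u3 > 55), 1, 5))
    return {"updrs1": u1, "updrs2": u2, "updrs3": u3, "hoehn_yahr": hy}


def _subject_ids(spec: CohortSpec):
    ids = [(f"C{i + 1:03d}", "control") for i in range(spec.n_control)]
    ids += [(f"P{i + 1:03d}", "pd") for i in range(spec.n_pd)]
    return ids


def simulate_cohort_scalars(spec: CohortSpec | None = None,
                            seed: int | None = None) -> ScalarCohort:
    """Draw per-subject scalar SURs for every ROI x laterality x phase.

    Each subject contributes one Gaussian draw per (structure, side label,
    phase) from their group's distribution; PD subjects get UPDRS scores via
    the log-linear link on their contralateral anterior-putamen late SUR.
    Fully reproducible under the spec seed.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sur_rows, subj_rows = [], []
    for sid, group in _subject_ids(spec):
        side = (spec.control_pseudo_side if group == "control"
                else ("left", "right")[rng.integers(2)])
        draws = {phase: _draw_subject_surs(spec, group, phase, rng)
                 for phase in ("early", "late")}
        for phase, d in draws.items():
            for (structure, side_label), sur in d.items():
                sur_rows.append({
                    "subject_id": sid, "group": group, "roi": structure,
                    "side_label": side_label, "phase": phase, "sur": sur,
                })
        link_sur = draws["late"][(spec.updrs_link.linked_structure, "contralateral")]
        scores = _clinical_scores(group, link_sur, spec.updrs_link, rng)
        subj_rows.append({"subject_id": sid, "group": group,
                          "symptomatic_side": side, **scores})
    return ScalarCohort(pd.DataFrame(sur_rows), pd.DataFrame(subj_rows))


def _random_rigid(rng, max_t, max_r) -> RigidTransform:
    p = np.concatenate([rng.uniform(-max_t, max_t, 3),
                        rng.uniform(-max_r, max_r, 3)])
    return RigidTransform(rigid_matrix(p))


def _random_affine(rng, ranges: TransformRanges) -> AffineTransform:
    p = np.concatenate([
        rng.uniform(-ranges.max_translation_mm, ranges.max_translation_mm, 3),
        rng.uniform(-ranges.max_rotation_deg, ranges.max_rotation_deg, 3),
        rng.uniform(*ranges.scale_range, 3),
        np.zeros(3),
    ])
    return AffineTransform(affine_matrix_from_params(p))


def _random_deformation(rng, grid: GridSpec, amp_mm: float,
                        scale_mm: float) -> DisplacementTransform:
    from scipy.ndimage import gaussian_filter

    sigma_vox = scale_mm / grid.spacing
    f = rng.normal(0, 1, (3,) + grid.shape)
    for i in range(3):
        f[i] = gaussian_filter(f[i], sigma=sigma_vox, mode="constant")
    mag = np.sqrt((f ** 2).sum(axis=0)).max()
    f *= amp_mm / max(mag, 1e-12)
    return DisplacementTransform(f, grid.affine)


def _hemisphere_for(side_label: str, symptomatic_side: str) -> str:
    """Contralateral = hemisphere opposite the symptomatic body side."""
    opposite = {"left": "right", "right": "left"}
    return opposite[symptomatic_side] if side_label == "contralateral" else symptomatic_side


def _surs_by_roi_name(draws: dict, symptomatic_side: str) -> dict:
    """Map (structure, side_label) draws onto concrete atlas ROI names."""
    out = {}
    for (structure, side_label), sur in draws.items():
        hemi = _hemisphere_for(side_label, symptomatic_side)
        out[f"{structure}_{hemi}"] = sur
    return out


@dataclass
class Cohort:
    """Simulated image cohort: subject records with lazily realized images.

    Images are deterministic per subject (seeds split from the cohort seed),
    so ``realize`` may be called in any order or repeatedly.
    """

    spec: CohortSpec
    atlas: ROIAtlas
    subjects: list
    _noise_seeds: list

    def __len__(self) -> int:
        return len(self.subjects)

    def realize(self, record: SubjectRecord) -> tuple[Volume, Volume, Volume]:
        """(early, late, structural) native images for one subject."""
        i = next(i for i, r in enumerate(self.subjects)
                 if r.subject_id == record.subject_id)
        rng = np.random.default_rng(self._noise_seeds[i])
        early, late = make_subject_images(record.truth, self.atlas,
                                          self.spec.phase_params, rng)
        structural = make_structural_image(record.truth, self.atlas,
                                           self.spec.phase_params)
        return early, late, structural

    def subjects_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"subject_id": r.subject_id, "group": r.group,
             "symptomatic_side": r.symptomatic_side, "updrs1": r.updrs1,
             "updrs2": r.updrs2, "updrs3": r.updrs3,
             "hoehn_yahr": r.hoehn_yahr}
            for r in self.subjects
        ])

    def truth_table(self) -> pd.DataFrame:
        """Long table of true SURs per subject, ROI, laterality and phase."""
        rows = []
        for r in self.subjects:
            for phase, surs in (("early", r.truth.sur_early),
                                ("late", r.truth.sur_late)):
                for roi, sur in surs.items():
                    hemi = self.atlas.side_of(roi)
                    side_label = ("contralateral"
                                  if hemi != r.symptomatic_side else "ipsilateral")
                    rows.append({"subject_id": r.subject_id, "group": r.group,
                                 "roi": self.atlas.structure_of(roi),
                                 "side_label": side_label, "phase": phase,
                                 "sur": sur})
        return pd.DataFrame(rows)


def simulate_cohort_images(spec: CohortSpec | None = None,
                           atlas: ROIAtlas | None = None,
                           seed: int | None = None) -> Cohort:
    """Simulate the image cohort: subject truths, transforms and clinical scores.

    Per-subject misalignments are drawn from the configured ranges
    (translation <= 6 mm, rotation <= 6 deg, anisotropic scale 0.95-1.05 by
    default; an optional smooth truth deformation can be enabled through
    ``spec.ranges.deformation_amp_mm``). Raises if a drawn transform would
    push the striatum out of the field of view.
    """
    spec = spec or CohortSpec()
    atlas = atlas if atlas is not None else make_atlas()
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    rng = np.random.default_rng(root)
    noise_seeds = [s.generate_state(1)[0] % (2 ** 31)
                   for s in root.spawn(spec.n_control + spec.n_pd)]
    grid = atlas.grid
    lo = grid.affine[:3, 3]
    hi = lo + (np.asarray(grid.shape) - 1) * grid.spacing
    subjects = []
    for sid, group in _subject_ids(spec):
        side = (spec.control_pseudo_side if group == "control"
                else ("left", "right")[rng.integers(2)])
        draws = {phase: _draw_subject_surs(spec, group, phase, rng)
                 for phase in ("early", "late")}
        affine = _random_affine(rng, spec.ranges)
        xform = affine
        if spec.ranges.deformation_amp_mm > 0:
            disp = _random_deformation(rng, grid, spec.ranges.deformation_amp_mm,
                                       spec.ranges.deformation_scale_mm)
            xform = compose(disp, affine)
        # striatum must stay in-field in native space: check inverse images
        # of standard-space target centers under the (invertible) affine part
        centers = np.array([atlas.geometry["rois"][n][0]
                            for n in atlas.names("target")]).T
        native = affine.inverse()(centers)
        if np.any(native < lo[:, None] + 3) or np.any(native > hi[:, None] - 3):
            raise ValueError(
                f"transform ranges push the striatum out of field for {sid}")
        truth = SubjectTruth(
            sur_late=_surs_by_roi_name(draws["late"], side),
            sur_early=_surs_by_roi_name(draws["early"], side),
            transform=xform,
            late_offset=_random_rigid(rng, spec.ranges.offset_translation_mm,
                                      spec.ranges.offset_rotation_deg),
            struct_offset=_random_rigid(rng, spec.ranges.offset_translation_mm,
                                        spec.ranges.offset_rotation_deg),
            symptomatic_side=side,
            noise_sd=spec.noise_sd,
        )
        link_sur = draws["late"][(spec.updrs_link.linked_structure, "contralateral")]
        scores = _clinical_scores(group, link_sur, spec.updrs_link, rng)
        subjects.append(SubjectRecord(sid, group, side, truth=truth, **scores))
    return Cohort(spec, atlas, subjects, noise_seeds)


def write_cohort(cohort: Cohort, out_dir: str) -> None:
    """Write the cohort as NIfTI volumes plus subjects.tsv and truth.json."""
    os.makedirs(out_dir, exist_ok=True)
    cohort.subjects_frame().to_csv(os.path.join(out_dir, "subjects.tsv"),
                                   sep="\t", index=False)
    truth = {}
    for rec in cohort.subjects:
        early, late, structural = cohort.realize(rec)
        for vol, tag in ((early, "early"), (late, "late"),
                         (structural, "structural")):
            vol.save(os.path.join(out_dir, f"{rec.subject_id}_{tag}.nii.gz"))
        t = rec.truth
        entry = {"sur_late": t.sur_late, "sur_early": t.sur_early,
                 "symptomatic_side": t.symptomatic_side,
                 "noise_sd": t.noise_sd}
        if isinstance(t.transform, AffineTransform):
            entry["transform"] = t.transform.to_json_dict()
        truth[rec.subject_id] = entry
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
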