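"""Specific uptake ratio (SUR) extraction and laterality assignment.

SUR = (target uptake - reference uptake) / reference uptake, with the pons
as the early-phase reference and the whole occipital region as the
late-phase reference. Laterality follows the clinical convention: the
hemisphere opposite the symptomatic onset side is "contralateral".
"""

from __future__ import annotations

import pandas as pd

from .imaging import ROIAtlas, Volume, roi_mean

__all__ = ["compute_sur", "extract_surs", "lateralize", "subject_sur_table",
           "SUR_COLUMNS"]

SUR_COLUMNS = ("subject_id", "group", "roi", "side_label", "phase", "sur")


def compute_sur(target_mean: float, ref_mean: float) -> float:
    """(target - reference) / reference; requires a positive reference."""
    if ref_mean <= 0:
        raise ValueError(f"reference uptake must be positive, got {ref_mean}")
    return (target_mean - ref_mean) / ref_mean


def extract_surs(vol: Volume, atlas: ROIAtlas, phase: str | None = None) -> pd.DataFrame:
    """One SUR per target ROI of a standard-space image.

    Columns: roi (structure), side (hemisphere), roi_name, phase, sur.
    The reference region is chosen by phase (pons early, occipital late);
    structural images have no reference and are refused.
    """
    phase = phase or vol.phase
    if phase not in ("early", "late"):
        raise ValueError(f"cannot extract SURs for phase {phase!r}")
    ref_roi = atlas.reference_roi(phase)
    ref = roi_mean(vol, atlas, ref_roi)
    if ref <= 0:
        raise ValueError(f"reference region {ref_roi!r} has non-positive mean {ref}")
    rows = []
    for name in atlas.names("target"):
        sur = compute_sur(roi_mean(vol, atlas, name), ref)
        rows.append({"roi": atlas.structure_of(name), "side": atlas.side_of(name),
                     "roi_name": name, "phase": phase, "sur": sur})
    return pd.DataFrame(rows)


def lateralize(rows: pd.DataFrame, symptomatic_side: str) -> pd.DataFrame:
    """Label each hemisphere ROI contralateral/ipsilateral to symptom onset.

    The hemisphere opposite the symptomatic hand is contralateral (a
    right-hand-onset patient's left-hemisphere putamen is contralateral).
    Controls get a configured pseudo-side upstream. Recomputing the labels
    is idempotent because they derive from the immutable ``side`` column.
    """
    if symptomatic_side not in ("left", "right"):
        raise ValueError(f"symptomatic side must be left/right, got {symptomatic_side!r}")
    if "side" not in rows.columns:
        raise ValueError("rows lack the hemisphere 'side' column")
    if rows["side"].isna().any():
        raise ValueError("missing side annotation on some rows")
    out = rows.copy()

    def label(side: str) -> str:
        if side == "midline":
            return "midline"
        return "ipsilateral" if side == symptomatic_side else "contralateral"

    out["side_label"] = out["side"].map(label)
    return out


def subject_sur_table(vols: dict, atlas: ROIAtlas, symptomatic_side: str,
                      subject_id: str, group: str) -> pd.DataFrame:
    """Long SUR table for one subject from phase-tagged standard-space images."""
    parts = []
    for phase, vol in vols.items():
        t = lateralize(extract_surs(vol, atlas, phase), symptomatic_side)
        t["subject_id"], t["group"] = subject_id, group
        parts.append(t)
    table = pd.concat(parts, ignore_index=True)
    return table[list(SUR_COLUMNS) + ["side", "roi_name"]]
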