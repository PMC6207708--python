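"""Simulate one subject and verify SUR quantification against its truth.

Builds a control-like subject whose late-phase uptake follows the healthy
group means, warps it to a misaligned native frame, adds 5% noise, then
runs the MRI-based (traditional) pathway and compares the extracted SURs
with the simulation ground truth. The printed relative errors show how
much the registration chain costs on top of the exact construction.
"""

import numpy as np

import striaq as sq
import striaq.synthetic as syn
from striaq.pipeline import run_traditional

atlas = sq.make_atlas()
spec = syn.CohortSpec(n_control=1, n_pd=1, seed=42)
cohort = syn.simulate_cohort_images(spec, atlas)
rec = cohort.subjects[0]
early, late, structural = cohort.realize(rec)
std_struct = syn.make_standard_structural(atlas)

run = run_traditional(early, late, structural, atlas, std_struct,
                      rec.subject_id, rec.group, rec.symptomatic_side)
truth = cohort.truth_table()
m = run.rows.merge(truth, on=["subject_id", "roi", "side_label", "phase"],
                   suffixes=("", "_true"))
m = m[m.phase == "late"]

print(f"subject {rec.subject_id} ({rec.group}), "
      f"symptomatic side {rec.symptomatic_side}, converged={run.converged}")
print(f"{'ROI':20s} {'later.':14s} {'SUR':>7s} {'truth':>7s} {'rel err':>8s}")
for r in m.itertuples():
    rel = (r.sur - r.sur_true) / r.sur_true
    print(f"{r.roi:20s} {r.side_label:14s} {r.sur:7.3f} {r.sur_true:7.3f} "
          f"{100 * rel:7.2f}%")
print("\nmedian |rel err| = "
      f"{100 * np.median(np.abs((m.sur - m.sur_true) / m.sur_true)):.2f}% "
      "(sub-percent errors mean the three-stage chain preserved the truth)")
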