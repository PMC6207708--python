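"""Compare the MRI-based and template-based normalization pathways.

Simulates a small image cohort (6 controls + 6 PD), runs the traditional
chain on every subject, builds the transporter-specific late-phase template
from the normalized controls, runs the direct template pathway, and prints
the per-region Spearman agreement plus the paired-difference bias. The
negative correlation between bias and baseline SUR reproduces the key
caveat of the template route: low-uptake putamina are pulled toward the
normal-control template, inflating their SURs.

Takes a couple of minutes (about five registration stages per subject);
scale n_control/n_pd up for smoother statistics.
"""

import numpy as np

import striaq as sq
import striaq.synthetic as syn
from striaq.pipeline import run_study
from striaq.stats import paired_difference, pathway_agreement

atlas = sq.make_atlas()
spec = syn.CohortSpec(n_control=6, n_pd=6, seed=3)
cohort = syn.simulate_cohort_images(spec, atlas)
res = run_study(cohort)

late_trad = res.sur_traditional.query("phase == 'late'")
agree = pathway_agreement(late_trad, res.sur_template)
print("Spearman agreement between pathways (late phase):")
print(agree[["roi", "side_label", "rho", "p"]].to_string(index=False))

d = paired_difference(late_trad, res.sur_template)
put = d[d.roi.str.contains("putamen")]
r = np.corrcoef(put["baseline"], put["diff"])[0, 1]
low = put[put.baseline < put.baseline.median()]
print(f"\nputaminal bias (template - traditional): "
      f"corr(bias, baseline) = {r:.2f}")
print(f"low-baseline rows: mean bias = {low['diff'].mean():+.3f} SUR, "
      f"{100 * (low['diff'] > 0).mean():.0f}% positive "
      "(the template route over-estimates degenerated putamina)")
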