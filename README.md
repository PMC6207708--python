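# striaq

Automated quantification of striatal VMAT2 PET uptake, built as a fully
testable pipeline on synthetic phantom cohorts.

Dopaminergic degeneration in Parkinson's disease (PD) is measured in vivo
with tracers such as ¹⁸F-DTBZ that bind the vesicular monoamine
transporter (VMAT2) in the striatum. The standard readout is the specific
uptake ratio of a target region against a reference region,

    SUR = (target uptake − reference uptake) / reference uptake,

with the pons as reference for early-phase (perfusion-like) frames and the
occipital region for late-phase (transporter-specific) frames. Automating
the analysis requires warping every subject's late-phase image into a
common standard space — and the route taken matters, because late-phase
binding is confined to the striatum, which makes direct PET-to-MRI
coregistration by intensity matching unreliable.

`striaq` implements and compares the two routes:

- **traditional (MRI-based)** — rigid late→early coregistration, affine
  early→structural coregistration, nonlinear structural→standard
  normalization; the composed transform is applied to the late image with
  a single interpolation;
- **template-based** — direct normalization of the native late image to a
  transporter-specific late-phase template built from the normalized
  control scans (basal-ganglia mean scaled to 1 so each control
  contributes equally, then averaged and smoothed).

Around these sit a 6/12-DOF + demons-style SSD registration engine, a
parametric striatal ROI atlas (bilateral caudate, anterior/posterior
putamen, nucleus accumbens, substantia nigra; pons and occipital
references), SUR extraction with contralateral/ipsilateral labelling, a
synthetic cohort generator seeded by published group distributions
(26 controls, 39 PD), and the study statistics: Mann–Whitney ROC/AUC,
Welch t-tests, chi-square, Spearman method agreement, log-UPDRS-III motor
regression and sigmoid fits, and paired-difference bias analysis. It is a
library for Python users — see `examples/` for narrative scripts — with
NIfTI + TSV/JSON serialization for volumes, atlases, transforms and SUR
tables.

## Worked example

```python
import striaq as sq
import striaq.synthetic as syn
from striaq.pipeline import run_study
from striaq.stats import pathway_agreement

atlas = sq.make_atlas()                       # 64x64x54 @ 3 mm study atlas
spec = syn.CohortSpec(n_control=6, n_pd=6, seed=3)
cohort = syn.simulate_cohort_images(spec, atlas)
res = run_study(cohort)                       # both pathways, one template
agree = pathway_agreement(
    res.sur_traditional.query("phase == 'late'"), res.sur_template)
print(agree[["roi", "side_label", "rho"]].to_string(index=False))
```

prints (seed 3, default misalignment ≤ 6 mm / 6°, 5% noise):

```
              roi    side_label      rho
 anterior_putamen contralateral 0.951049
 anterior_putamen   ipsilateral 0.923077
          caudate contralateral 0.993007
          caudate   ipsilateral 0.937063
nucleus_accumbens contralateral 0.664336
nucleus_accumbens   ipsilateral 0.720280
posterior_putamen contralateral 0.930070
posterior_putamen   ipsilateral 0.972028
 substantia_nigra contralateral 0.783217
 substantia_nigra   ipsilateral 0.636364
```

Each ρ is the Spearman rank correlation across subjects between the two
pathways' SURs for one region: the caudate and putamen agree strongly even
at n = 12, while the small nucleus accumbens is among the least stable —
the same ordering the clinical comparison reports (at the full 65-subject
cohort the caudate/putamen correlations exceed 0.9). `examples/compare_pathways.py` extends
this with the paired-difference bias, showing that the template route
systematically over-estimates low-uptake putamina (its nonlinear stage
pulls degenerated putamina toward the normal-control template).

The other examples: `build_atlas.py` (atlas layout and ROI volumes),
`simulate_subject.py` (single-subject truth recovery through the
traditional chain), `cohort_statistics.py` (t-tests, AUCs and the motor
regression on a scalar cohort).

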