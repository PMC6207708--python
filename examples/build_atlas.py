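"""Build the parametric striatal ROI atlas and inspect its layout.

Creates the 64x64x54 @ 3 mm study atlas: ten mirrored target ellipsoids
(caudate, anterior/posterior putamen, nucleus accumbens, substantia nigra,
each bilateral), the pons (early-phase reference) and the occipital region
(late-phase reference). Prints each ROI's voxel count and volume; the
printed left/right counts are identical because the atlas is an exact
mirror about the midsagittal plane.
"""

import numpy as np

import striaq as sq

atlas = sq.make_atlas()
voxel_ml = np.prod(atlas.grid.spacing) / 1000.0

print(f"grid {atlas.grid.shape} @ {atlas.grid.spacing[0]:.0f} mm")
print(f"{'ROI':28s} {'side':8s} {'role':16s} {'voxels':>7s} {'ml':>7s}")
for _, row in atlas.table.iterrows():
    n = int(atlas.mask(row["name"]).sum())
    print(f"{row['name']:28s} {row['side']:8s} {row['role']:16s} "
          f"{n:7d} {n * voxel_ml:7.2f}")

bg = atlas.mask("basal_ganglia")
print(f"\nbasal-ganglia composite (caudate + putamen): "
      f"{int(bg.sum())} voxels, {bg.sum() * voxel_ml:.2f} ml")
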