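"""Transporter-specific late-phase PET template construction.

The template is the voxelwise mean of spatially normalized control scans,
each first divided by its mean uptake over the basal-ganglia mask so that
every control contributes equally, then Gaussian-smoothed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .imaging import GridSpec, ROIAtlas, Volume, default_grid, gaussian_smooth, roi_mean

__all__ = ["TemplateSpec", "normalize_basal_ganglia", "build_template",
           "save_template"]


@dataclass(frozen=True)
class TemplateSpec:
    control_ids: tuple = ()
    smoothing_fwhm_mm: float = 4.0
    grid: GridSpec = field(default_factory=default_grid)

    def __post_init__(self):
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be >= 0")


def normalize_basal_ganglia(vol: Volume, atlas: ROIAtlas) -> Volume:
    """Divide the image by its basal-ganglia mean so that mean becomes 1.

    The basal ganglia mask is the union of the bilateral caudate and
    anterior/posterior putamen labels. Idempotent, and invariant to global
    intensity scaling of the input.
    """
    bg = _bg_mean(vol, atlas)
    out = vol.with_data(vol.data / bg)
    out.phase = vol.phase
    return out


def _bg_mean(vol: Volume, atlas: ROIAtlas) -> float:
    mask = atlas.mask("basal_ganglia")
    if vol.data.shape != mask.shape or not np.allclose(vol.affine, atlas.affine):
        raise ValueError("volume grid does not match atlas grid")
    m = float(vol.data[mask].mean())
    if m <= 0:
        raise ValueError(f"basal-ganglia mean must be positive, got {m}")
    return m


def build_template(controls: list, atlas: ROIAtlas,
                   spec: TemplateSpec | None = None) -> Volume:
    """Average basal-ganglia-normalized controls and smooth.

    Requires at least two controls, all on the standard grid. Permutation of
    the control order changes nothing (the voxelwise mean is symmetric), and
    each subject's contribution is exactly 1/N of its normalized image.
    """
    spec = spec or TemplateSpec()
    if len(controls) < 2:
        raise ValueError("template construction needs at least 2 controls")
    grid = spec.grid
    normalized = []
    for vol in controls:
        if vol.data.shape != grid.shape or not np.allclose(vol.affine, grid.affine):
            raise ValueError("control volume is not on the template grid")
        normalized.append(np.asarray(normalize_basal_ganglia(vol, atlas).data,
                                     dtype=float))
    # canonical accumulation order + extended precision make the voxelwise
    # mean bit-reproducible under any permutation of the control list
    normalized.sort(key=lambda a: a.tobytes())
    acc = np.zeros(grid.shape, dtype=np.longdouble)
    for a in normalized:
        acc += a
    mean = Volume((acc / len(controls)).astype(float), grid.affine.copy(),
                  "template")
    out = gaussian_smooth(mean, spec.smoothing_fwhm_mm)
    out.phase = "template"
    return out


def save_template(template: Volume, path: str, spec: TemplateSpec,
                  provenance_path: str | None = None, seed: int | None = None) -> None:
    template.save(path)
    if provenance_path:
        with open(provenance_path, "w") as fh:
            json.dump({"control_ids": list(spec.control_ids),
                       "smoothing_fwhm_mm": spec.smoothing_fwhm_mm,
                       "seed": seed}, fh, indent=1)
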