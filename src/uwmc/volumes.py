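"""Lobar WMH volume and ICV normalisation.

The comparator measurement for UWMC: lesion volume per bilateral lobe in
mm^3 (voxel count x voxel volume, with voxel volume = |det| of the affine's
3x3 block), each divided by intracranial volume to remove head-size
differences.  Lesion voxels falling outside the four lobes are tallied
under "other" rather than dropped.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import BinaryMask, LabelVolume, check_same_grid

__all__ = ["WmhVolumeSummary", "lobar_wmh_volume"]


@dataclasses.dataclass
class WmhVolumeSummary:
    per_lobe_mm3: dict[str, float]
    icv_mm3: float
    per_lobe_normalized: dict[str, float]
    #: optional multiplier applied to normalized ratios for display only
    display_multiplier: float = 1.0

    def displayed(self) -> dict[str, float]:
        return {k: v * self.display_multiplier for k, v in self.per_lobe_normalized.items()}


def lobar_wmh_volume(
    wmh: BinaryMask,
    lobe_labels: LabelVolume,
    icv_mask: BinaryMask,
    display_multiplier: float = 1.0,
) -> WmhVolumeSummary:
    """Per-lobe WMH volume (mm^3) and ICV-normalised unitless ratios."""
    check_same_grid(wmh, lobe_labels, icv_mask)
    voxel_mm3 = float(abs(np.linalg.det(np.asarray(wmh.affine)[:3, :3])))
    icv_mm3 = icv_mask.n_true * voxel_mm3
    if icv_mm3 == 0:
        raise ValueError("ICV mask is empty")

    by_id = lobe_labels.by_id
    lobes = sorted({rec.lobe for rec in lobe_labels.table} | {"other"})
    per_lobe = {lobe: 0.0 for lobe in lobes}
    lesion_labels = lobe_labels.data[wmh.data]
    ids, counts = np.unique(lesion_labels, return_counts=True)
    for lab, n in zip(ids.tolist(), counts.tolist()):
        lobe = by_id[lab].lobe if lab != 0 else "other"
        per_lobe[lobe] += n * voxel_mm3
    normalized = {lobe: v / icv_mm3 for lobe, v in per_lobe.items()}
    return WmhVolumeSummary(per_lobe, icv_mm3, normalized, display_multiplier)
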