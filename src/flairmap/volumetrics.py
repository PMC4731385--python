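"""Headline measurements: T2LV, lesion filling, and ICV normalization.

T2 lesion volume (T2LV) is reported as a percentage of brain volume, where
brain volume is the WM + GM tissue labels united with the final lesion voxels
(lesions are brain tissue; CSF is excluded). Lesion filling relabels detected
lesion voxels as white matter before tissue volumes are read off, restoring
WM volume that the intensity model misclassified because of the lesions.
Volumes are made comparable across head sizes by scaling with the ratio of a
standard intracranial volume to the subject's, yielding "normalized mm^3"
(a volume measure in standard rather than subject space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lesion_extraction import LesionComponentSet
from .tissue_segmentation import LABEL_GM, LABEL_WM, TissueSegmentation, tissue_volumes

__all__ = ["T2LVResult", "compute_t2lv", "fill_lesions", "normalize_volume"]


@dataclass
class T2LVResult:
    """Final lesion burden plus the bookkeeping needed to audit the run."""

    lesion_volume_mm3: float
    brain_volume_mm3: float
    t2lv_percent: float
    n_components_final: int
    stage_counts: dict = field(default_factory=dict)
    status: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.brain_volume_mm3 <= 0:
            raise ValueError("zero brain volume")
        expected = 100.0 * self.lesion_volume_mm3 / self.brain_volume_mm3
        if abs(self.t2lv_percent - expected) > 1e-9:
            raise ValueError("t2lv_percent inconsistent with volumes")


def compute_t2lv(
    final: LesionComponentSet,
    seg: TissueSegmentation,
    voxel_vol: float,
    stage_counts: dict | None = None,
    status: list | None = None,
) -> T2LVResult:
    """T2LV as a percentage of brain volume.

    Brain volume counts every voxel labelled WM or GM plus every final lesion
    voxel (lesion voxels were pushed into the nonbrain class upstream and are
    restored to the brain here).
    """
    if final.label_map.shape != seg.labels.shape:
        raise ValueError("lesion set and segmentation are on different grids")
    lesion_vox = final.mask
    brain_vox = (seg.labels == LABEL_WM) | (seg.labels == LABEL_GM) | lesion_vox
    lesion_volume = float(lesion_vox.sum() * voxel_vol)
    brain_volume = float(brain_vox.sum() * voxel_vol)
    if brain_volume <= 0:
        raise ValueError("zero brain volume")
    return T2LVResult(
        lesion_volume_mm3=lesion_volume,
        brain_volume_mm3=brain_volume,
        t2lv_percent=100.0 * lesion_volume / brain_volume,
        n_components_final=final.n_components,
        stage_counts=dict(stage_counts or {}),
        status=list(status or []),
    )


def fill_lesions(seg: TissueSegmentation, final: LesionComponentSet) -> TissueSegmentation:
    """Relabel every final lesion voxel as white matter (posterior (0, 1, 0)).

    Returns a new segmentation; all other voxels are unchanged. Restores the
    WM volume that was misclassified because lesions were captured into the
    nonbrain class (or, on T1-based pipelines, into GM).
    """
    if final.label_map.shape != seg.labels.shape:
        raise ValueError("lesion set and segmentation are on different grids")
    out = seg.copy()
    lesion_vox = final.mask
    out.labels[lesion_vox] = LABEL_WM
    out.posteriors[lesion_vox] = np.array([0.0, 1.0, 0.0], dtype=out.posteriors.dtype)
    return out


def normalize_volume(raw_mm3: float, subject_icv_mm3: float, standard_icv_mm3: float) -> float:
    """Scale a subject-space volume into standard space (normalized mm^3).

    ``normalized = raw * standard_icv / subject_icv``: a subject with a small
    head is scaled up so that equal tissue fractions give equal normalized
    volumes.
    """
    if subject_icv_mm3 <= 0 or standard_icv_mm3 <= 0:
        raise ValueError("intracranial volumes must be positive")
    return float(raw_mm3) * (standard_icv_mm3 / subject_icv_mm3)
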