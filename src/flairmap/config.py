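"""Pipeline configuration.

All distance parameters are expressed in millimetres and converted to voxels
per axis using the image voxel dimensions, so the defaults keep their meaning
on anisotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


@dataclass
class PipelineConfig:
    """Tunable parameters of the lesion-mapping pipeline.

    Attributes
    ----------
    smoothing_sigma_mm
        Gaussian blur applied after brain extraction (mm). Default 0.5.
    wm_prob_threshold
        White-matter probability above which (strictly) a voxel enters the
        WM mask used by the false-positive filter. Default 0.7.
    midline_touch_mm
        A candidate lesion whose minimum distance to the mid-sagittal plane
        is <= this value is treated as touching the midline. Default 4.
    midline_max_removal_mm
        Midline removal is truncated at this distance: voxels farther from
        the plane are never deleted. Default 9.
    histogram_bins
        Number of equal-width bins for the nonbrain-intensity histogram
        searched for the first empty bin. Default 32 (see docs/methods.md
        for the bin-width rationale).
    connectivity
        3-D neighbourhood for connected components: 6, 18 or 26. Default 26.
    bright_outlier_z
        Voxels brighter than mean_GM + z * sd_GM are captured into the
        nonbrain class (hyperintensity capture). Default 3.5.
    outlier_sd
        Statistical outlier rule: |x - mean| >= k * sd. Default 3.
    brain_mask_median_factor
        Fallback brain-mask threshold as a fraction of the median nonzero
        intensity. Default 0.3.
    rng_seed
        Seed for every stochastic element (EM restarts).
    """

    smoothing_sigma_mm: float = 0.5
    wm_prob_threshold: float = 0.7
    midline_touch_mm: float = 4.0
    midline_max_removal_mm: float = 9.0
    histogram_bins: int = 32
    connectivity: int = 26
    bright_outlier_z: float = 3.5
    outlier_sd: float = 3.0
    brain_mask_median_factor: float = 0.3
    gmm_tol: float = 1e-8
    gmm_max_iter: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothing_sigma_mm < 0:
            raise ValueError("smoothing_sigma_mm must be >= 0")
        if not 0 < self.wm_prob_threshold < 1:
            raise ValueError("wm_prob_threshold must lie in (0, 1)")
        if self.midline_touch_mm < 0:
            raise ValueError("midline_touch_mm must be >= 0")
        if self.midline_max_removal_mm < self.midline_touch_mm:
            raise ValueError("midline_max_removal_mm must be >= midline_touch_mm")
        if self.histogram_bins < 16:
            raise ValueError("histogram_bins must be >= 16")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.bright_outlier_z <= 0:
            raise ValueError("bright_outlier_z must be > 0")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")
        for name in ("midline_touch_mm", "midline_max_removal_mm", "wm_prob_threshold",
                     "bright_outlier_z", "outlier_sd", "smoothing_sigma_mm"):
            if not float(getattr(self, name)) == getattr(self, name) or not \
                    abs(float(getattr(self, name))) < float("inf"):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)
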