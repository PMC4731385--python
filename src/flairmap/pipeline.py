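"""End-to-end orchestration of the lesion-mapping pipeline.

Stage order matches the original method: brain extraction (or a user mask),
slight Gaussian blur, 3-class GMM tissue segmentation with hyperintensity
capture, histogram gap threshold within the nonbrain class, connected
candidate components, WM-overlap filter, midline filter, then volumetrics
(T2LV %, lesion-filled tissue volumes, ICV normalization). Every threshold
that affected the run is recorded in the :class:`RunReport`, which is
sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .fp_filters import (
    AtlasBundle,
    AffineTransform,
    Plane,
    fallback_midline_plane,
    filter_by_wm_overlap,
    make_wm_mask,
    midline_filter,
    register_affine,
    resample_to_subject,
    synthetic_atlas,
)
from .lesion_extraction import (
    LesionComponentSet,
    build_histogram,
    extract_candidates,
    find_gap_threshold,
)
from .preprocessing import apply_brain_mask, estimate_brain_mask, gaussian_smooth
from .tissue_segmentation import (
    TissueSegmentation,
    classify_tissues,
    fit_gmm_with_capture,
    tissue_volumes,
)
from .volume_io import BinaryMask, Volume, read_volume, write_mask, write_volume
from .volumetrics import T2LVResult, compute_t2lv, fill_lesions, normalize_volume

__all__ = ["RunReport", "run_pipeline", "run_pipeline_on_volume"]

log = logging.getLogger("flairmap")


@dataclass
class RunReport:
    """Everything needed to audit and reproduce one pipeline run."""

    config: dict
    gmm: dict
    gap_threshold: float
    gap_status: str
    stage_counts: dict
    t2lv: T2LVResult
    volumes_mm3: dict
    volumes_normalized_mm3: dict
    subject_icv_mm3: float
    standard_icv_mm3: float
    registration_matrix: list | None
    midline_plane: dict
    status: list
    version: str = __version__
    input_sha256: str = ""
    timestamp: str = ""
    # heavyweight artifacts, not serialized
    segmentation: TissueSegmentation | None = field(default=None, repr=False)
    candidates: LesionComponentSet | None = field(default=None, repr=False)
    final: LesionComponentSet | None = field(default=None, repr=False)
    brain_mask: BinaryMask | None = field(default=None, repr=False)
    wm_mask: BinaryMask | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "version": self.version,
            "timestamp": self.timestamp,
            "input_sha256": self.input_sha256,
            "config": self.config,
            "gmm": self.gmm,
            "gap_threshold": self.gap_threshold,
            "gap_status": self.gap_status,
            "stage_counts": self.stage_counts,
            "t2lv": {
                "lesion_volume_mm3": self.t2lv.lesion_volume_mm3,
                "brain_volume_mm3": self.t2lv.brain_volume_mm3,
                "t2lv_percent": self.t2lv.t2lv_percent,
                "n_components_final": self.t2lv.n_components_final,
            },
            "volumes_mm3": self.volumes_mm3,
            "volumes_normalized_mm3": self.volumes_normalized_mm3,
            "subject_icv_mm3": self.subject_icv_mm3,
            "standard_icv_mm3": self.standard_icv_mm3,
            "registration_matrix": self.registration_matrix,
            "midline_plane": self.midline_plane,
            "status": self.status,
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def _sha256_of(v: Volume) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(v.data).tobytes())
    h.update(np.ascontiguousarray(v.affine).tobytes())
    return h.hexdigest()


def run_pipeline_on_volume(
    flair: Volume,
    config: PipelineConfig | None = None,
    brain_mask: BinaryMask | None = None,
    wm_prob: Volume | None = None,
    atlas: AtlasBundle | None = None,
) -> RunReport:
    """Run the full pipeline on an in-memory FLAIR volume.

    ``brain_mask`` overrides the fallback brain extractor. ``wm_prob``, when
    given, must already be in subject space and bypasses registration;
    otherwise the WM probability map of ``atlas`` (default: the packaged
    synthetic atlas) is propagated through a moments-based affine. The
    zero-lesion outcome is a success, flagged in ``status``.
    """
    config = config or PipelineConfig()
    status: list[str] = []
    voxel_vol = flair.voxel_volume_mm3()

    log.info("brain mask: %s", "supplied" if brain_mask is not None else "estimating")
    if brain_mask is None:
        brain_mask = estimate_brain_mask(flair, config.brain_mask_median_factor)
    if np.isnan(flair.data[brain_mask.data]).any():
        raise ValueError("NaN intensities inside the brain mask")

    masked = apply_brain_mask(flair, brain_mask)
    smoothed = gaussian_smooth(masked, config.smoothing_sigma_mm)
    log.info("smoothed with sigma %.3g mm", config.smoothing_sigma_mm)

    fit, capture_threshold = fit_gmm_with_capture(
        smoothed.data[brain_mask.data],
        bright_outlier_z=config.bright_outlier_z,
        tol=config.gmm_tol,
        max_iter=config.gmm_max_iter,
        seed=config.rng_seed,
    )
    log.info(
        "GMM means %s sds %s weights %s (%d iters, converged=%s); capture > %.4g",
        np.round(fit.means, 2), np.round(fit.sds, 2), np.round(fit.weights, 3),
        fit.n_iter, fit.converged, capture_threshold,
    )
    seg = classify_tissues(
        smoothed, brain_mask, fit, config.bright_outlier_z,
        capture_threshold=capture_threshold,
    )

    nonbrain_values = smoothed.data[seg.nonbrain_mask.data]
    if nonbrain_values.size == 0:
        threshold, gap_status = float("inf"), "empty_nonbrain"
    else:
        hist = build_histogram(nonbrain_values, config.histogram_bins)
        threshold, gap_status = find_gap_threshold(hist)
        if hist.degenerate:
            gap_status = "degenerate_histogram"
    if gap_status != "ok":
        status.append(gap_status)
        log.warning("gap threshold degenerate: %s", gap_status)
    log.info("gap threshold %.4g (%s)", threshold, gap_status)

    candidates = extract_candidates(
        smoothed, seg.nonbrain_mask, threshold, config.connectivity, status=status
    )
    log.info("candidate components: %d", candidates.n_components)

    registration_matrix = None
    if wm_prob is not None:
        wm_prob_subject = wm_prob
        midline_plane = atlas.midline_plane if atlas is not None else fallback_midline_plane(brain_mask)
        if atlas is None:
            status.append("fallback_midline_plane")
    else:
        atlas = atlas or synthetic_atlas()
        transform = register_affine(brain_mask, atlas.brain_mask)
        registration_matrix = transform.matrix.tolist()
        wm_prob_subject = resample_to_subject(atlas.wm_prob, transform, flair)
        wm_prob_subject.data = np.clip(wm_prob_subject.data, 0.0, 1.0)
        midline_plane = transform.apply_plane(atlas.midline_plane)
    wm_mask = make_wm_mask(wm_prob_subject, config.wm_prob_threshold)

    after_wm = filter_by_wm_overlap(candidates, wm_mask, config.connectivity)
    log.info("after WM-overlap filter: %d", after_wm.n_components)
    final = midline_filter(
        after_wm,
        midline_plane,
        touch_mm=config.midline_touch_mm,
        truncate_mm=config.midline_max_removal_mm,
        connectivity=config.connectivity,
    )
    log.info("after midline filter: %d", final.n_components)
    if final.n_components == 0:
        status.append("zero_lesions")

    stage_counts = {
        "candidates": candidates.n_components,
        "after_wm_filter": after_wm.n_components,
        "after_midline_filter": final.n_components,
    }
    t2lv = compute_t2lv(final, seg, voxel_vol, stage_counts=stage_counts, status=status)
    filled = fill_lesions(seg, final)
    raw = tissue_volumes(filled, voxel_vol)
    subject_icv = brain_mask.volume_mm3()  # tissue + CSF proxy for ICV
    standard_icv = atlas.standard_icv_mm3 if atlas is not None else subject_icv
    normalized = {
        k: normalize_volume(v, subject_icv, standard_icv) for k, v in raw.items()
    }
    log.info("T2LV %.4g%% of brain volume (%d components)", t2lv.t2lv_percent, final.n_components)

    return RunReport(
        config=config.to_dict(),
        gmm={
            "means": fit.means.tolist(),
            "sds": fit.sds.tolist(),
            "weights": fit.weights.tolist(),
            "log_likelihood": fit.log_likelihood,
            "n_iter": fit.n_iter,
            "converged": fit.converged,
            "capture_threshold": capture_threshold,
        },
        gap_threshold=threshold,
        gap_status=gap_status,
        stage_counts=stage_counts,
        t2lv=t2lv,
        volumes_mm3=raw,
        volumes_normalized_mm3=normalized,
        subject_icv_mm3=subject_icv,
        standard_icv_mm3=standard_icv,
        registration_matrix=registration_matrix,
        midline_plane={
            "point": midline_plane.point.tolist(),
            "normal": midline_plane.normal.tolist(),
        },
        status=status,
        input_sha256=_sha256_of(flair),
        timestamp=datetime.now(timezone.utc).isoformat(),
        segmentation=seg,
        candidates=candidates,
        final=final,
        brain_mask=brain_mask,
        wm_mask=wm_mask,
    )


def run_pipeline(
    flair_path,
    out_dir=None,
    config: PipelineConfig | None = None,
    brain_mask_path=None,
    wm_prob_path=None,
    atlas: AtlasBundle | None = None,
) -> RunReport:
    """File-level entry point: read inputs, run, optionally write outputs.

    Outputs (when ``out_dir`` is given): ``lesion_mask.nii.gz``,
    ``tissue_labels.nii.gz``, ``candidates.nii.gz``, ``summary.tsv`` and
    ``report.json``.
    """
    flair = read_volume(flair_path)
    brain_mask = None
    if brain_mask_path is not None:
        bm = read_volume(brain_mask_path)
        brain_mask = BinaryMask(data=bm.data > 0, affine=bm.affine)
    wm_prob = read_volume(wm_prob_path) if wm_prob_path is not None else None
    report = run_pipeline_on_volume(
        flair, config=config, brain_mask=brain_mask, wm_prob=wm_prob, atlas=atlas
    )
    if out_dir is not None:
        write_outputs(report, flair, Path(out_dir))
    return report


def write_outputs(report: RunReport, flair: Volume, out_dir: Path) -> None:
    """Write lesion/label maps, the TSV summary and the JSON report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = flair.affine
    write_mask(BinaryMask(report.final.mask, affine), out_dir / "lesion_mask.nii.gz")
    write_volume(
        Volume(report.segmentation.labels.astype(float), affine),
        out_dir / "tissue_labels.nii.gz",
        dtype=np.uint8,
    )
    write_volume(
        Volume(report.candidates.label_map.astype(float), affine),
        out_dir / "candidates.nii.gz",
        dtype=np.int32,
    )
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    cols = [
        ("t2lv_percent", report.t2lv.t2lv_percent),
        ("lesion_volume_mm3", report.t2lv.lesion_volume_mm3),
        ("brain_volume_mm3", report.t2lv.brain_volume_mm3),
        ("wmv_mm3", report.volumes_mm3["wm"]),
        ("gmv_mm3", report.volumes_mm3["gm"]),
        ("wmv_normalized_mm3", report.volumes_normalized_mm3["wm"]),
        ("gmv_normalized_mm3", report.volumes_normalized_mm3["gm"]),
        ("n_components_final", report.t2lv.n_components_final),
        ("candidates", report.stage_counts["candidates"]),
        ("after_wm_filter", report.stage_counts["after_wm_filter"]),
        ("after_midline_filter", report.stage_counts["after_midline_filter"]),
        ("status", ";".join(report.status) or "clean"),
    ]
    header = "\t".join(k for k, _ in cols)
    row = "\t".join(f"{v:.6g}" if isinstance(v, float) else str(v) for _, v in cols)
    (out_dir / "summary.tsv").write_text(header + "\n" + row + "\n")
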