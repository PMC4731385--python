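"""CSF/hyperintensity separation by histogram gap search, and candidate components.

On FLAIR the nonbrain class of the tissue segmentation contains two widely
separated intensity populations: dark fluid (CSF, dura, blood) and bright
hyperintensities. The threshold between them is found exactly as in the
original pipeline: scan the nonbrain intensity histogram from the dark end,
removing the darkest bin until an empty bin is reached; that bin marks the
gap, and only voxels strictly brighter than its upper edge survive. An image
with no empty bin (no gap) is a valid lesion-free outcome and is flagged
rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, Volume

__all__ = [
    "Histogram",
    "Component",
    "LesionComponentSet",
    "build_histogram",
    "find_gap_threshold",
    "extract_candidates",
    "connectivity_structure",
    "NO_GAP_FOUND",
]

NO_GAP_FOUND = "no_gap_found"


@dataclass
class Histogram:
    """Equal-width intensity histogram: ``len(bin_edges) == len(counts) + 1``."""

    bin_edges: np.ndarray
    counts: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class Component:
    """One candidate lesion component (summary record)."""

    id: int
    n_voxels: int
    volume_mm3: float
    min_midline_dist_mm: float | None = None
    wm_overlap_voxels: int | None = None


@dataclass
class LesionComponentSet:
    """Labelled candidate (or final) lesion components on the image grid."""

    label_map: np.ndarray
    affine: np.ndarray
    voxel_volume_mm3: float
    threshold_used: float
    components: list[Component] = field(default_factory=list)
    status: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0

    def n_voxels(self) -> int:
        return int((self.label_map > 0).sum())

    def total_volume_mm3(self) -> float:
        return self.n_voxels() * self.voxel_volume_mm3


def build_histogram(values: np.ndarray, nbins: int) -> Histogram:
    """Equal-width histogram over [min, max]; rightmost edge inclusive.

    Constant input (zero range) yields a single-bin histogram flagged
    ``degenerate`` instead of an error.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty values")
    if nbins < 16:
        raise ValueError("nbins must be >= 16")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return Histogram(
            bin_edges=np.array([lo, lo + 1.0]),
            counts=np.array([values.size]),
            degenerate=True,
        )
    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts)


def find_gap_threshold(h: Histogram) -> tuple[float, str]:
    """First-empty-bin scan from the dark end of the histogram.

    Returns ``(threshold, status)`` where the threshold is the upper edge of
    the first empty bin, so that everything in and below the gap is removed by
    a strictly-greater-than comparison. When every bin is occupied the status
    is ``no_gap_found`` and the threshold is +inf (zero lesions downstream).
    """
    empty = np.flatnonzero(h.counts == 0)
    if empty.size == 0:
        return float("inf"), NO_GAP_FOUND
    return float(h.bin_edges[empty[0] + 1]), "ok"


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3-D structuring element for 6-, 18- or 26-connected components."""
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be one of 6, 18, 26") from None
    return ndimage.generate_binary_structure(3, order)


def label_components(
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_vol: float,
    connectivity: int,
    threshold_used: float,
    status: list[str] | None = None,
) -> LesionComponentSet:
    """Connected-component labelling of a boolean grid into a component set."""
    labels, n = ndimage.label(mask, structure=connectivity_structure(connectivity))
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    comps = [
        Component(id=i, n_voxels=int(counts[i]), volume_mm3=float(counts[i] * voxel_vol))
        for i in range(1, n + 1)
    ]
    return LesionComponentSet(
        label_map=labels.astype(np.int32),
        affine=np.asarray(affine, dtype=float),
        voxel_volume_mm3=voxel_vol,
        threshold_used=threshold_used,
        components=comps,
        status=list(status or []),
    )


def extract_candidates(
    v: Volume,
    nonbrain: BinaryMask,
    threshold: float,
    connectivity: int = 26,
    status: list[str] | None = None,
) -> LesionComponentSet:
    """Candidate lesions: nonbrain voxels strictly brighter than the threshold.

    A +inf threshold (no gap found) yields an empty component set.
    """
    nonbrain.check_same_grid(v)
    cand = nonbrain.data & (v.data > threshold)
    return label_components(
        cand,
        affine=v.affine,
        voxel_vol=v.voxel_volume_mm3(),
        connectivity=connectivity,
        threshold_used=threshold,
        status=status,
    )
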