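"""False-positive filters: white-matter overlap and midline removal.

Two classes of false positives survive the gap threshold: consistently bright
gray-matter structures outside the white matter, and the septum pellucidum /
other bright midline tissue. The first is removed by requiring each candidate
component to share at least one voxel with a white-matter mask propagated
from an atlas; the second by deleting components that touch (come within
``touch_mm`` of) the mid-sagittal plane, with deletion truncated at
``truncate_mm`` so genuinely periventricular lesion tissue farther out is
kept.

Atlas propagation here is a moments-based affine (centre of mass, principal
axes, per-axis scale): deliberately simpler than full nonlinear registration,
which is out of scope. Users with a subject-space WM probability map can
bypass registration entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .lesion_extraction import Component, LesionComponentSet, label_components
from .volume_io import BinaryMask, Volume

__all__ = [
    "AffineTransform",
    "Plane",
    "AtlasBundle",
    "register_affine",
    "resample_to_subject",
    "make_wm_mask",
    "make_flair_like_reference",
    "filter_by_wm_overlap",
    "midline_filter",
    "midline_distances",
    "fallback_midline_plane",
    "synthetic_atlas",
]


@dataclass
class AffineTransform:
    """4x4 world-mm map from atlas space to subject space."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("non-invertible transform")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def apply_point(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.matrix[:3, :3] @ p + self.matrix[:3, 3]

    def apply_plane(self, plane: "Plane") -> "Plane":
        # Normals transform by the inverse-transpose of the linear part.
        n = np.linalg.inv(self.matrix[:3, :3]).T @ plane.normal
        return Plane(point=self.apply_point(plane.point), normal=n / np.linalg.norm(n))


@dataclass
class Plane:
    """A plane in world mm: a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if norm == 0:
            raise ValueError("plane normal cannot be zero")
        self.normal = self.normal / norm


@dataclass
class AtlasBundle:
    """Standard-space companions needed by the false-positive filters."""

    brain_mask: BinaryMask
    wm_prob: Volume
    midline_plane: Plane
    standard_icv_mm3: float
    flair_like_reference: Volume | None = None

    def __post_init__(self) -> None:
        lo, hi = float(self.wm_prob.data.min()), float(self.wm_prob.data.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"wm_prob values must lie in [0, 1], got [{lo}, {hi}]")


def _mask_moments(mask: BinaryMask):
    """Centroid (world mm), principal axes and per-axis sd of a mask."""
    idx = np.argwhere(mask.data)
    if idx.shape[0] == 0:
        raise ValueError("empty mask")
    coords = idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    center = coords.mean(axis=0)
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-9 * evals[0]:
        raise ValueError("degenerate mask: nearly planar or linear second moments")
    # Deterministic sign convention: each axis points along its dominant
    # world component; enforce a right-handed frame on the last axis.
    for i in range(3):
        j = int(np.argmax(np.abs(evecs[:, i])))
        if evecs[j, i] < 0:
            evecs[:, i] = -evecs[:, i]
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    return center, evecs, np.sqrt(evals)


def register_affine(subject_mask: BinaryMask, atlas_mask: BinaryMask) -> AffineTransform:
    """Moments-based affine mapping atlas world coordinates to subject space.

    Composed of centre-of-mass translation, principal-axes rotation and
    per-axis scaling from the second moments of the two masks. Deterministic;
    raises on degenerate (planar/linear) masks.
    """
    c_s, r_s, s_s = _mask_moments(subject_mask)
    c_a, r_a, s_a = _mask_moments(atlas_mask)
    linear = r_s @ np.diag(s_s / s_a) @ r_a.T
    matrix = np.eye(4)
    matrix[:3, :3] = linear
    matrix[:3, 3] = c_s - linear @ c_a
    return AffineTransform(matrix)


def resample_to_subject(map_vol: Volume, t: AffineTransform, target: Volume) -> Volume:
    """Trilinear resampling of an atlas-space map onto the subject grid.

    Out-of-field voxels are 0.
    """
    # subject voxel -> subject world -> atlas world -> atlas voxel
    m = np.linalg.inv(map_vol.affine) @ t.inverse() @ target.affine
    out = ndimage.affine_transform(
        map_vol.data,
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=target.shape,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return Volume(data=out, affine=target.affine.copy())


def make_wm_mask(wm_prob_subject: Volume, threshold: float = 0.7) -> BinaryMask:
    """White-matter mask: probability strictly greater than the threshold."""
    lo, hi = float(wm_prob_subject.data.min()), float(wm_prob_subject.data.max())
    if lo < -1e-9 or hi > 1 + 1e-9:
        raise ValueError(f"WM probabilities must lie in [0, 1], got [{lo}, {hi}]")
    return BinaryMask(data=wm_prob_subject.data > threshold, affine=wm_prob_subject.affine.copy())


def make_flair_like_reference(t2_standard: Volume, csf_mask: Volume) -> Volume:
    """FLAIR-like standard image: T2 standard minus CSF mask, clipped at 0."""
    if t2_standard.shape != csf_mask.shape:
        raise ValueError("shape mismatch")
    return t2_standard.like(np.clip(t2_standard.data - csf_mask.data, 0.0, None))


def _relabel(
    keep_mask: np.ndarray,
    c: LesionComponentSet,
    connectivity: int,
    status: list[str],
) -> LesionComponentSet:
    return label_components(
        keep_mask,
        affine=c.affine,
        voxel_vol=c.voxel_volume_mm3,
        connectivity=connectivity,
        threshold_used=c.threshold_used,
        status=status,
    )


def filter_by_wm_overlap(
    c: LesionComponentSet, wm: BinaryMask, connectivity: int = 26
) -> LesionComponentSet:
    """Keep whole components with >= 1 voxel inside the WM mask; drop the rest.

    Component ids are re-densified in the result.
    """
    if c.label_map.shape != wm.shape:
        raise ValueError("shape mismatch between components and WM mask")
    overlap = np.bincount(
        c.label_map[wm.data].ravel(), minlength=c.n_components + 1
    )
    keep_ids = np.flatnonzero(overlap[1:] > 0) + 1
    keep_mask = np.isin(c.label_map, keep_ids) & (c.label_map > 0)
    out = _relabel(keep_mask, c, connectivity, list(c.status))
    # Annotate retained components with their overlap counts.
    new_overlap = np.bincount(out.label_map[wm.data].ravel(), minlength=out.n_components + 1)
    for comp in out.components:
        comp.wm_overlap_voxels = int(new_overlap[comp.id])
    return out


def midline_distances(c: LesionComponentSet, plane: Plane) -> np.ndarray:
    """Unsigned perpendicular distance (mm) of every labelled voxel centre."""
    idx = np.argwhere(c.label_map > 0)
    coords = idx @ c.affine[:3, :3].T + c.affine[:3, 3]
    return np.abs((coords - plane.point) @ plane.normal)


def midline_filter(
    c: LesionComponentSet,
    midline_plane: Plane,
    touch_mm: float = 4.0,
    truncate_mm: float = 9.0,
    connectivity: int = 26,
) -> LesionComponentSet:
    """Remove midline false positives with touch-gated, truncated deletion.

    A component whose minimum unsigned distance to the mid-sagittal plane is
    <= ``touch_mm`` has its voxels at distance <= ``truncate_mm`` deleted;
    voxels beyond ``truncate_mm`` are never removed, so periventricular
    lesions contiguous with the septum keep their distal tissue (surviving
    voxels are re-labelled as fresh components). Components farther than
    ``touch_mm`` pass unchanged. Both boundaries are inclusive.
    """
    if touch_mm > truncate_mm:
        raise ValueError("touch_mm must be <= truncate_mm")
    lm = c.label_map
    idx = np.argwhere(lm > 0)
    if idx.shape[0] == 0:
        return _relabel(lm > 0, c, connectivity, list(c.status))
    coords = idx @ c.affine[:3, :3].T + c.affine[:3, 3]
    dist = np.abs((coords - midline_plane.point) @ midline_plane.normal)
    labels_flat = lm[tuple(idx.T)]
    keep = np.ones(idx.shape[0], dtype=bool)
    min_dist = {comp.id: np.inf for comp in c.components}
    for lab in np.unique(labels_flat):
        sel = labels_flat == lab
        dmin = float(dist[sel].min())
        min_dist[int(lab)] = dmin
        if dmin <= touch_mm:
            keep[sel & (dist <= truncate_mm)] = False
    keep_mask = np.zeros(lm.shape, dtype=bool)
    keep_mask[tuple(idx[keep].T)] = True
    for comp in c.components:  # annotate the inputs for auditability
        comp.min_midline_dist_mm = min_dist.get(comp.id)
    out = _relabel(keep_mask, c, connectivity, list(c.status))
    if out.n_components:
        od = midline_distances(out, midline_plane)
        ol = out.label_map[out.label_map > 0]
        for comp in out.components:
            comp.min_midline_dist_mm = float(od[ol == comp.id].min())
    return out


def fallback_midline_plane(brain_mask: BinaryMask) -> Plane:
    """Mid-sagittal plane estimate without an atlas.

    The plane passes through the brain-mask centroid with normal along the
    left-right (first) axis of the affine.
    """
    idx = np.argwhere(brain_mask.data)
    if idx.shape[0] == 0:
        raise ValueError("empty brain mask")
    coords = idx @ brain_mask.affine[:3, :3].T + brain_mask.affine[:3, 3]
    normal = brain_mask.affine[:3, 0]
    return Plane(point=coords.mean(axis=0), normal=normal / np.linalg.norm(normal))


def synthetic_atlas(smooth_sigma_mm: float = 1.0) -> AtlasBundle:
    """Build the packaged standard-space atlas from the noise-free phantom.

    The atlas is synthetic by construction: it is the standard phantom
    anatomy (no lesions, no noise) rendered at 1 mm isotropic resolution.
    The WM probability map is the binary WM region blurred with a 1 mm
    Gaussian, the mid-sagittal plane is exact, and the standard intracranial
    volume is the brain ellipsoid volume. Users may substitute real
    standard-space files wherever an :class:`AtlasBundle` is accepted.
    """
    from . import phantom as ph
    from .preprocessing import gaussian_smooth

    spec = ph.PhantomSpec(noise_sd=0.0, seed=0)
    vol, truth = ph.generate_phantom(spec)
    wm_prob = gaussian_smooth(
        Volume(data=truth.wm_mask.data.astype(float), affine=vol.affine.copy()),
        smooth_sigma_mm,
    )
    wm_prob.data = np.clip(wm_prob.data, 0.0, 1.0)
    plane = Plane(point=np.array([spec.midline_x_mm, 0.0, 0.0]), normal=np.array([1.0, 0.0, 0.0]))
    return AtlasBundle(
        brain_mask=truth.brain_mask,
        wm_prob=wm_prob,
        midline_plane=plane,
        standard_icv_mm3=truth.brain_mask.volume_mm3(),
        flair_like_reference=vol,
    )
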