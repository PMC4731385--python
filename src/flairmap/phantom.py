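"""Synthetic FLAIR phantom generator with voxel-exact ground truth.

The phantom emulates the properties of a brain-extracted 3-D FLAIR volume
that the lesion-mapping pipeline relies on: dark suppressed fluid (CSF),
mid-intensity white matter, brighter cortical gray matter, strongly
hyperintense lesions, and a bright thin mid-sagittal septum-like sheet that
acts as the canonical midline false positive. Geometry is analytic (nested
triaxial ellipsoids plus spheres and a sheet), intensities are a constant
palette per region plus additive Gaussian noise, and every region mask is
returned as ground truth, so each pipeline stage can be scored exactly.

The anatomy, outside in: a thin film of sulcal/subarachnoid CSF left behind
by brain extraction, a cortical GM shell, a WM core, two mirrored ventricles
(CSF) flanking the mid-sagittal plane, and the septum sheet between them.
The mid-sagittal plane is exactly x = nx/2 in world mm, so midline-filter
geometry is analytically known.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume_io import BinaryMask, Volume

__all__ = [
    "Lesion",
    "SeptumSpec",
    "PhantomSpec",
    "PhantomTruth",
    "Scenario",
    "generate_phantom",
    "default_lesions",
    "default_validation_suite",
]

#: Default intensity palette (arbitrary FLAIR-like units).
DEFAULT_PALETTE = {"csf": 20.0, "wm": 55.0, "gm": 70.0, "lesion": 130.0, "septum": 120.0}


@dataclass(frozen=True)
class Lesion:
    """A spherical lesion: centre in world mm and radius in mm."""

    center_mm: tuple[float, float, float]
    radius_mm: float


@dataclass(frozen=True)
class SeptumSpec:
    """Bright mid-sagittal sheet between the ventricles.

    ``offset_mm`` displaces the sheet laterally from the mid-sagittal plane
    (used to emulate the atrophic failure mode where midline structures sit
    farther from the plane than the filter expects).
    """

    offset_mm: float = 0.0
    half_thickness_mm: float = 1.5
    half_extent_y_mm: float = 10.0
    half_extent_z_mm: float = 6.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, palette and noise of one synthetic FLAIR volume."""

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semiaxes_mm: tuple[float, float, float] = (38.0, 46.0, 34.0)
    csf_rim_mm: float = 2.0
    gm_shell_mm: float = 3.0
    ventricle_semiaxes_mm: tuple[float, float, float] = (5.0, 13.0, 8.0)
    ventricle_offset_mm: float = 8.0
    septum: SeptumSpec | None = SeptumSpec()
    lesions: tuple[Lesion, ...] = ()
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.brain_semiaxes_mm):
            raise ValueError("brain semi-axes must be positive")
        if self.csf_rim_mm < 0 or self.gm_shell_mm < 0:
            raise ValueError("shell thicknesses must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        p = self.palette
        if not p["csf"] < p["wm"] < p["gm"] < p["lesion"]:
            raise ValueError("palette must satisfy CSF < WM < GM < lesion")

    @property
    def center_mm(self) -> tuple[float, float, float]:
        """Brain centre; x is exactly the mid-sagittal plane coordinate."""
        return tuple(self.shape[i] * self.voxel_dims[i] / 2.0 for i in range(3))

    @property
    def midline_x_mm(self) -> float:
        return self.center_mm[0]


@dataclass
class PhantomTruth:
    """Ground-truth region masks and derived reference quantities."""

    brain_mask: BinaryMask
    csf_mask: BinaryMask
    wm_mask: BinaryMask
    gm_mask: BinaryMask
    lesion_mask: BinaryMask
    septum_mask: BinaryMask
    true_lesion_volume_mm3: float
    true_brain_volume_mm3: float
    true_t2lv_percent: float


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    q = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semiaxes))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Render the phantom volume and its ground truth.

    Deterministic given ``spec.seed`` (bit-identical regeneration). Region
    priority where shapes overlap: lesion > septum > ventricle CSF > tissue
    shells. Noise is added only inside the brain (background stays exactly 0)
    and intensities are clipped at 0, as magnitude MR images are nonnegative.
    A lesion with any voxel outside the brain ellipsoid is an error;
    overlapping lesions merge in the truth mask.
    """
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.voxel_dims
    affine = np.diag([dx, dy, dz, 1.0])
    xs = (np.arange(nx) * dx)[:, None, None]
    ys = (np.arange(ny) * dy)[None, :, None]
    zs = (np.arange(nz) * dz)[None, None, :]
    coords = (xs, ys, zs)
    c = spec.center_mm
    a, b, cc = spec.brain_semiaxes_mm

    brain = _ellipsoid(coords, c, (a, b, cc))
    inner1 = (a - spec.csf_rim_mm, b - spec.csf_rim_mm, cc - spec.csf_rim_mm)
    inner2 = tuple(s - spec.gm_shell_mm for s in inner1)
    gm_plus_core = _ellipsoid(coords, c, inner1)
    core = _ellipsoid(coords, c, inner2)
    rim = brain & ~gm_plus_core
    gm = gm_plus_core & ~core

    vent = np.zeros(spec.shape, dtype=bool)
    for side in (-1.0, +1.0):
        vc = (c[0] + side * spec.ventricle_offset_mm, c[1], c[2])
        vent |= _ellipsoid(coords, vc, spec.ventricle_semiaxes_mm)
    vent &= core

    septum = np.zeros(spec.shape, dtype=bool)
    if spec.septum is not None:
        s = spec.septum
        septum = (
            (np.abs(xs - (c[0] + s.offset_mm)) <= s.half_thickness_mm)
            & (np.abs(ys - c[1]) <= s.half_extent_y_mm)
            & (np.abs(zs - c[2]) <= s.half_extent_z_mm)
            & core
        )

    lesion = np.zeros(spec.shape, dtype=bool)
    for les in spec.lesions:
        sphere = _ellipsoid(coords, les.center_mm, (les.radius_mm,) * 3)
        if np.any(sphere & ~brain):
            raise ValueError(f"lesion at {les.center_mm} extends outside the brain")
        lesion |= sphere

    # Priority resolution (highest wins): lesion > septum > ventricle > shells.
    septum &= ~lesion
    vent &= ~(lesion | septum)
    csf = (rim | vent) & ~(lesion | septum)
    gm_final = gm & ~(lesion | septum | csf)
    wm_final = core & ~(lesion | septum | vent)

    img = np.zeros(spec.shape, dtype=float)
    img[csf] = spec.palette["csf"]
    img[wm_final] = spec.palette["wm"]
    img[gm_final] = spec.palette["gm"]
    img[septum] = spec.palette["septum"]
    img[lesion] = spec.palette["lesion"]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=spec.shape)
        img[brain] += noise[brain]
        np.clip(img, 0.0, None, out=img)

    voxel_vol = dx * dy * dz

    def _mask(m: np.ndarray) -> BinaryMask:
        return BinaryMask(data=m, affine=affine.copy())

    lesion_vol = float(lesion.sum() * voxel_vol)
    brain_tissue_vol = float((wm_final.sum() + gm_final.sum() + lesion.sum()) * voxel_vol)
    truth = PhantomTruth(
        brain_mask=_mask(brain),
        csf_mask=_mask(csf),
        wm_mask=_mask(wm_final),
        gm_mask=_mask(gm_final),
        lesion_mask=_mask(lesion),
        septum_mask=_mask(septum),
        true_lesion_volume_mm3=lesion_vol,
        true_brain_volume_mm3=brain_tissue_vol,
        true_t2lv_percent=100.0 * lesion_vol / brain_tissue_vol if brain_tissue_vol else 0.0,
    )
    return Volume(data=img, affine=affine), truth


def default_lesions() -> tuple[Lesion, ...]:
    """Three deep-WM spheres giving a lesion load close to 1% of brain volume.

    All centres keep the whole sphere more than 9 mm from the mid-sagittal
    plane (x = 48 mm), so the midline filter leaves them untouched.
    """
    return (
        Lesion(center_mm=(66.0, 48.0, 48.0), radius_mm=7.0),
        Lesion(center_mm=(30.0, 58.0, 40.0), radius_mm=5.0),
        Lesion(center_mm=(58.0, 32.0, 58.0), radius_mm=4.0),
    )


@dataclass(frozen=True)
class Scenario:
    """A named phantom configuration with the properties it is built to show."""

    name: str
    spec: PhantomSpec
    expectations: dict


def default_validation_suite(noise_sd: float = 4.0, seed: int = 0) -> list[Scenario]:
    """The named scenarios exercised by the validation tests.

    - ``lesion_free``: standard anatomy, no lesions; T2LV must be exactly 0.
    - ``deep_wm``: a single deep white-matter lesion; one final component.
    - ``periventricular``: a lesion contiguous with the septum, spanning from
      the midline out to 12 mm; removal must truncate at 9 mm so only voxels
      strictly beyond 9 mm survive.
    - ``septum_only``: the septum is the only bright structure; the
      false-positive filters must leave zero final lesions.
    - ``atrophic_ventricles``: enlarged ventricles displace the septum-like
      sheet about 7 mm laterally, beyond the 4 mm touch gate, reproducing the
      documented failure mode in which midline false positives survive.
    """
    base = PhantomSpec(noise_sd=noise_sd, seed=seed)
    tall_septum = SeptumSpec(half_extent_z_mm=10.0)
    scenarios = [
        Scenario("lesion_free", base, {"t2lv_percent": 0.0, "n_components_final": 0}),
        Scenario(
            "deep_wm",
            replace(base, lesions=(Lesion((66.0, 48.0, 48.0), 7.0),)),
            {"n_components_final": 1, "t2lv_positive": True},
        ),
        Scenario(
            "periventricular",
            replace(
                base,
                septum=tall_septum,
                lesions=(Lesion((54.0, 48.0, 58.0), 6.0),),
            ),
            {"survivors_beyond_mm": 9.0, "t2lv_positive": True},
        ),
        Scenario("septum_only", base, {"n_components_final": 0}),
        Scenario(
            "atrophic_ventricles",
            replace(
                base,
                ventricle_semiaxes_mm=(8.0, 13.0, 8.0),
                ventricle_offset_mm=10.0,
                septum=SeptumSpec(offset_mm=7.0, half_extent_z_mm=10.0),
            ),
            {"midline_false_positive_survives": True},
        ),
    ]
    return scenarios
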