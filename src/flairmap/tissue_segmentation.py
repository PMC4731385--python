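"""Three-class Gaussian-mixture tissue segmentation of FLAIR intensities.

The brain intensity histogram of a FLAIR image is modelled as a mixture of
three Gaussians ordered dark to bright: nonbrain/CSF (fluid is suppressed and
dark), white matter, and gray matter. T2 hyperintense lesions are far brighter
than any tissue mode; a plain mixture can absorb them into the gray-matter
class, so :func:`classify_tissues` additionally captures voxels brighter than
``mean_GM + z * sd_GM`` into the nonbrain class. That reproduces, as an
explicit deterministic rule, the behaviour of histogram-fitting segmenters
that mislabel hyperintensities as nonbrain — which is precisely what the
downstream gap-threshold lesion extraction relies on.

Class label coding on the hard label map: 0 background, 1 nonbrain/CSF,
2 white matter, 3 gray matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .volume_io import BinaryMask, Volume

__all__ = [
    "GMMFit",
    "TissueSegmentation",
    "fit_gmm",
    "fit_gmm_with_capture",
    "classify_tissues",
    "tissue_volumes",
]

LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_WM = 2
LABEL_GM = 3

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GMMFit:
    """Parameters of a fitted univariate Gaussian mixture, means ascending.

    For the 3-class FLAIR fit, class identities follow the ascending means:
    index 0 nonbrain/CSF (darkest), 1 white matter, 2 gray matter (brightest
    tissue).
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(self.sds > 0):
            raise ValueError("sds must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")

    @property
    def k(self) -> int:
        return self.means.size


@dataclass
class TissueSegmentation:
    """Per-voxel tissue posteriors and hard labels inside the brain mask.

    ``posteriors`` has shape ``shape + (k,)`` and sums to 1 per in-mask voxel;
    ``labels`` is the argmax class (1-based; ties break to the lower class);
    ``nonbrain_mask`` is the CSF-argmax set united with captured bright
    outliers and is always a subset of the brain mask.
    """

    posteriors: np.ndarray
    labels: np.ndarray
    nonbrain_mask: BinaryMask
    brain_mask: BinaryMask
    fit: GMMFit

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def copy(self) -> "TissueSegmentation":
        return TissueSegmentation(
            posteriors=self.posteriors.copy(),
            labels=self.labels.copy(),
            nonbrain_mask=BinaryMask(self.nonbrain_mask.data.copy(), self.nonbrain_mask.affine.copy()),
            brain_mask=self.brain_mask,
            fit=self.fit,
        )


def _log_component_densities(x: np.ndarray, means, sds, weights) -> np.ndarray:
    """Weighted log densities, shape (n, k)."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return np.log(weights)[None, :] - np.log(sds)[None, :] - 0.5 * (z * z + _LOG_2PI)


def _init_quantiles(x: np.ndarray, k: int) -> np.ndarray:
    # 10/50/85 percentiles for the FLAIR 3-class case (dark CSF minority,
    # WM bulk, bright GM); evenly spread quantiles otherwise.
    if k == 3:
        q = [10.0, 50.0, 85.0]
    elif k == 1:
        q = [50.0]
    else:
        q = list(np.linspace(10.0, 90.0, k))
    return np.percentile(x, q)


def fit_gmm(
    intensities: np.ndarray,
    k: int = 3,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> GMMFit:
    """Fit a k-component univariate Gaussian mixture by expectation-maximization.

    Initialization is deterministic: class means at fixed intensity quantiles,
    equal weights, a common sd equal to the sample sd. Convergence is declared
    when the relative log-likelihood change drops below ``tol``. Component sds
    are clamped at a floor of 1e-3 of the data range (variance-floor
    regularization: a noise-free image legitimately concentrates a class on a
    point mass, which must not abort the fit); a component that loses all its
    responsibility mass triggers a restart with jittered means (at most 5,
    driven by ``seed``).

    Returns the fit with components relabelled so means are ascending.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("intensities contain non-finite values")
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} samples for k={k}, got {x.size}")
    data_range = float(x.max() - x.min())
    sd_floor = max(1e-3 * data_range, 1e-12)
    rng = np.random.default_rng(seed)

    base_means = _init_quantiles(x, k)
    for restart in range(6):
        means = base_means.copy()
        if restart > 0:
            means = means + rng.normal(0.0, 0.02 * max(data_range, 1.0), size=k)
        sds = np.full(k, max(float(x.std()), sd_floor))
        weights = np.full(k, 1.0 / k)
        ll_old = -np.inf
        degenerate = False
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            log_dens = _log_component_densities(x, means, sds, weights)
            log_norm = logsumexp(log_dens, axis=1)
            ll = float(log_norm.sum())
            resp = np.exp(log_dens - log_norm[:, None])
            nk = resp.sum(axis=0)
            if np.any(nk <= 0):
                degenerate = True
                break
            means = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            sds = np.maximum(np.sqrt(var), sd_floor)
            weights = nk / x.size
            if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * abs(ll_old):
                converged = True
                break
            ll_old = ll
        if not degenerate:
            order = np.argsort(means)
            return GMMFit(
                means=means[order],
                sds=sds[order],
                weights=weights[order] / weights.sum(),
                log_likelihood=ll,
                n_iter=n_iter,
                converged=converged,
            )
    raise RuntimeError("degenerate fit: a component emptied in all 5 restarts")


def fit_gmm_with_capture(
    intensities: np.ndarray,
    bright_outlier_z: float = 3.5,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    max_capture_iter: int = 20,
) -> tuple[GMMFit, float]:
    """Tissue fit with self-consistent bright-outlier exclusion.

    Hyperintense lesions are gross outliers under the three-tissue model, and
    like all gross outliers they corrupt the very estimates used to detect
    them: absorbed into the gray-matter class they inflate ``sd_GM`` and push
    the capture threshold ``mean_GM + z * sd_GM`` above their own intensities.
    This routine therefore alternates (a) fitting the mixture on the voxels
    not currently captured and (b) recomputing the capture threshold from the
    new gray-matter parameters, until the captured set stops changing. The
    fixed point leaves the tissue fit describing tissue only, with the
    threshold settled in the intensity gap between the gray-matter mode and
    the hyperintensities.

    Returns the final fit and the capture threshold it implies.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    keep = np.ones(x.size, dtype=bool)
    fit = fit_gmm(x, k=3, tol=tol, max_iter=max_iter, seed=seed)
    threshold = float(fit.means[2] + bright_outlier_z * fit.sds[2])
    for _ in range(max_capture_iter):
        new_keep = x <= threshold
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
        fit = fit_gmm(x[keep], k=3, tol=tol, max_iter=max_iter, seed=seed)
        threshold = float(fit.means[2] + bright_outlier_z * fit.sds[2])
    return fit, threshold


def classify_tissues(
    v: Volume,
    m: BinaryMask,
    fit: GMMFit,
    bright_outlier_z: float = 3.5,
    capture_threshold: float | None = None,
) -> TissueSegmentation:
    """Label every in-mask voxel by Bayes rule under the fitted mixture.

    The nonbrain mask is the union of voxels whose maximum-posterior class is
    nonbrain/CSF and of bright outliers with intensity strictly above
    ``mean_GM + bright_outlier_z * sd_GM`` (hyperintensity capture); captured
    voxels also have their hard label set to nonbrain. An explicit
    ``capture_threshold`` (e.g. from :func:`fit_gmm_with_capture`) overrides
    the formula.
    """
    m.check_same_grid(v)
    if not m.data.any():
        raise ValueError("empty brain mask")
    if fit.k != 3:
        raise ValueError("classify_tissues requires a 3-class fit")
    if capture_threshold is None:
        capture_threshold = float(fit.means[2] + bright_outlier_z * fit.sds[2])
    x = v.data[m.data]
    log_dens = _log_component_densities(x, fit.means, fit.sds, fit.weights)
    post = np.exp(log_dens - logsumexp(log_dens, axis=1)[:, None])
    labels_in = np.argmax(post, axis=1)  # ties -> lower class index
    bright = x > capture_threshold
    nonbrain_in = (labels_in == 0) | bright
    labels_in = labels_in + 1  # 1-based tissue coding
    labels_in[bright] = LABEL_CSF

    shape = v.shape
    posteriors = np.zeros(shape + (3,), dtype=np.float32)
    posteriors[m.data] = post.astype(np.float32)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[m.data] = labels_in.astype(np.uint8)
    nonbrain = np.zeros(shape, dtype=bool)
    nonbrain[m.data] = nonbrain_in
    return TissueSegmentation(
        posteriors=posteriors,
        labels=labels,
        nonbrain_mask=BinaryMask(data=nonbrain, affine=v.affine.copy()),
        brain_mask=m,
        fit=fit,
    )


def tissue_volumes(seg: TissueSegmentation, voxel_vol: float) -> dict[str, float]:
    """Per-class volumes in mm^3 from the hard labels.

    ``brain`` is WM + GM: the nonbrain/CSF class is excluded, and lesion
    voxels re-enter the brain volume in the volumetrics stage once they have
    been identified and filtered.
    """
    counts = np.bincount(seg.labels.ravel(), minlength=4)
    out = {
        "csf": float(counts[LABEL_CSF] * voxel_vol),
        "wm": float(counts[LABEL_WM] * voxel_vol),
        "gm": float(counts[LABEL_GM] * voxel_vol),
    }
    out["brain"] = out["wm"] + out["gm"]
    return out
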