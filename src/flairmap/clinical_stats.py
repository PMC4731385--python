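"""Validation statistics: transforms, outliers, correlations, hierarchical regression.

This module reproduces the statistical machinery used to relate lesion burden
to clinical disability in a cross-sectional cohort: normality-restoring
transforms (square root, log10, inverse), a 3-standard-deviation outlier
rule, Pearson and age-controlled partial correlations with two-tailed
significance, and hierarchical multiple regression (HMR) evaluated by the
increment in R^2 and its F test, with standardized betas in the final model.

All functions operate on plain numeric arrays (or pandas Series); listwise
deletion of missing values is applied per analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "detect_outliers",
    "select_transform",
    "apply_transform_log10",
    "pearson",
    "partial_corr",
    "hmr",
    "HMRStage",
    "HMRResult",
    "adjusted_r2",
    "two_tailed_p_from_r",
    "correlation_matrix",
    "partial_correlation_matrix",
    "synthetic_cohort",
]


# ---------------------------------------------------------------------------
# screening: outliers and transforms

def detect_outliers(x, k: float = 3.0) -> np.ndarray:
    """Indices of values at least ``k`` sample standard deviations from the mean.

    Mean and sd (n-1 denominator) are computed once on the full sample; the
    rule is inclusive (``>= k * sd``). A zero-variance sample has no outliers.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(x - x.mean()) >= k * sd)


def apply_transform_log10(x) -> np.ndarray:
    """Elementwise log10; every value must be strictly positive."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log10 transform requires strictly positive values")
    return np.log10(x)


_TRANSFORMS = {
    "identity": (lambda x: x, lambda x: True),
    "sqrt": (np.sqrt, lambda x: np.all(x >= 0)),
    "log10": (np.log10, lambda x: np.all(x > 0)),
    "inverse": (lambda x: 1.0 / x, lambda x: np.all(x > 0)),
}


def select_transform(x, identity_margin: float = 0.005) -> tuple[np.ndarray, str]:
    """Pick the transform that best restores normality.

    Candidates are identity, square root, log10 and inverse, restricted to
    those whose domain admits the data (sqrt needs nonnegative values, log10
    and inverse strictly positive). Normality is scored by the Shapiro-Wilk
    W statistic; the highest W wins, except that identity is kept whenever it
    scores within ``identity_margin`` of the best (prefer untransformed data
    on effective ties). The inverse transform reverses monotonic order, which
    is flagged with a warning so correlation signs are interpreted correctly.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    scores: dict[str, float] = {}
    transformed: dict[str, np.ndarray] = {}
    for name, (fn, admissible) in _TRANSFORMS.items():
        if not admissible(x):
            continue
        tx = fn(x)
        if np.ptp(tx) == 0:
            continue
        scores[name] = float(stats.shapiro(tx).statistic)
        transformed[name] = tx
    if not scores:
        warnings.warn("no admissible transform; returning identity")
        return x.copy(), "identity"
    best = max(scores, key=lambda name: scores[name])
    if "identity" in scores and scores["identity"] >= scores[best] - identity_margin:
        best = "identity"
    if best == "inverse":
        warnings.warn("inverse transform reverses monotonic order")
    return transformed[best], best


# ---------------------------------------------------------------------------
# correlations

def two_tailed_p_from_r(r: float, df: int) -> float:
    """Two-tailed p-value of a correlation via t = r * sqrt(df / (1 - r^2))."""
    if df <= 0:
        raise ValueError("df must be positive")
    r = float(r)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def _pairwise_complete(*arrays) -> list[np.ndarray]:
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("samples must have equal length")
    ok = np.ones(n, dtype=bool)
    for a in arrays:
        ok &= np.isfinite(a)
    return [a[ok] for a in arrays]


def pearson(x, y) -> tuple[float, float, int]:
    """Product-moment correlation with two-tailed significance.

    Returns ``(r, p, n)`` on pairwise-complete observations; the p-value
    comes from ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance sample")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, two_tailed_p_from_r(r, n - 2), n


def partial_corr(x, y, covariates=()) -> tuple[float, float, int]:
    """Partial correlation of x and y controlling for covariates.

    Computed as the Pearson correlation of the least-squares residuals of x
    and y on the covariates (with intercept). Returns ``(r, p, df)`` with
    ``df = n - 2 - k`` for k covariates; with no covariates this reduces
    exactly to :func:`pearson`.
    """
    covariates = [np.asarray(c, dtype=float) for c in covariates]
    k = len(covariates)
    if k == 0:
        r, p, n = pearson(x, y)
        return r, p, n - 2
    cols = _pairwise_complete(x, y, *covariates)
    x, y, covariates = cols[0], cols[1], cols[2:]
    n = x.size
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations for {k} covariates")
    z = np.column_stack([np.ones(n)] + list(covariates))
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("collinear covariates")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    return r, two_tailed_p_from_r(r, df), df


def correlation_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson r over the named columns (pairwise-complete)."""
    columns = columns or list(table.columns)
    out = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r, _, _ = pearson(table[a], table[b])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def partial_correlation_matrix(
    table: pd.DataFrame, columns: list[str], covariates: list[str]
) -> pd.DataFrame:
    """Pairwise partial correlations controlling for the covariate columns."""
    out = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    covs = [table[c] for c in covariates]
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r, _, _ = partial_corr(table[a], table[b], covs)
            out.loc[a, b] = out.loc[b, a] = r
    return out


# ---------------------------------------------------------------------------
# hierarchical multiple regression

def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) for p predictors."""
    if n - p - 1 <= 0:
        raise ValueError("not enough observations for the predictor count")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class HMRStage:
    """One nested model in a hierarchical regression."""

    predictors: list[str]
    r2: float
    adj_r2: float
    r2_change: float
    f_change: float
    p_f_change: float


@dataclass
class HMRResult:
    """Stagewise fit statistics plus the final standardized model."""

    stages: list[HMRStage]
    n: int
    final_betas: pd.DataFrame  # index: predictor; columns: beta, p
    final_r2: float
    final_p: float

    @property
    def r2_sequence(self) -> list[float]:
        return [s.r2 for s in self.stages]


def _ols_r2(y: np.ndarray, x: np.ndarray) -> float:
    design = np.column_stack([np.ones(y.size), x]) if x.size else np.ones((y.size, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid ** 2).sum()) / sst


def hmr(y, blocks, names: list[list[str]] | None = None) -> HMRResult:
    """Hierarchical multiple regression over ordered predictor blocks.

    ``blocks`` is an ordered sequence; each element is a 2-D array of shape
    (n, q_m) holding the predictors added at stage m (a DataFrame per block
    also works and contributes its column names). Stage m fits ordinary least
    squares of y on all predictors of blocks 1..m with an intercept and
    reports R^2, adjusted R^2, the R^2 increment over the previous stage, and
    the F test of that increment::

        F_change = (dR^2 / q_m) / ((1 - R^2_m) / (n - p_m - 1))

    with p_m cumulative predictors. The final model is refit on z-scored
    response and predictors to obtain standardized betas with per-coefficient
    two-tailed t tests, plus the overall model F p-value.

    Raises on rank deficiency, naming the offending stage.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    mats: list[np.ndarray] = []
    block_names: list[list[str]] = []
    for m, block in enumerate(blocks, start=1):
        if isinstance(block, pd.DataFrame):
            block_names.append([str(c) for c in block.columns])
            mats.append(block.to_numpy(dtype=float))
        else:
            arr = np.asarray(block, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            mats.append(arr)
            block_names.append([f"x{m}_{j + 1}" for j in range(arr.shape[1])])
    if names is not None:
        block_names = [list(b) for b in names]
    n = y.size
    total_p = sum(m.shape[1] for m in mats)
    if n <= total_p + 1:
        raise ValueError("need n > total predictors + 1")

    stages: list[HMRStage] = []
    cum: np.ndarray = np.empty((n, 0))
    cum_names: list[str] = []
    r2_prev = 0.0
    for m, (mat, bn) in enumerate(zip(mats, block_names), start=1):
        cum = np.column_stack([cum, mat]) if cum.size else mat
        cum_names = cum_names + bn
        design = np.column_stack([np.ones(n), cum])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"rank-deficient design at stage {m}")
        p_m = cum.shape[1]
        q_m = mat.shape[1]
        r2 = _ols_r2(y, cum)
        dr2 = r2 - r2_prev
        denom_df = n - p_m - 1
        f_change = (dr2 / q_m) / ((1.0 - r2) / denom_df)
        p_f = float(stats.f.sf(f_change, q_m, denom_df))
        stages.append(
            HMRStage(
                predictors=list(cum_names),
                r2=r2,
                adj_r2=adjusted_r2(r2, n, p_m),
                r2_change=dr2,
                f_change=f_change,
                p_f_change=p_f,
            )
        )
        r2_prev = r2

    zy = (y - y.mean()) / y.std(ddof=1)
    zx = (cum - cum.mean(axis=0)) / cum.std(axis=0, ddof=1)
    fit = sm.OLS(zy, sm.add_constant(zx)).fit()
    betas = pd.DataFrame(
        {"beta": fit.params[1:], "p": fit.pvalues[1:]}, index=cum_names
    )
    return HMRResult(
        stages=stages,
        n=n,
        final_betas=betas,
        final_r2=stages[-1].r2,
        final_p=float(fit.f_pvalue),
    )


# ---------------------------------------------------------------------------
# synthetic cohort

#: Target correlation structure for the synthetic cohort, columns:
#: log10(T2LV%), WMV, GMV, EDSS, 6MW, T25FW, SDMT, age. Values chosen to
#: mimic a moderately disabled MS cohort in which lesion burden and atrophy
#: track disability and age is a nuisance variable.
_COHORT_COLUMNS = ["log_t2lv", "wmv", "gmv", "edss", "sixmw", "t25fw", "sdmt", "age"]
_COHORT_CORR = np.array([
    #  logT2LV  WMV    GMV    EDSS   6MW    T25FW  SDMT   age
    [1.000, -0.532, -0.582, 0.344, -0.513, -0.438, -0.499, 0.373],
    [-0.532, 1.000, 0.693, -0.334, 0.406, 0.466, 0.704, -0.280],
    [-0.582, 0.693, 1.000, -0.195, 0.324, 0.267, 0.442, -0.410],
    [0.344, -0.334, -0.195, 1.000, -0.779, -0.796, -0.511, 0.289],
    [-0.513, 0.406, 0.324, -0.779, 1.000, 0.917, 0.556, -0.378],
    [-0.438, 0.466, 0.267, -0.796, 0.917, 1.000, 0.588, -0.404],
    [-0.499, 0.704, 0.442, -0.511, 0.556, 0.588, 1.000, -0.255],
    [0.373, -0.280, -0.410, 0.289, -0.378, -0.404, -0.255, 1.000],
])
#: Per-column (mean, sd) on the natural measurement scales. log_t2lv is the
#: log10 of T2LV in % brain volume (T2LV mean 0.86%, range ~0.01-4%); volumes
#: in normalized mm^3; 6MW in feet; T25FW in feet/s; SDMT in correct answers;
#: age in years.
_COHORT_SCALE = {
    "log_t2lv": (-0.35, 0.55),
    "wmv": (721215.0, 56756.0),
    "gmv": (662147.0, 52034.0),
    "edss": (4.5, 2.0),
    "sixmw": (1131.0, 620.0),
    "t25fw": (3.87, 1.92),
    "sdmt": (46.06, 12.16),
    "age": (51.0, 8.4),
}


def synthetic_cohort(n: int = 52, seed: int = 0) -> pd.DataFrame:
    """Simulate a cross-sectional MS cohort with a planted correlation structure.

    Draws ``n`` subjects from a multivariate normal with the module-level
    target correlation matrix, then maps each column onto its measurement
    scale; lesion burden is exponentiated so ``t2lv_pct`` is log10-normal.
    Returns a DataFrame with columns t2lv_pct, wmv_mm3, gmv_mm3, edss,
    sixmw_ft, t25fw_fps, sdmt, age_yr. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    # Symmetrize + eigenvalue clip so the target matrix is a valid covariance.
    corr = (_COHORT_CORR + _COHORT_CORR.T) / 2
    w, v = np.linalg.eigh(corr)
    corr = v @ np.diag(np.clip(w, 1e-6, None)) @ v.T
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    z = rng.multivariate_normal(np.zeros(len(_COHORT_COLUMNS)), corr, size=n,
                                method="cholesky")
    out = {}
    for j, col in enumerate(_COHORT_COLUMNS):
        mu, sd = _COHORT_SCALE[col]
        out[col] = mu + sd * z[:, j]
    df = pd.DataFrame(
        {
            "t2lv_pct": 10.0 ** out["log_t2lv"],
            "wmv_mm3": out["wmv"],
            "gmv_mm3": out["gmv"],
            "edss": np.clip(np.round(out["edss"] * 2) / 2, 0.0, 10.0),
            "sixmw_ft": np.clip(out["sixmw"], 47.0, None),
            "t25fw_fps": np.clip(out["t25fw"], 0.2, None),
            "sdmt": np.clip(np.round(out["sdmt"]), 0, 110),
            "age_yr": np.clip(np.round(out["age"]), 18, 90),
        }
    )
    df.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(n)])
    return df
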