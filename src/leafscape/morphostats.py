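"""Morphospace PCA, trait correlations, allometry, and species tests.

* PCA centers but does not scale, matching the convention used for shape
  feature matrices; percent variance is reported per component.
* Trait correlations are Pearson, with Bonferroni correction over the
  unique trait pairs in the displayed matrix.
* Allometry between two log-transformed dimensions is tested with
  standardized major axis (SMA) regression, whose slope is
  sign(r) * sd(y)/sd(x); the slope = 1 null (isometry) is tested by the
  correlation between SMA residual and fitted axis scores.
* Species contrasts use the Mann-Whitney U test (exact enumeration for
  small samples, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from leafscape.errors import ParameterError, ShapeError

__all__ = [
    "PCAResult",
    "SMAFit",
    "pca",
    "corr_matrix",
    "sma_fit",
    "mann_whitney",
    "pc_extremes",
]


@dataclass
class PCAResult:
    """Scores, loadings, and percent variance of a centered PCA."""

    scores: np.ndarray  # (n_samples, n_components)
    loadings: np.ndarray  # (n_features, n_components)
    percent_variance: np.ndarray  # sums to 100
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class SMAFit:
    """Standardized major axis fit on (already log-transformed) data."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2: float
    p_slope_h0: float  # H0: slope equals the tested null value
    n: int
    slope_h0: float = 1.0


def pca(X, center: bool = True, scale: bool = False) -> PCAResult:
    """Principal components via SVD with a deterministic sign convention.

    Components are ordered by decreasing variance; for each component the
    loading entry with the largest magnitude is made positive so PC-extreme
    accession identities are reproducible run to run.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ShapeError("X must be 2D with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ShapeError("X contains non-finite values")
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if not Xc.any():
        raise ShapeError("constant matrix: no variance to decompose")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2 / (X.shape[0] - 1)
    keep = S > S[0] * 1e-12
    U, S, Vt, var = U[:, keep], S[keep], Vt[keep], var[keep]
    # sign convention: largest-|loading| element positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = U * S
    pct = 100.0 * var / var.sum()
    return PCAResult(scores=scores, loadings=Vt.T, percent_variance=pct, mean=mean)


def corr_matrix(traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with Bonferroni-corrected p-values.

    The Bonferroni denominator is the number of unique off-diagonal trait
    pairs.  Cells with fewer than 3 complete pairs or a zero-variance
    trait are NaN.
    """
    cols = list(traits.columns)
    k = len(cols)
    n_pairs = k * (k - 1) // 2
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    np.fill_diagonal(p.values, np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            sub = traits[[cols[i], cols[j]]].dropna()
            x, y = sub.iloc[:, 0].values, sub.iloc[:, 1].values
            if len(sub) < 3 or x.std() == 0 or y.std() == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij = float(res.statistic)
                pij = min(1.0, float(res.pvalue) * n_pairs)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def sma_fit(x, y, slope_h0: float = 1.0, alpha: float = 0.05) -> SMAFit:
    """Standardized major axis regression with a slope test.

    ``x`` and ``y`` are expected already log-transformed by the caller.
    slope = sign(r) * sd(y)/sd(x); the line passes through the means.  The
    95% CI inverts the F statistic of the residual-versus-fitted
    correlation, and ``p_slope_h0`` tests H0: slope = ``slope_h0`` the
    same way (correlation between y - B0 x and y + B0 x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("need n >= 3 paired values")
    n = len(x)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0:
        raise ParameterError("zero variance in x")
    if sy == 0:
        raise ParameterError("zero variance in y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())

    # CI by F-statistic inversion
    fcrit = stats.f.ppf(1.0 - alpha, 1, n - 2)
    B = fcrit * (1.0 - r * r) / (n - 2)
    ci_low = slope * (np.sqrt(B + 1.0) - np.sqrt(B))
    ci_high = slope * (np.sqrt(B + 1.0) + np.sqrt(B))
    if slope < 0:
        ci_low, ci_high = ci_high, ci_low

    # slope test: residual vs fitted axis scores under H0
    res = y - slope_h0 * x
    fit = y + slope_h0 * x
    if res.std(ddof=1) == 0 or fit.std(ddof=1) == 0:
        p_val = 1.0 if abs(slope - slope_h0) < 1e-12 else 0.0
    else:
        r_rf = float(np.corrcoef(res, fit)[0, 1])
        r_rf = min(max(r_rf, -1.0), 1.0)
        if abs(r_rf) == 1.0:
            p_val = 0.0
        else:
            F = r_rf * r_rf * (n - 2) / (1.0 - r_rf * r_rf)
            p_val = float(stats.f.sf(F, 1, n - 2))
    return SMAFit(
        slope=slope,
        intercept=intercept,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        r2=r * r,
        p_slope_h0=p_val,
        n=n,
        slope_h0=slope_h0,
    )


def mann_whitney(
    group_a, group_b, n_comparisons: int = 1
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test with optional Bonferroni correction.

    Returns (U of group_a, two-sided p, Bonferroni-adjusted p).  The exact
    permutation distribution is used when both groups have <= 20
    observations and no ties straddle the groups; otherwise the normal
    approximation with tie correction applies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return float(res.statistic), p, min(1.0, p * n_comparisons)


def pc_extremes(result: PCAResult, k: int = 5, ids=None) -> pd.DataFrame:
    """Sample ids attaining the minimum and maximum score on each of the
    first k PCs (ties broken by first occurrence)."""
    if k > result.n_components:
        raise ParameterError(
            f"k={k} exceeds available components ({result.n_components})"
        )
    n = result.scores.shape[0]
    ids = list(ids) if ids is not None else list(range(n))
    rows = []
    for pc in range(k):
        col = result.scores[:, pc]
        imin, imax = int(np.argmin(col)), int(np.argmax(col))
        rows.append(
            {
                "pc": pc + 1,
                "min_id": ids[imin],
                "max_id": ids[imax],
                "degenerate": bool(np.ptp(col) == 0),
            }
        )
    return pd.DataFrame(rows).set_index("pc")
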