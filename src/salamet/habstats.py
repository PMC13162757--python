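"""Spawning-habitat statistical screen.

Given a site table (one row per spawning site: water chemistry, habitat
area, outline circularity, egg-sac count) this module provides the standard
exploratory screen for "which conditions go with more egg sacs":

* Z-score standardization, Z = (X - mu) / sigma, so variables on different
  units are comparable;
* a Pearson correlation screen with two-sided p-values from the t transform
  t = r * sqrt(n-2) / sqrt(1-r^2), pairwise-complete observations (dried-up
  sites lack chemistry), and Bonferroni correction applied to the
  environment-vs-response family only (default family size 9);
* post hoc power for a correlation via the Fisher-z approximation;
* variance inflation factors, VIF_j = 1 / (1 - R^2_j), for collinearity
  diagnosis (duplicate measures such as DO mg/L vs DO %% show up here);
* PCA of the standardized variables (correlation-matrix PCA via SVD) with a
  fixed sign convention;
* mean / SE / 95%% CI descriptive summaries with the normal multiplier
  z = 1.96.

``infer_sample_size`` inverts a printed (r, p) pair back to the sample size
implied by the t transform — useful as an internal-consistency check on
published correlation tables that omit n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError

__all__ = [
    "SITE_VARIABLES",
    "CorrelationScreen",
    "PCAResult",
    "zscore",
    "pearson_screen",
    "posthoc_power_correlation",
    "vif",
    "pca",
    "describe_with_ci",
    "ci_from_summary",
    "infer_sample_size",
]

#: canonical environment-variable columns of a site table (response: egg_sac)
SITE_VARIABLES = (
    "temp_C", "pH", "do_mgL", "do_pct", "conductivity_uScm",
    "alkalinity_mgL_CaCO3", "turbidity_NTU", "area_m2", "circularity_pct",
)


def zscore(table: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each column to mean 0, sample SD 1.

    Missing values are ignored in mu/sigma and propagate as missing.
    A constant column raises, naming the column.
    """
    df = table.astype(float)
    sd = df.std(ddof=ddof)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        raise ValidationError(f"constant column(s), cannot standardize: {constant}")
    return (df - df.mean()) / sd


@dataclass
class CorrelationScreen:
    """Pairwise Pearson r/p/n matrices plus the corrected response screen."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    response: pd.DataFrame  # per-variable r, p_uncorrected, p_bonferroni, n
    family_size: int


def _pearson_pairwise(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan, np.nan, n
    r, _ = stats.pearsonr(x[ok], y[ok])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


def pearson_screen(table: pd.DataFrame, response: str = "egg_sac",
                   family_size: int = 9) -> CorrelationScreen:
    """Pearson correlation screen with Bonferroni correction on the response
    row.

    Uses pairwise-complete observations; pairs with fewer than 3 complete
    observations are skipped with a warning and reported as NaN.
    """
    if response not in table.columns:
        raise ValidationError(f"response column {response!r} not in table")
    cols = list(table.columns)
    k = len(cols)
    r_mat = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p_mat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n_mat = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    arr = table.astype(float).to_numpy()
    for i in range(k):
        n_mat.iloc[i, i] = int(np.isfinite(arr[:, i]).sum())
        for j in range(i + 1, k):
            r, p, n = _pearson_pairwise(arr[:, i], arr[:, j])
            if n < 3:
                warnings.warn(f"pair ({cols[i]}, {cols[j]}): only {n} complete "
                              "observations; skipped", stacklevel=2)
            r_mat.iloc[i, j] = r_mat.iloc[j, i] = r
            p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
            n_mat.iloc[i, j] = n_mat.iloc[j, i] = n
    others = [c for c in cols if c != response]
    resp = pd.DataFrame({
        "variable": others,
        "r": [r_mat.loc[response, c] for c in others],
        "p_uncorrected": [p_mat.loc[response, c] for c in others],
        "n": [n_mat.loc[response, c] for c in others],
    })
    resp["p_bonferroni"] = np.minimum(1.0, family_size * resp["p_uncorrected"])
    return CorrelationScreen(r_mat, p_mat, n_mat, resp, family_size)


def posthoc_power_correlation(r: float, n: int, alpha: float = 0.05) -> float:
    """Power to detect a correlation of magnitude ``r`` at sample size ``n``.

    Fisher-z approximation: with zeta = atanh(|r|) * sqrt(n - 3) the
    two-sided power is Phi(zeta - z_crit) + Phi(-zeta - z_crit).  At r = 0
    this returns alpha exactly.
    """
    if not (0 <= abs(r) < 1):
        raise ValidationError("|r| must be < 1")
    if n < 4:
        raise ValidationError("n must be >= 4")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    zcrit = stats.norm.ppf(1 - alpha / 2)
    zeta = np.arctanh(abs(r)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(zeta - zcrit) + stats.norm.cdf(-zeta - zcrit))


def vif(table: pd.DataFrame, predictors: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per predictor.

    VIF_j = 1 / (1 - R^2_j) from least-squares regression of predictor j on
    the remaining predictors (with intercept).  Exact collinearity is
    reported as ``inf`` rather than raising.
    """
    cols = list(predictors) if predictors is not None else list(table.columns)
    if len(cols) < 2:
        raise ValidationError("VIF needs at least two predictors")
    df = table[cols].astype(float).dropna()
    if df.shape[0] < len(cols) + 2:
        raise ValidationError("too few complete rows for VIF")
    if (df.std(ddof=1) == 0).any():
        bad = df.columns[(df.std(ddof=1) == 0)].tolist()
        raise ValidationError(f"constant predictor(s): {bad}")
    out = {}
    X = df.to_numpy()
    for j, col in enumerate(cols):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class PCAResult:
    """Loadings (variables x components), scores (rows x components) and the
    percentage of variance per component."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_pct: pd.Series


def pca(table: pd.DataFrame) -> PCAResult:
    """PCA of an already-standardized table via SVD.

    Variance percentages sum to 100 over all returned components; each
    component's sign is fixed so its largest-magnitude loading is positive.
    """
    df = table.astype(float)
    if df.isna().any().any():
        raise ValidationError("PCA input must be complete (no missing values)")
    n, k = df.shape
    if n < 2 or k < 1:
        raise ValidationError("PCA needs >= 2 rows and >= 1 column")
    X = df.to_numpy() - df.to_numpy().mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(Vt.shape[0]):
        idx = np.argmax(np.abs(Vt[c]))
        if Vt[c, idx] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValidationError("degenerate input: zero total variance")
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(Vt.T, index=df.columns, columns=comps),
        scores=pd.DataFrame(U * s, index=df.index, columns=comps),
        variance_pct=pd.Series(100.0 * var / total, index=comps),
    )


def ci_from_summary(mean: float, se: float, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation confidence interval from a printed mean and SE."""
    return mean - z * se, mean + z * se


def describe_with_ci(values, z: float = 1.96) -> dict[str, float]:
    """Mean, standard error and z-based CI of a sample (NaNs dropped)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValidationError("describe_with_ci needs n >= 2 observations")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(len(x)))
    lo, hi = ci_from_summary(mean, se, z)
    return {"mean": mean, "se": se, "ci_low": lo, "ci_high": hi, "n": len(x)}


def infer_sample_size(r: float, p: float) -> float:
    """Sample size implied by a two-sided Pearson (r, p) pair.

    Inverts p = 2 * sf_t(|r| sqrt(n-2) / sqrt(1-r^2); n-2) for continuous n.
    """
    if not 0 < abs(r) < 1 or not 0 < p < 1:
        raise ValidationError("need 0 < |r| < 1 and 0 < p < 1")

    def f(n):
        t = abs(r) * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        return 2 * stats.t.sf(t, n - 2) - p

    return float(optimize.brentq(f, 3.0001, 1e6))
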