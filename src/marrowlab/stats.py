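"""Cohort statistics: normality screening, OLS regressions, bootstrap validation.

Pairwise associations between marrow fat fraction, CT parameters and
normalized failure load are quantified with simple linear regressions
(slope B, its standard error, Pearson r, two-sided p from the t distribution
with n-2 df).  Because specimen cohorts are small, each regression is also
validated by case bootstrap: specimens are resampled with replacement and
the replicate-slope distribution yields a bootstrap standard error and a
sign-crossing p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class RegressionResult:
    slope: float       # B, units of y per unit of x
    intercept: float
    se_slope: float
    r: float           # Pearson correlation, carries the sign of B
    p: float           # two-sided
    n: int


@dataclass
class BootstrapResult:
    n_boot: int
    se_slope: float
    p: float
    seed: int
    quantiles: dict[float, float]    # of the replicate slope distribution
    n_redrawn: int                   # degenerate (constant-x) replicates redrawn


def ks_normality(values, lilliefors_correction: bool = True) -> tuple[float, float]:
    """One-sample KS test against a normal with sample-estimated mean and SD.

    With ``lilliefors_correction`` (default) the p-value accounts for the
    parameters having been estimated from the same sample; without it the
    plain KS p-value is returned (anti-conservative, but the variant some
    statistics packages report).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs at least three values")
    if np.std(x) == 0:
        raise ValueError("zero variance: normality test undefined")
    if lilliefors_correction:
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
        return float(stat), float(p)
    res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the conventional summary."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least three points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: regression undefined")
    fit = sps.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            se_slope=float(fit.stderr), r=float(fit.rvalue),
                            p=float(fit.pvalue), n=int(n))


def bootstrap_regression(x, y, n_boot: int = 1000, seed: int = 0,
                         p_method: str = "sign") -> BootstrapResult:
    """Case-resampling bootstrap of the regression slope.

    ``n_boot`` replicates of size n are drawn with replacement from the
    (x, y) pairs; replicates with constant x (no defined slope) are redrawn
    and counted.  The bootstrap SE is the SD of the replicate slopes.  The
    p-value is, with ``p_method="sign"``, twice the smaller tail fraction of
    replicate slopes on either side of zero (floored at 2/n_boot); with
    ``p_method="normal"``, a two-sided normal test of B against the
    bootstrap SE.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("bootstrap needs at least three pairs")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if p_method not in ("sign", "normal"):
        raise ValueError("p_method must be 'sign' or 'normal'")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    n_redrawn = 0
    while True:
        xb = x[idx]
        degenerate = np.ptp(xb, axis=1) == 0
        if not degenerate.any():
            break
        n_redrawn += int(degenerate.sum())
        idx[degenerate] = rng.integers(0, n, size=(int(degenerate.sum()), n))

    yb = y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    sxx = ((xb - xm) ** 2).sum(axis=1)
    sxy = ((xb - xm) * (yb - ym)).sum(axis=1)
    slopes = sxy / sxx

    se = float(np.std(slopes, ddof=1))
    if p_method == "sign":
        p = 2.0 * min(float(np.mean(slopes <= 0)), float(np.mean(slopes >= 0)))
        p = float(np.clip(max(p, 2.0 / n_boot), 0.0, 1.0))
    else:
        b = linreg(x, y).slope
        p = 1.0 if se == 0 and b == 0 else (
            float(np.clip(max(2.0 * sps.norm.sf(abs(b) / se), 2.0 / n_boot), 0.0, 1.0))
            if se > 0 else 2.0 / n_boot)
    qs = (0.025, 0.25, 0.5, 0.75, 0.975)
    quantiles = {q: float(np.quantile(slopes, q)) for q in qs}
    return BootstrapResult(n_boot=n_boot, se_slope=se, p=p, seed=seed,
                           quantiles=quantiles, n_redrawn=n_redrawn)


# Pairwise models of the published regression layout: fat fraction against
# strength and CT parameters, and normalized failure load against the rest.
TABLE_PAIRS: tuple[tuple[str, str], ...] = (
    ("fat_fraction", "norm_fl"),
    ("fat_fraction", "bmd"),
    ("fat_fraction", "bv_tv"),
    ("fat_fraction", "tbn"),
    ("fat_fraction", "fd"),
    ("norm_fl", "fat_fraction"),
    ("norm_fl", "bmd"),
    ("norm_fl", "bv_tv"),
    ("norm_fl", "tbn"),
    ("norm_fl", "fd"),
)

# Percent-scaled variables regressed on as fractions so slope magnitudes are
# comparable with the conventional reporting.
_FRACTIONAL = {"fat_fraction": 0.01, "bv_tv": 0.01}


def build_regression_table(cohort: pd.DataFrame, seed: int = 0,
                           n_boot: int = 1000,
                           fractional_units: bool = True,
                           p_method: str = "sign") -> pd.DataFrame:
    """All pairwise regressions of the standard layout, with bootstrap columns.

    Each row regresses column ``y`` on column ``x`` of the cohort table.
    With ``fractional_units`` (default) percent-valued predictors (fat
    fraction, BV/TV) enter as fractions, which only rescales slopes; r and
    p are unit-free.  No multiple-testing correction is applied.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for y_name, x_name in TABLE_PAIRS:
        x = cohort[x_name].to_numpy(dtype=float)
        y = cohort[y_name].to_numpy(dtype=float)
        if fractional_units:
            x = x * _FRACTIONAL.get(x_name, 1.0)
            y = y * _FRACTIONAL.get(y_name, 1.0)
        reg = linreg(x, y)
        bseed = int(rng.integers(0, 2**31 - 1))
        boot = bootstrap_regression(x, y, n_boot=n_boot, seed=bseed,
                                    p_method=p_method)
        rows.append({
            "y": y_name, "x": x_name, "n": reg.n,
            "B": reg.slope, "se_B": reg.se_slope, "r": reg.r, "p": reg.p,
            "se_B_boot": boot.se_slope, "p_boot": boot.p,
            "n_boot": boot.n_boot, "boot_seed": bseed,
        })
    return pd.DataFrame(rows)
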