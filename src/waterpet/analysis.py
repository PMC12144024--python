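"""Reconstruction-comparison statistics.

Works on a long-format CBF table with one row per (subject, method, region,
quantification) and the CBF value in mL/cm3/min.  Provides the per-method
summaries (mean +/- SD and GM/CWM ratio), median relative percentage
difference matrices between methods, exact Wilcoxon signed-rank tests
against the reference method, Shapiro–Wilk normality checks, and linear
regressions of mean CBF on effective spatial resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "load_reference_cbf_means",
    "gm_cwm_ratio",
    "summarize_cbf",
    "percent_diff_matrix",
    "paired_signed_rank",
    "normality_check",
    "regress_cbf_on_resolution",
]

REGIONS = ("WB", "GM", "CWM")
QUANTIFICATIONS = ("regional", "voxelwise")


def load_reference_cbf_means() -> pd.DataFrame:
    """Published per-method mean +/- SD CBF table (reference cohort, n = 8).

    Columns: method, region, quantification, mean_cbf, sd_cbf.
    """
    with resources.files("waterpet").joinpath(
        "data/reference_cbf_means.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _ratio_1dp(gm: float, cwm: float) -> float:
    """GM/CWM ratio to one decimal, half away from zero.

    The division is done in decimal so that printed-precision inputs behave
    like hand arithmetic (0.57 / 0.20 = 2.85 -> 2.9, not 2.8499... -> 2.8).
    """
    q = Decimal(repr(gm)) / Decimal(repr(cwm))
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gm_cwm_ratio(
    means: pd.DataFrame, method: str, quantification: str = "regional"
) -> float:
    """GM/CWM ratio of mean CBF for one method, one decimal, half away from 0.

    ``means`` needs columns method, region, quantification, mean_cbf.
    """
    sel = means[(means["method"] == method) & (means["quantification"] == quantification)]
    gm = float(sel.loc[sel["region"] == "GM", "mean_cbf"].iloc[0])
    cwm = float(sel.loc[sel["region"] == "CWM", "mean_cbf"].iloc[0])
    return _ratio_1dp(gm, cwm)


def _check_complete(table: pd.DataFrame) -> None:
    counts = table.groupby(["method", "region", "quantification"])["subject"].nunique()
    if counts.nunique() > 1:
        missing = counts[counts < counts.max()]
        raise ValueError(f"incomplete subject crossing for cells: {list(missing.index)}")


def summarize_cbf(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean and sample SD (ddof=1) per region and quantification.

    Adds the GM/CWM ratio (one decimal, half away from zero) per
    (method, quantification).
    """
    if table["subject"].nunique() < 2:
        raise ValueError("at least 2 subjects required")
    _check_complete(table)
    out = (
        table.groupby(["method", "region", "quantification"], sort=False)["cbf"]
        .agg(mean_cbf="mean", sd_cbf=lambda v: v.std(ddof=1))
        .reset_index()
    )
    ratios = {}
    for (method, quant), grp in out.groupby(["method", "quantification"], sort=False):
        gm = grp.loc[grp["region"] == "GM", "mean_cbf"]
        cwm = grp.loc[grp["region"] == "CWM", "mean_cbf"]
        if len(gm) and len(cwm) and float(cwm.iloc[0]) > 0:
            ratios[(method, quant)] = _ratio_1dp(float(gm.iloc[0]), float(cwm.iloc[0]))
    out["gm_cwm_ratio"] = [
        ratios.get((m, q), np.nan)
        for m, q in zip(out["method"], out["quantification"])
    ]
    return out


def percent_diff_matrix(
    table: pd.DataFrame, region: str, quantification: str
) -> pd.DataFrame:
    """Median relative percentage difference between every method pair.

    Entry (A, B) = median over subjects of 100 * (CBF_A - CBF_B) / CBF_B.
    The denominator is the column method B, so the matrix is not exactly
    antisymmetric.  Diagonal is 0; entries with a zero denominator for any
    subject are NaN.
    """
    sel = table[(table["region"] == region) & (table["quantification"] == quantification)]
    wide = sel.pivot(index="subject", columns="method", values="cbf")
    if wide.isna().any().any():
        raise ValueError("incomplete subject/method crossing")
    methods = list(wide.columns)
    mat = pd.DataFrame(index=methods, columns=methods, dtype=float)
    for a in methods:
        for b in methods:
            if a == b:
                mat.loc[a, b] = 0.0
                continue
            denom = wide[b].to_numpy()
            if np.any(denom == 0):
                mat.loc[a, b] = np.nan
                continue
            mat.loc[a, b] = float(
                np.median(100.0 * (wide[a].to_numpy() - denom) / denom)
            )
    return mat


def paired_signed_rank(
    table: pd.DataFrame,
    method: str,
    reference: str,
    region: str,
    quantification: str,
) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test of method vs reference.

    Zero differences are dropped (Wilcoxon's convention); with the study's
    n <= 25 the exact null distribution is used.  If all differences are
    zero the result is degenerate and p = 1 is returned with statistic NaN.
    """
    sel = table[(table["region"] == region) & (table["quantification"] == quantification)]
    wide = sel.pivot(index="subject", columns="method", values="cbf")
    x = wide[method].to_numpy(float)
    y = wide[reference].to_numpy(float)
    if x.size < 5:
        raise ValueError("at least 5 pairs required")
    d = x - y
    if np.all(d == 0):
        return float("nan"), 1.0
    res = stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", method="exact"
    )
    return float(res.statistic), float(res.pvalue)


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p for per-subject CBF values (3<=n<=50)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro–Wilk requires at least 3 values")
    if values.size > 50:
        raise ValueError("Shapiro–Wilk supported here for n <= 50")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of mean CBF on effective resolution, with 95% intervals."""

    slope: float  # mL/cm3/min per mm
    slope_ci: tuple[float, float]
    intercept: float
    pearson_r: float
    r_ci: tuple[float, float]
    r_squared: float
    n: int


def regress_cbf_on_resolution(
    means: np.ndarray, resolutions: np.ndarray
) -> RegressionResult:
    """Simple linear regression of per-method mean CBF on effective FWHM.

    Slope CI is t-based; the Pearson-r CI uses the Fisher z transform
    (NaN bounds for n = 3, where the transform is undefined).
    """
    y = np.asarray(means, dtype=float)
    x = np.asarray(resolutions, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in resolutions")
    fit = stats.linregress(x, y)
    n = x.size
    tcrit = stats.t.ppf(0.975, n - 2)
    slope_ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    r = fit.rvalue
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        r_ci = (float(np.tanh(z - 1.959963984540054 * se)),
                float(np.tanh(z + 1.959963984540054 * se)))
    else:
        r_ci = (float("nan"), float("nan"))
    return RegressionResult(
        slope=float(fit.slope),
        slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
        intercept=float(fit.intercept),
        pearson_r=float(r),
        r_ci=r_ci,
        r_squared=float(r**2),
        n=n,
    )
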