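"""Exploratory pre/post comparisons and nonparametric effect sizes.

Group differences between the two test occasions are screened with
Wilcoxon-Mann-Whitney U tests (interval/ordinal variables) or chi-squared
tests on occasion-by-level counts (binary/nominal variables), without
multiplicity correction — the screen is exploratory and p-values are
reported raw.

Effect sizes use the nonparametric "Impact" measure, which combines a
robust central-tendency difference with a distribution-shape difference so
that it stays meaningful for ordinal and one-hot recoded data:

    CT    = (median(y) - median(x)) / s_pool,
            s_pool = sqrt((sigma_x^2 + sigma_y^2) / 2),
            sigma  = 1.4826 * MAD (falling back to the SD when MAD = 0)
    SHAPE = 1 - overlap of the kernel-density estimates of the two
            median-centered samples on a shared grid
    Impact = sign(CT) * max(|CT|, SHAPE)

For location-shifted Gaussian samples Impact closely tracks Cohen's d,
which is the fidelity contract tested in the suite. Confidence intervals
come from percentile bootstrap over patient resamples.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import OCCASIONS, Schema

__all__ = [
    "EffectResult",
    "explore_pre_post",
    "impact",
    "cohens_d",
    "bootstrap_ci",
]

_MAD_SCALE = 1.4826  # consistency constant for the normal distribution


@dataclass(frozen=True)
class EffectResult:
    variable: str
    test: str                       # "mann-whitney-u" | "chi2" | "wilcoxon-signed-rank"
    p_value: float
    impact: float | None = None
    ci95: tuple | None = None
    n_boot: int = 0
    untestable: bool = False


def _robust_sigma(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    if mad > 0:
        return _MAD_SCALE * mad
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def _kde_overlap(x: np.ndarray, y: np.ndarray) -> float:
    """Overlap coefficient of Gaussian KDEs of two median-centered samples.

    Silverman bandwidths, a shared 512-point grid spanning the pooled range
    extended by three bandwidths, overlap as the Riemann sum of pointwise
    minima.
    """
    xc = x - np.median(x)
    yc = y - np.median(y)

    def bandwidth(v: np.ndarray) -> float:
        sd = np.std(v, ddof=1) if v.size > 1 else 0.0
        iqr = np.subtract(*np.percentile(v, [75, 25]))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        if spread == 0:
            spread = max(abs(v).max(), 1.0) * 1e-3
        return 0.9 * spread * v.size ** (-1 / 5)

    hx, hy = bandwidth(xc), bandwidth(yc)
    h = max(hx, hy, 1e-12)
    lo = min(xc.min(), yc.min()) - 3 * h
    hi = max(xc.max(), yc.max()) + 3 * h
    grid = np.linspace(lo, hi, 512)
    step = grid[1] - grid[0]

    def kde(v: np.ndarray, bw: float) -> np.ndarray:
        z = (grid[:, None] - v[None, :]) / bw
        return np.exp(-0.5 * z**2).sum(axis=1) / (v.size * bw * np.sqrt(2 * np.pi))

    fx, fy = kde(xc, max(hx, 1e-12)), kde(yc, max(hy, 1e-12))
    return float(np.minimum(fx, fy).sum() * step)


def impact(x_values, y_values) -> float:
    """Signed nonparametric effect size of y relative to x."""
    x = np.asarray(x_values, float)
    y = np.asarray(y_values, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 5 or y.size < 5:
        raise ValueError("need >= 5 non-missing values per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 0.0
    if x.size == y.size and np.array_equal(np.sort(x), np.sort(y)):
        return 0.0  # identical samples: no effect, exactly

    sx, sy = _robust_sigma(x), _robust_sigma(y)
    s_pool = np.sqrt((sx**2 + sy**2) / 2)
    med_diff = np.median(y) - np.median(x)
    ct = med_diff / s_pool if s_pool > 0 else 0.0
    shape = 1.0 - min(_kde_overlap(x, y), 1.0)
    sign = np.sign(ct) if ct != 0 else np.sign(y.mean() - x.mean())
    if sign == 0:
        sign = 1.0
    return float(sign * max(abs(ct), shape))


def cohens_d(x, y) -> float:
    """Classical standardized mean difference, pooled by degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((y.mean() - x.mean()) / np.sqrt(pooled_var))


def bootstrap_ci(statistic, x, y, n_boot: int = 1000, seed: int | None = None
                 ) -> tuple[float, float]:
    """Percentile bootstrap 95% CI of a two-sample statistic.

    Each group is resampled with replacement at its original size; the CI
    is the 2.5th/97.5th percentile range of the resampled statistics.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} < 100 gives unstable percentile CIs",
                      stacklevel=2)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        xb = x[rng.integers(0, x.size, x.size)]
        yb = y[rng.integers(0, y.size, y.size)]
        vals[b] = statistic(xb, yb)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def explore_pre_post(table: pd.DataFrame, schema: Schema, alpha: float = 0.05,
                     n_boot: int = 1000, seed: int | None = None,
                     paired: bool = False, effect_sizes: bool = True,
                     ) -> list[EffectResult]:
    """Per-variable occasion comparison with effect sizes.

    Interval/ordinal variables: two-sample Wilcoxon-Mann-Whitney U between
    occasions (a paired signed-rank alternative is available via
    ``paired=True``); binary/nominal variables: chi-squared on occasion x
    level counts. No multiplicity correction is applied. Results are sorted
    by decreasing |Impact|.
    """
    results = []
    base = table[table["occasion"] == "baseline"]
    post = table[table["occasion"] == "post"]
    for var in schema:
        if var.name not in table.columns:
            continue
        x = base[var.name].to_numpy(float)
        y = post[var.name].to_numpy(float)
        x_obs, y_obs = x[~np.isnan(x)], y[~np.isnan(y)]
        pooled = np.concatenate([x_obs, y_obs])
        if pooled.size == 0 or np.ptp(pooled) == 0:
            results.append(EffectResult(var.name, "degenerate", np.nan,
                                        untestable=True))
            continue
        if var.is_numeric:
            if paired:
                ok = ~np.isnan(x) & ~np.isnan(y)
                if np.ptp(x[ok] - y[ok]) == 0 and (x[ok] == y[ok]).all():
                    results.append(EffectResult(var.name, "wilcoxon-signed-rank",
                                                1.0, impact=0.0))
                    continue
                stat = stats.wilcoxon(x[ok], y[ok])
                test = "wilcoxon-signed-rank"
            else:
                stat = stats.mannwhitneyu(x_obs, y_obs, alternative="two-sided")
                test = "mann-whitney-u"
            p = float(stat.pvalue)
            eff, ci = None, None
            if effect_sizes:
                eff = impact(x_obs, y_obs)
                ci = bootstrap_ci(impact, x_obs, y_obs, n_boot=n_boot, seed=seed)
            results.append(EffectResult(var.name, test, p, impact=eff, ci95=ci,
                                        n_boot=n_boot if effect_sizes else 0))
        else:
            levels = sorted(set(pooled))
            counts = np.array([
                [(x_obs == lv).sum() for lv in levels],
                [(y_obs == lv).sum() for lv in levels],
            ])
            counts = counts[:, counts.sum(axis=0) > 0]
            if counts.shape[1] < 2:
                results.append(EffectResult(var.name, "chi2", np.nan,
                                            untestable=True))
                continue
            chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
            eff, ci = None, None
            if effect_sizes:
                eff = impact(x_obs, y_obs)
                ci = bootstrap_ci(impact, x_obs, y_obs, n_boot=n_boot, seed=seed)
            results.append(EffectResult(var.name, "chi2", float(p), impact=eff,
                                        ci95=ci, n_boot=n_boot if effect_sizes else 0))
    results.sort(key=lambda r: -abs(r.impact) if r.impact is not None else np.inf)
    return results
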