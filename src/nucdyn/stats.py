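"""Statistical layer: group comparisons, outlier-filtered correlation,
and Gaussian histogram fits.

Conventions, used consistently and echoed into output metadata:

* sample (n-1) standard deviations;
* the outlier rule is one-sided (high values only) and single-pass — the
  mean and SD are computed once on the full input, and points above
  ``mean + 2 SD`` on either axis are removed, with no re-iteration;
* Bonferroni correction multiplies each raw pairwise p by the number of
  comparisons, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationFit",
    "GaussianFit",
    "remove_outliers_2sd",
    "pearson_fit",
    "filtered_pearson_fit",
    "anova_bonferroni",
    "gaussian_fit_histogram",
]


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    anova_F: float
    anova_p: float
    pairwise: dict[tuple[str, str], dict[str, float]]  # raw and corrected p per pair
    n_comparisons: int


@dataclass
class CorrelationFit:
    n_in: int
    n_removed: int
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    valid: bool = True


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float
    bin_centers: np.ndarray
    counts: np.ndarray
    fitted: np.ndarray
    converged: bool


def remove_outliers_2sd(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided mean + 2 SD outlier filter on paired data.

    A pair is removed if its x exceeds ``mean(x) + 2*sd(x)`` or its y exceeds
    ``mean(y) + 2*sd(y)`` (strict inequality, sample SD, thresholds computed
    once on the full input).  Returns ``(x_kept, y_kept, removed_mask)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    thr_x = x.mean() + 2.0 * x.std(ddof=1)
    thr_y = y.mean() + 2.0 * y.std(ddof=1)
    removed = (x > thr_x) | (y > thr_y)
    return x[~removed], y[~removed], removed


def pearson_fit(x: np.ndarray, y: np.ndarray) -> CorrelationFit:
    """Pearson correlation plus ordinary least-squares line for paired data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        return CorrelationFit(len(x), 0, np.nan, np.nan, np.nan, np.nan, valid=False)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = sps.pearsonr(x, y)
    res = sps.linregress(x, y)
    return CorrelationFit(len(x), 0, float(r), float(p), float(res.slope), float(res.intercept))


def filtered_pearson_fit(x: np.ndarray, y: np.ndarray) -> CorrelationFit:
    """Outlier filter (mean + 2 SD, one-sided) followed by :func:`pearson_fit`."""
    xk, yk, removed = remove_outliers_2sd(x, y)
    if len(xk) < 3:
        return CorrelationFit(len(xk), int(removed.sum()), np.nan, np.nan, np.nan, np.nan, valid=False)
    fit = pearson_fit(xk, yk)
    fit.n_removed = int(removed.sum())
    return fit


def anova_bonferroni(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA plus Bonferroni-corrected pairwise two-sample t tests."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    values = list(arrays.values())
    if np.ptp(np.concatenate(values)) == 0:
        # all values identical across all groups: F is 0/0; report the
        # degenerate no-difference result instead of a NaN surprise
        F, p = 0.0, 1.0
    else:
        F, p = sps.f_oneway(*values)
    pairs = list(combinations(arrays, 2))
    k = len(pairs)
    pairwise = {}
    for a, b in pairs:
        if np.ptp(arrays[a]) == 0 and np.ptp(arrays[b]) == 0 and arrays[a].mean() == arrays[b].mean():
            raw = 1.0
        else:
            raw = float(sps.ttest_ind(arrays[a], arrays[b]).pvalue)
        pairwise[(a, b)] = {"p_raw": raw, "p_bonferroni": min(1.0, raw * k)}
    return GroupComparison(arrays, float(F), float(p), pairwise, k)


def gaussian_fit_histogram(
    values: Sequence[float], bin_width: float | None = None
) -> GaussianFit:
    """Least-squares Gaussian fit to a histogram of the values.

    The curve ``A * exp(-(x - mu)^2 / (2 sigma^2))`` is fitted to the binned
    counts (free amplitude, as plotting software does).  Default bin width is
    Freedman-Diaconis.  Non-convergence and degenerate inputs are flagged;
    the raw histogram is always returned.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 values for a histogram fit")
    if bin_width is None:
        edges = np.histogram_bin_edges(values, bins="fd")
        if len(edges) < 3:  # FD collapses for near-constant data
            edges = np.histogram_bin_edges(values, bins=3)
    else:
        if bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        lo, hi = values.min(), values.max() + bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    mu0, sd0 = float(values.mean()), float(values.std(ddof=1))
    if np.ptp(values) == 0 or sd0 == 0 or len(centers) < 3:
        return GaussianFit(mu0, sd0, float(counts.max(initial=0)), centers, counts,
                           np.zeros_like(centers, dtype=float), converged=False)
    try:
        popt, _ = optimize.curve_fit(
            gauss, centers, counts, p0=[counts.max(), mu0, sd0], maxfev=10000
        )
        amp, mu, sigma = popt
        return GaussianFit(float(mu), abs(float(sigma)), float(amp), centers, counts,
                           gauss(centers, *popt), converged=True)
    except RuntimeError:
        return GaussianFit(mu0, sd0, float(counts.max()), centers, counts,
                           np.zeros_like(centers, dtype=float), converged=False)
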