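"""Nuclear dynamics metrics: area, circularity and edge fluctuations.

The central quantity is the percentage-residual amplitude of the projected
nuclear area: the area series A(t) is de-trended with a third-order
polynomial fit (absorbing slow drift from cell spreading or focus), the
residuals are expressed as a percentage of the trend,

    pct(t) = (A(t) - poly(t)) / poly(t) * 100,

and the sample standard deviation of pct(t) is the fluctuation amplitude
(its square is reported as the variance).  Sample (n-1) conventions are
used for every SD/variance in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import NucleusTrack

__all__ = [
    "FluctuationResult",
    "detrend_area_series",
    "fluctuation_amplitude",
    "circularity_fluctuation",
    "edge_fluctuations",
    "analyze_track",
]


@dataclass
class FluctuationResult:
    """All shape-dynamics statistics of one nucleus track."""

    times: np.ndarray  # s
    areas: np.ndarray  # um^2
    trend: np.ndarray  # um^2, cubic fit values
    pct_residuals: np.ndarray  # %
    amp_sd: float  # % (SD of pct_residuals)
    amp_var: float  # %^2 (= amp_sd^2 exactly)
    circ_mean: float
    circ_sd: float
    circ_fluct: float  # % (coefficient of variation of circularity)
    edge_fluct: np.ndarray  # per-lag-pair non-overlap ratios
    edge_fluct_mean: float


def detrend_area_series(
    areas: np.ndarray, times: np.ndarray, order: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial de-trend of an area time series.

    The time axis is rescaled to [-1, 1] before fitting for numerical
    conditioning (the fitted values are analytically identical).  Returns
    ``(trend, residuals)`` with ``residuals = areas - trend``.
    """
    areas = np.asarray(areas, dtype=float)
    times = np.asarray(times, dtype=float)
    if areas.shape != times.shape or areas.ndim != 1:
        raise ValueError("areas and times must be 1-D arrays of equal length")
    if len(areas) <= order + 1:
        raise ValueError(
            f"series too short for order-{order} detrend: need > {order + 1} points, "
            f"got {len(areas)}"
        )
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    x = 2.0 * (times - times[0]) / (times[-1] - times[0]) - 1.0
    coeffs = np.polynomial.polynomial.polyfit(x, areas, order)
    trend = np.polynomial.polynomial.polyval(x, coeffs)
    return trend, areas - trend


def fluctuation_amplitude(
    areas: np.ndarray, times: np.ndarray, order: int = 3
) -> tuple[np.ndarray, float, float]:
    """Percentage-residual fluctuation amplitude of an area series.

    Returns ``(pct_residuals, amp_sd, amp_var)``; ``amp_var`` is exactly
    ``amp_sd ** 2``.
    """
    trend, resid = detrend_area_series(areas, times, order=order)
    if np.any(trend <= 0):
        raise ValueError(
            "fitted trend crosses zero; the area series is malformed "
            "(upstream segmentation failure?)"
        )
    pct = resid / trend * 100.0
    amp_sd = float(np.std(pct, ddof=1))
    return pct, amp_sd, amp_sd**2


def circularity_fluctuation(circ: np.ndarray) -> tuple[float, float, float]:
    """Mean, SD and scaled SD (CV in %) of a circularity time series.

    ``S = sigma / mu * 100`` is the coefficient of variation in percent.
    """
    circ = np.asarray(circ, dtype=float)
    if circ.ndim != 1 or len(circ) < 2:
        raise ValueError("need a 1-D series with >= 2 points")
    mu = float(np.mean(circ))
    if mu <= 0:
        raise ValueError("mean circularity must be > 0")
    sigma = float(np.std(circ, ddof=1))
    return mu, sigma, sigma / mu * 100.0


def edge_fluctuations(
    masks: np.ndarray, lag: int = 1, align_centroids: bool = True
) -> np.ndarray:
    """Boundary-motion metric: lagged non-overlap ratio of nucleus masks.

    ``ratio(t) = area(mask(t) XOR mask(t+lag)) / area(mask(t))``.  With
    ``align_centroids`` (default) each later mask is translated by the
    integer-rounded centroid displacement first, so whole-nucleus migration
    does not count as boundary motion.
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3:
        raise ValueError("masks must be T x H x W")
    T = masks.shape[0]
    if not 1 <= lag < T:
        raise ValueError("lag must satisfy 1 <= lag < T")
    ratios = np.full(T - lag, np.nan)
    for t in range(T - lag):
        a, b = masks[t], masks[t + lag]
        na = a.sum()
        if na == 0 or b.sum() == 0:
            continue  # flagged as NaN
        if align_centroids:
            ca = np.array(ndimage.center_of_mass(a))
            cb = np.array(ndimage.center_of_mass(b))
            shift = np.round(ca - cb).astype(int)
            b = np.roll(b, shift, axis=(0, 1))
        ratios[t] = np.logical_xor(a, b).sum() / na
    return ratios


def analyze_track(
    track: NucleusTrack, lag: int = 1, align_centroids: bool = True
) -> FluctuationResult:
    """Compute every fluctuation statistic for one segmented nucleus."""
    areas = track.areas
    times = track.times
    trend, resid = detrend_area_series(areas, times)
    pct, amp_sd, amp_var = fluctuation_amplitude(areas, times)
    mu, sigma, s_pct = circularity_fluctuation(track.props["circularity"].to_numpy())
    edge = edge_fluctuations(track.masks, lag=lag, align_centroids=align_centroids)
    return FluctuationResult(
        times=times,
        areas=areas,
        trend=trend,
        pct_residuals=pct,
        amp_sd=amp_sd,
        amp_var=amp_var,
        circ_mean=mu,
        circ_sd=sigma,
        circ_fluct=s_pct,
        edge_fluct=edge,
        edge_fluct_mean=float(np.nanmean(edge)) if np.isfinite(edge).any() else float("nan"),
    )
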