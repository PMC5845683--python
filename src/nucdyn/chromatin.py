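"""Chromatin texture dynamics: the intensity correlation coefficient C.

For a registered single-nucleus movie, each frame is intensity-normalized
(divided by the summed in-nucleus intensity, removing photobleaching and
expression-level differences), a fixed window — 100 x 100 px centred on the
time-averaged nucleus centroid — is cropped from every frame, and each later
frame n is compared with frame 1 by the pixelwise Pearson correlation

    C_n = sum_ij (x1_ij - x1_ave)(xn_ij - xn_ave) / (N * sigma_1 * sigma_n),

with population SDs over the window's N pixels.  The reported coefficient
is the arithmetic mean of C_n over n = 2..end: 1 for a perfectly static
texture, ~0 for fully decorrelated chromatin.  Negative per-frame values
are mathematically possible and are reported as computed, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MovieStack
from .segmentation import NucleusTrack

__all__ = [
    "IntensityCorrelationResult",
    "normalize_intensity",
    "crop_window",
    "window_for_track",
    "intensity_correlation",
    "chromatin_correlation",
]


@dataclass
class IntensityCorrelationResult:
    """Per-frame and averaged intensity correlation against frame 1."""

    per_frame_c: np.ndarray  # index n-1 holds C of frame n (frame numbering from 0)
    c_mean: float
    window: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    skipped: np.ndarray  # bool per later frame: zero-variance frames excluded


def normalize_intensity(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide a frame by its summed in-mask intensity.

    After normalization the in-mask sum is exactly 1 (to float precision),
    making the texture comparison invariant to global intensity scale.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    total = float(frame[mask].sum())
    if total <= 0:
        raise ValueError("non-positive in-mask intensity total")
    return frame / total


def crop_window(
    frame: np.ndarray, center: tuple[float, float], size: int = 100
) -> np.ndarray:
    """Crop a ``size x size`` window centred at ``center = (x, y)`` px.

    The window is clamped flush to the image bounds if the centre lies too
    close to an edge; a frame smaller than the window is an error.
    """
    r0, r1, c0, c1 = window_bounds(frame.shape, center, size)
    return np.asarray(frame)[r0:r1, c0:c1]


def window_bounds(
    shape: tuple[int, int], center: tuple[float, float], size: int = 100
) -> tuple[int, int, int, int]:
    """Half-open (row0, row1, col0, col1) of the clamped crop window."""
    H, W = shape[-2], shape[-1]
    if H < size or W < size:
        raise ValueError(f"frame {H}x{W} smaller than the {size}x{size} crop window")
    cx, cy = center
    r0 = int(round(cy - size / 2))
    c0 = int(round(cx - size / 2))
    r0 = min(max(r0, 0), H - size)
    c0 = min(max(c0, 0), W - size)
    return r0, r0 + size, c0, c0 + size


def window_for_track(track: NucleusTrack, size: int = 100) -> tuple[int, int, int, int]:
    """Crop window centred on the time-averaged nucleus centroid (in px)."""
    c = track.centroids_um.mean(axis=0) / track.pixel_size
    H, W = track.masks.shape[1:]
    return window_bounds((H, W), (c[0], c[1]), size)


def intensity_correlation(series: np.ndarray) -> IntensityCorrelationResult:
    """Pearson correlation of each later frame's pixels against frame 1.

    ``series`` is a ``T x h x w`` stack of normalized, cropped, registered
    frames.  Frames with zero pixel variance are skipped (flagged) and the
    mean is taken over the remaining ones.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 3 or series.shape[0] < 2:
        raise ValueError("need a T x h x w series with T >= 2")
    first = series[0].ravel()
    s1 = first.std()
    if s1 == 0:
        raise ValueError("frame 1 has zero pixel variance")
    n_later = series.shape[0] - 1
    cs = np.full(n_later, np.nan)
    skipped = np.zeros(n_later, dtype=bool)
    f1 = first - first.mean()
    for i in range(n_later):
        x = series[i + 1].ravel()
        sn = x.std()
        if sn == 0:
            skipped[i] = True
            continue
        cs[i] = float(np.dot(f1, x - x.mean()) / (x.size * s1 * sn))
    used = cs[~skipped]
    c_mean = float(used.mean()) if used.size else float("nan")
    return IntensityCorrelationResult(cs, c_mean, (0, series.shape[1], 0, series.shape[2]), skipped)


def chromatin_correlation(
    movie: MovieStack,
    track: NucleusTrack,
    size: int = 100,
    window: tuple[int, int, int, int] | None = None,
) -> IntensityCorrelationResult:
    """End-to-end coefficient C for one registered single-nucleus movie.

    Normalizes each frame by its in-nucleus total, crops the shared window
    (automatic: centred on the time-mean centroid; or caller-supplied for
    manual parity), and correlates each later frame against frame 1.
    """
    if window is None:
        window = window_for_track(track, size)
    r0, r1, c0, c1 = window
    crops = np.empty((movie.n_frames, r1 - r0, c1 - c0))
    for t in range(movie.n_frames):
        norm = normalize_intensity(movie.frames[t], track.masks[t])
        crops[t] = norm[r0:r1, c0:c1]
    result = intensity_correlation(crops)
    return IntensityCorrelationResult(result.per_frame_c, result.c_mean, window, result.skipped)
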