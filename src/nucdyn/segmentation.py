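"""Single-nucleus segmentation and per-frame shape descriptors.

Each fluorescence frame is reduced to one hole-free binary mask (largest
connected component above a global threshold) and a row of shape
properties.  Circularity follows the best-fit-ellipse definition

    R = 4 * area / (pi * major_axis^2),

which equals 1 for a circle and b/a for an ellipse with semi-axes a >= b.
Note this is *not* the perimeter-based 4*pi*A/P^2 circularity; the two
disagree for non-elliptical shapes and the ellipse form is the one used
throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .io import MovieStack

__all__ = ["SegmentationError", "NucleusTrack", "threshold_nucleus", "frame_properties", "segment_movie"]


class SegmentationError(RuntimeError):
    """Raised when a frame contains no segmentable nucleus."""


@dataclass
class NucleusTrack:
    """Per-frame masks and shape properties of one tracked nucleus.

    ``props`` columns: ``frame``, ``time_s``, ``area_um2``, ``cx_um``,
    ``cy_um``, ``circularity``, ``solidity``, ``major_axis_um``.
    """

    masks: np.ndarray  # T x H x W bool
    props: pd.DataFrame
    pixel_size: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @property
    def areas(self) -> np.ndarray:
        return self.props["area_um2"].to_numpy()

    @property
    def times(self) -> np.ndarray:
        return self.props["time_s"].to_numpy()

    @property
    def centroids_um(self) -> np.ndarray:
        return self.props[["cx_um", "cy_um"]].to_numpy()


def threshold_nucleus(
    frame: np.ndarray,
    threshold: float | None = None,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Segment the single bright nucleus in one frame.

    A light Gaussian blur (``smooth_sigma`` px) is followed by a global Otsu
    threshold — or a caller-supplied fixed ``threshold`` — after which the
    largest connected component is kept and interior holes are filled.

    Raises
    ------
    SegmentationError
        If no pixel exceeds the threshold or the frame has no contrast.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    smoothed = ndimage.gaussian_filter(frame, smooth_sigma) if smooth_sigma > 0 else frame
    if threshold is None:
        if np.ptp(smoothed) == 0:
            raise SegmentationError("segmentation failed: frame has no contrast")
        threshold = filters.threshold_otsu(smoothed)
    fg = smoothed > threshold
    if not fg.any():
        raise SegmentationError("segmentation failed: no pixels above threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    mask = ndimage.binary_fill_holes(fg)
    # Otsu on a frame that is mostly background can latch onto noise; treat a
    # tiny foreground as a failure rather than returning a speck
    if mask.sum() < 9:
        raise SegmentationError("segmentation failed: foreground below 9 px")
    return mask


def frame_properties(mask: np.ndarray, pixel_size: float) -> dict[str, float]:
    """Shape descriptors of a single-nucleus mask.

    Returns area (um^2), centroid (x, y in um), best-fit-ellipse major axis
    (um), circularity ``R = 4*area/(pi*major_axis^2)`` and solidity
    (area / convex hull area).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if not (pixel_size > 0):
        raise ValueError("pixel_size must be > 0")
    region = max(measure.regionprops(mask.astype(np.uint8)), key=lambda r: r.area)
    area_px = float(region.area)
    major_px = float(region.axis_major_length)
    cy, cx = region.centroid  # row, col
    circularity = 4.0 * area_px / (np.pi * major_px**2) if major_px > 0 else np.nan
    return {
        "area_um2": area_px * pixel_size**2,
        "cx_um": cx * pixel_size,
        "cy_um": cy * pixel_size,
        "major_axis_um": major_px * pixel_size,
        "circularity": circularity,
        "solidity": float(region.solidity),
    }


def segment_movie(
    movie: MovieStack,
    threshold: float | None = None,
    smooth_sigma: float = 1.0,
) -> NucleusTrack:
    """Segment every frame of a single-nucleus movie.

    Raises :class:`SegmentationError` naming the first failing frame; the
    pipeline layer catches this to exclude (and count) unanalyzable cells.
    """
    masks = np.zeros(movie.shape, dtype=bool)
    rows = []
    for t in range(movie.n_frames):
        try:
            mask = threshold_nucleus(movie.frames[t], threshold=threshold, smooth_sigma=smooth_sigma)
        except SegmentationError as err:
            raise SegmentationError(f"frame {t}: {err}") from err
        masks[t] = mask
        row = frame_properties(mask, movie.pixel_size)
        row["frame"] = t
        row["time_s"] = t * movie.frame_interval
        rows.append(row)
    props = pd.DataFrame(rows)[
        ["frame", "time_s", "area_um2", "cx_um", "cy_um", "circularity", "solidity", "major_axis_um"]
    ]
    return NucleusTrack(masks, props, movie.pixel_size, movie.frame_interval)
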