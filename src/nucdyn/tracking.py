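"""Cell migration measurement.

Two complementary measurements, matching the two imaging modalities:

* **Nucleus-centroid trajectories** — the segmented nucleus centroid of
  consecutive frames joined by straight lines; total polyline length in um,
  optionally corrected for stage/field drift using offsets registered from a
  paired bright-field movie.
* **Time-projection streaks** — an aligned bright-field movie is
  min-intensity-projected over time; migrating cells (dark outlines) leave
  dark streaks whose skeleton path length measures the migration distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import filters, morphology

from .io import MovieStack
from .segmentation import NucleusTrack
from .simulate import polyline_length

__all__ = [
    "Trajectory",
    "TimeProjection",
    "centroid_trajectory",
    "min_intensity_projection",
    "measure_streaks",
    "normalize_trajectories",
]


@dataclass
class Trajectory:
    """A centroid polyline (um) and its total path length."""

    points: np.ndarray  # (T, 2) of (x, y) um
    drift_corrected: bool
    length: float  # um


@dataclass
class TimeProjection:
    """Per-pixel minimum over time plus measured streak lengths."""

    image: np.ndarray
    pixel_size: float
    streaks: list[float]  # um


def centroid_trajectory(
    track: NucleusTrack, stage_offsets: np.ndarray | None = None
) -> Trajectory:
    """Nucleus-centroid polyline with optional frame-wise drift correction.

    ``stage_offsets`` are per-frame (dx, dy) *pixel* displacements of the
    field (e.g. from registering a paired bright-field movie); they are
    subtracted before the length is computed.  Without offsets the
    trajectory is reported uncorrected and flagged as such — it then also
    contains any field drift.
    """
    pts = track.centroids_um.copy()
    corrected = False
    if stage_offsets is not None:
        offsets = np.asarray(stage_offsets, dtype=float)
        if offsets.shape != (len(pts), 2):
            raise ValueError(
                f"stage_offsets must be ({len(pts)}, 2), got {offsets.shape}"
            )
        pts = pts - offsets * track.pixel_size
        corrected = True
    return Trajectory(points=pts, drift_corrected=corrected, length=polyline_length(pts))


def min_intensity_projection(stack: MovieStack) -> TimeProjection:
    """Per-pixel minimum over time of an (already aligned) movie."""
    if stack.n_frames < 2:
        raise ValueError("projection needs at least 2 frames")
    return TimeProjection(
        image=np.min(stack.frames, axis=0), pixel_size=stack.pixel_size, streaks=[]
    )


def _skeleton_geodesic_um(skel: np.ndarray, pixel_size: float) -> tuple[float, int]:
    """Longest geodesic path length along a skeleton, and its endpoint count.

    The skeleton pixels form a graph with 8-neighbour edges weighted 1 or
    sqrt(2); the streak length is the graph diameter found by a double
    Dijkstra sweep (exact on trees, which simple streak skeletons are).
    """
    coords = np.argwhere(skel)
    n = len(coords)
    if n == 0:
        return 0.0, 0
    if n == 1:
        return 0.0, 1
    index = -np.ones(skel.shape, dtype=int)
    index[tuple(coords.T)] = np.arange(n)
    rows, cols, w = [], [], []
    neighbor_count = np.zeros(n, dtype=int)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        shifted = np.full(skel.shape, -1, dtype=int)
        r0, r1 = max(dr, 0), skel.shape[0] + min(dr, 0)
        c0, c1 = max(dc, 0), skel.shape[1] + min(dc, 0)
        shifted[r0:r1, c0:c1] = index[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        here = index[tuple(coords.T)]
        there = shifted[tuple(coords.T)]
        ok = there >= 0
        a, b = here[ok], there[ok]
        dist = np.hypot(dr, dc)
        rows.extend([a, b])
        cols.extend([b, a])
        w.extend([np.full(len(a), dist)] * 2)
        np.add.at(neighbor_count, a, 1)
        np.add.at(neighbor_count, b, 1)
    if not rows:
        return 0.0, n
    graph = coo_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    d0 = dijkstra(graph, indices=0)
    far = int(np.nanargmax(np.where(np.isinf(d0), np.nan, d0)))
    d1 = dijkstra(graph, indices=far)
    finite = d1[np.isfinite(d1)]
    length_px = float(finite.max()) if finite.size else 0.0
    n_endpoints = int((neighbor_count == 1).sum())
    return length_px * pixel_size, n_endpoints


def measure_streaks(
    projection: TimeProjection,
    min_length: float = 15.0,
    threshold: float | None = None,
    max_endpoints: int = 4,
) -> list[float]:
    """Measure dark migration streaks in a min-intensity time projection.

    Dark regions (below a global Otsu threshold, or a supplied fixed one)
    are hole-filled and skeletonized; each region's streak length is the
    longest geodesic path along its skeleton.  Regions shorter than
    ``min_length`` um are discarded — the automated counterpart of excluding
    traces shorter than a cell's characteristic length — and heavily
    branched skeletons (more than ``max_endpoints`` endpoints, i.e. crossing
    or tangled streaks a human tracer would reject) are excluded as
    unmeasurable.  Returns streak lengths in um and stores them on
    ``projection.streaks``.
    """
    img = np.asarray(projection.image, dtype=float)
    if np.ptp(img) == 0:
        projection.streaks = []
        return []
    thr = filters.threshold_otsu(img) if threshold is None else threshold
    dark = img < thr
    if not dark.any():
        projection.streaks = []
        return []
    dark = ndimage.binary_fill_holes(dark)
    labels, n = ndimage.label(dark)
    lengths: list[float] = []
    for lbl in range(1, n + 1):
        region = labels == lbl
        skel = morphology.skeletonize(region)
        length_um, n_end = _skeleton_geodesic_um(skel, projection.pixel_size)
        if n_end > max_endpoints:
            continue
        if length_um >= min_length:
            lengths.append(length_um)
    projection.streaks = lengths
    return lengths


def normalize_trajectories(
    lengths: pd.DataFrame,
    baseline: str,
    group_col: str = "condition",
    value_col: str = "length_um",
) -> pd.DataFrame:
    """Normalize per-group mean trajectory lengths to a baseline group's mean.

    Matches the convention of reporting each arm's later timepoints relative
    to that arm's 1 h mean.  Returns a table with group, n, mean, SE and the
    normalized mean.
    """
    if baseline not in set(lengths[group_col]):
        raise ValueError(f"baseline group {baseline!r} not present")
    grouped = lengths.groupby(group_col)[value_col]
    summary = grouped.agg(n="count", mean_um="mean", sd="std").reset_index()
    summary["se_um"] = summary["sd"] / np.sqrt(summary["n"])
    base = float(summary.loc[summary[group_col] == baseline, "mean_um"].iloc[0])
    if not base > 0:
        raise ValueError("baseline group mean must be > 0")
    summary["normalized_mean"] = summary["mean_um"] / base
    return summary.drop(columns="sd")
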