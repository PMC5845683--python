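"""Image containers and tabular output.

Conventions used throughout the package: pixel indices are 0-based with
``x`` = column and ``y`` = row, origin at the top-left; physical
coordinates are ``index * pixel_size`` in micrometres.  Movies are stored
time-first (``T x H x W``), z-stacks plane-first (``Z x H x W``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MovieStack",
    "ZStack",
    "read_movie",
    "write_movie",
    "read_zstack",
    "write_zstack",
    "write_results",
]

#: float formatting used for every CSV the package writes (reproducible diffs)
CSV_FLOAT_FORMAT = "%.6g"


@dataclass
class MovieStack:
    """A time-ordered grayscale image stack with physical calibration.

    Parameters
    ----------
    frames
        ``T x H x W`` array of non-negative intensities.
    pixel_size
        Lateral calibration in micrometres per pixel.
    frame_interval
        Time between consecutive frames in seconds.
    channel_label
        Free-text channel description (e.g. ``"H2B-GFP"``).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ZStack:
    """A single-channel confocal z-stack (``Z x H x W``)."""

    planes: np.ndarray
    z_step: float
    pixel_size: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError("planes must be a Z x H x W array with Z >= 1")
        if not (self.z_step > 0):
            raise ValueError("z_step must be > 0 (default acquisition uses 0.8 um)")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        return self.pixel_size**2 * self.z_step


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: MovieStack, path: str | Path, extra: Mapping | None = None) -> Path:
    """Write a movie as a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.frames)
    meta = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "channel_label": movie.channel_label,
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_movie(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> MovieStack:
    """Read a multi-page TIFF movie.

    Calibration is taken from the JSON sidecar written by :func:`write_movie`;
    explicit ``pixel_size`` / ``frame_interval`` arguments override it.  If no
    sidecar exists both arguments are required.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise ValueError(
                f"{path}: TIFF pages have non-uniform shapes {sorted(shapes)}"
            )
        frames = tif.asarray()
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: TIFF pages do not form a uniform T x H x W stack "
            f"(got array of shape {frames.shape})"
        )
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise ValueError(
            f"{path}: no metadata sidecar found; supply pixel_size and "
            "frame_interval explicitly"
        )
    return MovieStack(frames, float(px), float(dt), meta.get("channel_label", ""))


def write_zstack(stack: ZStack, path: str | Path, extra: Mapping | None = None) -> Path:
    """Write one channel of a z-stack as a multi-page TIFF (page order = z)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.planes)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "z_step_um": stack.z_step,
        "channel_label": stack.channel_label,
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_zstack(
    path: str | Path,
    pixel_size: float | None = None,
    z_step: float | None = None,
) -> ZStack:
    path = Path(path)
    planes = np.asarray(tifffile.imread(path))
    if planes.ndim == 2:
        planes = planes[None]
    if planes.ndim != 3:
        raise ValueError(f"{path}: TIFF pages do not form a uniform Z x H x W stack")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dz = z_step if z_step is not None else meta.get("z_step_um")
    if px is None or dz is None:
        raise ValueError(f"{path}: missing calibration; supply pixel_size and z_step")
    return ZStack(planes, float(dz), float(px), meta.get("channel_label", ""))


def write_results(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    config: Mapping | None = None,
) -> dict[str, Path]:
    """Write named result tables as CSV files plus a JSON manifest.

    Each table becomes ``<name>.csv`` under ``path``.  Floats are written with
    6 significant digits and rows in their given order so re-running a
    deterministic pipeline reproduces byte-identical files.  The manifest
    records the run configuration and package version.
    """
    from . import __version__

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        dest = out / f"{name}.csv"
        table.to_csv(dest, index=False, float_format=CSV_FLOAT_FORMAT)
        written[name] = dest
    manifest = {
        "tables": sorted(tables),
        "software": "nucdyn",
        "version": __version__,
        "config": _jsonable(config) if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written["manifest"] = out / "manifest.json"
    return written


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
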