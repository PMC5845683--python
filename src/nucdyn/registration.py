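"""Translation-only stack alignment.

Frames are registered to a reference frame (the first, by default) by
integer-pixel translation maximising the cross-correlation.  Translation
is deliberately the only model: the downstream metrics (intensity
correlation, minimum-intensity projection) need drift removal, and
avoiding rotation/scaling and sub-pixel interpolation keeps both the
texture statistics and area/shape measurements unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .io import MovieStack

__all__ = ["AlignmentResult", "align_stack"]


@dataclass
class AlignmentResult:
    """An aligned movie plus the per-frame offsets that were applied.

    ``offsets[t] = (dx, dy)`` is the integer pixel translation applied to
    frame ``t`` to bring it onto the reference frame; the reference frame's
    offset is ``(0, 0)``.  ``degenerate`` flags frames with no contrast
    (offset forced to zero).
    """

    aligned: MovieStack
    offsets: np.ndarray  # T x 2 int, (dx, dy)
    reference: int
    degenerate: np.ndarray  # T bool

    def offsets_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.offsets)),
             "dx_px": self.offsets[:, 0],
             "dy_px": self.offsets[:, 1]}
        )


def _background_level(frame: np.ndarray) -> float:
    """Background estimate used to fill pixels shifted in from out of frame."""
    border = np.concatenate([frame[0], frame[-1], frame[:, 0], frame[:, -1]])
    return float(np.median(border))


def align_stack(stack: MovieStack, reference: int = 0) -> AlignmentResult:
    """Align every frame of a movie to the reference frame by translation.

    Offsets are recovered with (integer-precision) phase cross-correlation.
    Constant frames cannot be registered; they are flagged and passed
    through unshifted.
    """
    if stack.n_frames < 2:
        raise ValueError("alignment needs at least 2 frames")
    if not 0 <= reference < stack.n_frames:
        raise ValueError("reference frame out of range")
    ref = np.asarray(stack.frames[reference], dtype=float)
    ref_flat = np.ptp(ref) == 0

    T = stack.n_frames
    offsets = np.zeros((T, 2), dtype=int)
    degenerate = np.zeros(T, dtype=bool)
    aligned = np.empty_like(stack.frames, dtype=float)
    for t in range(T):
        frame = np.asarray(stack.frames[t], dtype=float)
        if t == reference:
            aligned[t] = frame
            continue
        if ref_flat or np.ptp(frame) == 0:
            degenerate[t] = True
            aligned[t] = frame
            continue
        # classic (amplitude-weighted) cross-correlation: phase whitening
        # over-weights high-frequency noise on smooth microscopy frames
        shift, _err, _phase = phase_cross_correlation(
            ref, frame, upsample_factor=1, normalization=None
        )
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        offsets[t] = (dx, dy)
        aligned[t] = ndimage.shift(
            frame, (dy, dx), order=0, mode="constant", cval=_background_level(frame)
        )
    out = MovieStack(
        aligned.astype(stack.frames.dtype, copy=False),
        stack.pixel_size,
        stack.frame_interval,
        stack.channel_label,
    )
    return AlignmentResult(out, offsets, reference, degenerate)
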