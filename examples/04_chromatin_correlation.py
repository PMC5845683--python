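"""Chromatin texture dynamics via the intensity correlation coefficient.

Renders two nuclei whose interior texture decorrelates at different rates,
registers each movie, and compares the coefficient C (pixelwise Pearson
correlation of each frame against frame 1, averaged).  Static chromatin
gives C near 1; fast turnover drives C toward 0.
"""

import dataclasses

import numpy as np

from nucdyn import align_stack, segment_movie
from nucdyn.chromatin import chromatin_correlation
from nucdyn.simulate import SyntheticConfig, generate_nucleus_movie

for turnover in (0.05, 0.8):
    cfg = SyntheticConfig(frames=24, image_size=(192, 192), drift_speed=0.2,
                          texture_turnover=turnover, seed=3)
    movie, _masks, _truth = generate_nucleus_movie(cfg)
    track = segment_movie(movie)
    aligned = align_stack(movie)
    shifted_masks = np.stack(
        [np.roll(track.masks[t], tuple(aligned.offsets[t, ::-1]), axis=(0, 1))
         for t in range(movie.n_frames)]
    )
    shifted = dataclasses.replace(track, masks=shifted_masks)
    res = chromatin_correlation(aligned.aligned, shifted, size=48)
    print(f"texture turnover {turnover:.2f}/frame  ->  C = {res.c_mean:.3f}")
# The 48 px window sits inside the nucleus so C reflects texture dynamics
# rather than the static nucleus-background contrast.
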