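"""Measure cell migration from bright-field time projections.

Simulates one bright-field field of view (4 cells, 100 frames at 36 s),
aligns the stack, takes the per-pixel minimum over time — migrating cells
leave dark streaks — and measures each streak's skeleton path length.
"""

import numpy as np

from nucdyn import align_stack, condition_preset, generate_brightfield_movie
from nucdyn.tracking import measure_streaks, min_intensity_projection

cfg = condition_preset("unstrained", "1h", modality="brightfield")
cfg.seed = 2
movie, truth = generate_brightfield_movie(cfg, 4)

aligned = align_stack(movie)
projection = min_intensity_projection(aligned.aligned)
lengths = measure_streaks(projection, min_length=15.0)

print("true path lengths (um):", np.round(sorted(truth["true_traj_len_um"])[::-1], 1))
print("measured streaks (um): ", np.round(sorted(lengths)[::-1], 1))
print(f"condition preset mean: {cfg.mean_path_um:.0f} um per hour of imaging")
# Each dark streak's skeleton length approximates the cell's migration
# path; streaks shorter than 15 um (sub-cell-scale wiggles) are excluded,
# mirroring manual tracing practice.
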