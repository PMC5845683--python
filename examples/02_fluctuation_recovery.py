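"""Measure nuclear area fluctuations from rendered movies.

Simulates a small population at the strained 24 h preset (2% amplitude),
segments every frame, detrends the area series with a cubic polynomial and
reports the percentage-residual SD per cell — the pipeline's central
readout of nuclear dynamics.
"""

from nucdyn import condition_preset, generate_population, segment_movie
from nucdyn.fluctuations import analyze_track

cfg = condition_preset("strained", "24h")
cfg.seed = 4
cells, params = generate_population(cfg, 6)

print("cell  true_amp%  measured_amp%  circ_mean  edge_fluct")
for i, (movie, _masks, truth) in enumerate(cells):
    track = segment_movie(movie)
    res = analyze_track(track)
    print(f"{i:4d}  {truth.true_amp_pct:9.2f}  {res.amp_sd:13.2f}"
          f"  {res.circ_mean:9.3f}  {res.edge_fluct_mean:10.3f}")
# measured_amp tracks true_amp per cell; the condition mean recovers the
# 2% preset (4 expressed as variance). circ_mean is the best-fit-ellipse
# circularity; edge_fluct is the lag-1 non-overlap ratio after removing
# whole-nucleus translation.
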