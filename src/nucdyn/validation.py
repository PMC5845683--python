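"""Parameter-recovery benchmarks: run the full measurement pipelines on
synthetic populations with known truth.

These functions are the package's self-validation layer: each one generates
data with the condition presets, pushes it through the *measurement* path
(segmentation, detrending, registration, projection, streak measurement,
statistics) and returns what was recovered, so recovery can be compared
with the generator truth.  They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate
from .cytoskeleton import channel_normalized_intensity, percent_difference
from .fluctuations import fluctuation_amplitude
from .registration import align_stack
from .segmentation import SegmentationError, segment_movie
from .simulate import condition_preset, cytoskeleton_preset, generate_population
from .stats import anova_bonferroni, filtered_pearson_fit
from .tracking import centroid_trajectory, measure_streaks, min_intensity_projection

__all__ = [
    "nucleus_population_metrics",
    "migration_streak_lengths",
    "coupled_amplitude_trajectory_r",
    "cytoskeleton_percent_difference",
    "two_group_type_i_error",
]

def nucleus_population_metrics(
    condition: str, n_cells: int, seed: int, frames: int | None = None
) -> pd.DataFrame:
    """Measured per-cell amplitude and trajectory length for one condition.

    Renders a heterogeneous population with the condition preset and runs
    segmentation -> cubic detrend -> percentage-residual SD, plus centroid
    tracking, on every movie.  Unsegmentable cells are dropped (counted in
    the ``failed`` attribute of the returned frame).
    """
    cfg = condition_preset(condition)
    if frames is not None:
        cfg.frames = frames
    cfg.seed = seed
    cells, _params = generate_population(cfg, n_cells)
    rows, failed = [], 0
    for i, (movie, _masks, truth) in enumerate(cells):
        try:
            track = segment_movie(movie)
        except SegmentationError:
            failed += 1
            continue
        _, amp_sd, amp_var = fluctuation_amplitude(track.areas, track.times)
        traj = centroid_trajectory(track)
        rows.append(
            {
                "condition": condition,
                "cell": i,
                "amp_sd_pct": amp_sd,
                "amp_var_pct2": amp_var,
                "traj_len_um": traj.length,
                "true_amp_pct": truth.true_amp_pct,
                "true_traj_len_um": truth.true_trajectory_len,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["failed"] = failed
    return out


def migration_streak_lengths(
    condition: str, n_cells: int, seed: int, cells_per_field: int = 4
) -> pd.DataFrame:
    """Streak lengths measured from bright-field movies for one condition.

    Cells are distributed over fields of ``cells_per_field``; each movie is
    aligned, min-intensity projected and measured with the default streak
    filter.
    """
    rows = []
    truth_lengths = []
    done, movie_idx = 0, 0
    while done < n_cells:
        n_here = min(cells_per_field, n_cells - done)
        cfg = condition_preset(condition, modality="brightfield")
        cfg.seed = simulate._child_seed(seed, movie_idx)
        movie, truth = simulate.generate_brightfield_movie(cfg, n_here)
        res = align_stack(movie)
        proj = min_intensity_projection(res.aligned)
        for length in measure_streaks(proj):
            rows.append({"condition": condition, "movie": movie_idx, "length_um": length})
        truth_lengths.extend(truth["true_traj_len_um"])
        done += n_here
        movie_idx += 1
    out = pd.DataFrame(rows)
    out.attrs["true_mean_um"] = float(np.mean(truth_lengths))
    return out


def coupled_amplitude_trajectory_r(
    n_cells: int = 87, seed: int = 0, frames: int | None = None
) -> dict:
    """Outlier-filtered Pearson r between measured amplitude and trajectory.

    The population is generated with the preset amplitude-motility coupling;
    per-cell amplitude and trajectory length are *measured* by the nucleus
    pipeline, the one-sided mean + 2 SD filter is applied on both axes, and
    Pearson r of the survivors is returned.
    """
    df = nucleus_population_metrics("unstrained_1h", n_cells, seed, frames=frames)
    fit = filtered_pearson_fit(df["amp_sd_pct"].to_numpy(), df["traj_len_um"].to_numpy())
    latent_r = float(
        np.corrcoef(np.log(df["true_amp_pct"]), np.log(df["true_traj_len_um"]))[0, 1]
    )
    return {
        "pearson_r": fit.pearson_r,
        "n_in": fit.n_in,
        "n_removed": fit.n_removed,
        "latent_r": latent_r,
    }


def cytoskeleton_percent_difference(
    channel: str, timepoint: str = "24h", n_per_condition: int = 20, seed: int = 0
) -> dict:
    """Percent difference of mean volume-normalized intensity, strained vs
    unstrained, measured end-to-end from synthetic z-stacks.

    Each condition's stacks are generated at the preset density (the
    density is a condition parameter; stacks differ in region geometry and
    noise), so the comparison isolates the measurement chain.
    """
    means = {}
    for ci, condition in enumerate(("unstrained", "strained")):
        dens = cytoskeleton_preset(condition, timepoint)
        values = []
        for i in range(n_per_condition):
            a, b, _ = simulate.generate_cytoskeleton_zstack(
                dens["actin"],
                dens["tubulin"],
                seed=simulate._child_seed(seed, 1000 * (ci + 1) + i),
            )
            stack = {"actin": a, "tubulin": b}[channel]
            values.append(channel_normalized_intensity(stack).normalized)
        means[condition] = float(np.mean(values))
    return {
        "percent_difference": percent_difference(means["unstrained"], means["strained"]),
        "mean_unstrained": means["unstrained"],
        "mean_strained": means["strained"],
        "n": n_per_condition,
    }


def two_group_type_i_error(
    n_replicates: int = 300, n_per_group: int = 12, seed: int = 0, alpha: float = 0.05
) -> dict:
    """False-positive rate of the group comparison on equal presets.

    Each replicate draws two independent populations from the *same*
    condition preset (per-cell true amplitudes, no rendering — the
    calibration concerns the statistical layer, not the imaging chain) and
    tests them with the implemented ANOVA/Bonferroni machinery at ``alpha``.
    """
    cfg = condition_preset("unstrained_1h")
    rejections = 0
    for rep in range(n_replicates):
        amps = []
        for g in range(2):
            c = simulate.SyntheticConfig(
                area_fluct_target=cfg.area_fluct_target,
                seed=simulate._child_seed(seed, 2 * rep + g),
            )
            amps.append(simulate.draw_population_params(c, n_per_group)["amp_pct"].to_numpy())
        res = anova_bonferroni({"a": amps[0], "b": amps[1]})
        if res.anova_p < alpha:
            rejections += 1
    return {
        "type_i_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "n_per_group": n_per_group,
        "alpha": alpha,
    }
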