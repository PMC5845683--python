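"""End-to-end orchestration: simulate -> segment -> register -> metrics -> stats.

A :class:`RunConfig` (constructible from YAML) describes one run: which
condition presets to simulate (or which directory of movies to load), how
many cells per condition, per-module options, the output directory and the
master seed.  Per-cell failures (segmentation loss) are excluded and
counted, mirroring manual exclusion of unanalyzable movies; a run with more
than half its cells failing is marked failed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin, cytoskeleton, fluctuations, registration, simulate, tracking
from .io import write_results
from .segmentation import SegmentationError, segment_movie
from .simulate import SyntheticConfig, condition_preset, cytoskeleton_preset
from .stats import anova_bonferroni, filtered_pearson_fit

__all__ = ["RunConfig", "run", "compare_conditions", "analyze_nucleus_population",
           "analyze_migration", "analyze_cytoskeleton"]

log = logging.getLogger("nucdyn")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every option has a default."""

    conditions: tuple[str, ...] = tuple(f"{c}_{t}" for c, t in simulate.CONDITIONS)
    cells_per_condition: int = 10
    brightfield_cells_per_condition: int = 0  # 0 disables the migration stage
    zstacks_per_condition: int = 0  # 0 disables the cytoskeleton stage
    seed: int = 0
    out_dir: str = "nucdyn_run"
    # quick-run overrides of the acquisition presets (None = preset default)
    frames: int | None = None
    image_size: tuple[int, int] | None = None
    # per-module options
    threshold: float | None = None  # fixed segmentation threshold (None = Otsu)
    edge_lag: int = 1
    edge_align_centroids: bool = True
    corr_window: int = 100
    min_streak_length: float = 15.0
    outlier_filter: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config option(s): {sorted(unknown)}")
        if "conditions" in data:
            data = {**data, "conditions": tuple(data["conditions"])}
        if "image_size" in data and data["image_size"] is not None:
            data = {**data, "image_size": tuple(data["image_size"])}
        return cls(**data)

    def effective(self) -> dict:
        return dataclasses.asdict(self)


def _apply_overrides(cfg: SyntheticConfig, run_cfg: RunConfig) -> SyntheticConfig:
    if run_cfg.frames is not None:
        cfg.frames = run_cfg.frames
    if run_cfg.image_size is not None:
        cfg.image_size = run_cfg.image_size
    return cfg


def analyze_nucleus_population(
    cells: list, run_cfg: RunConfig, condition: str
) -> tuple[pd.DataFrame, int]:
    """Per-cell fluctuation/trajectory/chromatin metrics for rendered cells.

    Returns the per-cell table and the number of excluded (unsegmentable)
    cells.
    """
    rows = []
    failures = 0
    for i, (movie, _truth_masks, truth) in enumerate(cells):
        try:
            track = segment_movie(movie, threshold=run_cfg.threshold)
        except SegmentationError as err:
            failures += 1
            log.warning("condition %s cell %d excluded: %s", condition, i, err)
            continue
        fl = fluctuations.analyze_track(
            track, lag=run_cfg.edge_lag, align_centroids=run_cfg.edge_align_centroids
        )
        traj = tracking.centroid_trajectory(track)
        aligned = registration.align_stack(movie)
        # reuse the segmentation: translate masks and centroids by the
        # recovered offsets instead of re-segmenting the aligned frames
        shifted_masks = np.stack(
            [
                np.roll(track.masks[t], (aligned.offsets[t, 1], aligned.offsets[t, 0]), axis=(0, 1))
                for t in range(track.n_frames)
            ]
        )
        shifted_props = track.props.copy()
        shifted_props["cx_um"] += aligned.offsets[:, 0] * movie.pixel_size
        shifted_props["cy_um"] += aligned.offsets[:, 1] * movie.pixel_size
        shifted_track = dataclasses.replace(track, masks=shifted_masks, props=shifted_props)
        corr = chromatin.chromatin_correlation(
            aligned.aligned, shifted_track, size=min(run_cfg.corr_window, movie.shape[1])
        )
        rows.append(
            {
                "condition": condition,
                "cell": i,
                "amp_sd_pct": fl.amp_sd,
                "amp_var_pct2": fl.amp_var,
                "circ_mean": fl.circ_mean,
                "circ_fluct_pct": fl.circ_fluct,
                "edge_fluct_mean": fl.edge_fluct_mean,
                "traj_len_um": traj.length,
                "traj_corrected": traj.drift_corrected,
                "c_mean": corr.c_mean,
                "true_amp_pct": truth.true_amp_pct,
                "true_traj_len_um": truth.true_trajectory_len,
            }
        )
    return pd.DataFrame(rows), failures


def analyze_migration(
    run_cfg: RunConfig, condition: str, n_cells: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and measure bright-field migration for one condition.

    Cells are spread over as many movies as needed (4 cells per field).
    Returns (per-streak table, per-cell truth table).
    """
    per_field = 4
    streak_rows, truth_frames = [], []
    done = 0
    movie_idx = 0
    while done < n_cells:
        n_here = min(per_field, n_cells - done)
        cfg = condition_preset(condition, modality="brightfield")
        cfg = _apply_overrides(cfg, run_cfg)
        cfg.seed = simulate._child_seed(seed, movie_idx)
        movie, truth = simulate.generate_brightfield_movie(cfg, n_here)
        aligned = registration.align_stack(movie)
        proj = tracking.min_intensity_projection(aligned.aligned)
        for length in tracking.measure_streaks(proj, min_length=run_cfg.min_streak_length):
            streak_rows.append(
                {"condition": condition, "movie": movie_idx, "length_um": length}
            )
        truth_frames.append(truth.assign(movie=movie_idx))
        done += n_here
        movie_idx += 1
    return pd.DataFrame(streak_rows), pd.concat(truth_frames, ignore_index=True)


def analyze_cytoskeleton(run_cfg: RunConfig, condition: str, n: int, seed: int) -> pd.DataFrame:
    """Simulate and measure two-channel z-stacks for one condition."""
    dens = cytoskeleton_preset(condition)
    rows = []
    rng = np.random.default_rng(seed)
    for i in range(n):
        # per-cell lognormal variability around the condition density means
        cv = 0.15
        sig = np.sqrt(np.log(1 + cv**2))
        fa = dens["actin"] * np.exp(sig * rng.standard_normal() - sig**2 / 2)
        ft = dens["tubulin"] * np.exp(sig * rng.standard_normal() - sig**2 / 2)
        stack_a, stack_b, _truth = simulate.generate_cytoskeleton_zstack(
            fa, ft, seed=simulate._child_seed(seed, i)
        )
        for stack in (stack_a, stack_b):
            res = cytoskeleton.channel_normalized_intensity(stack)
            rows.append(
                {
                    "condition": condition,
                    "cell": i,
                    "channel": stack.channel_label,
                    "total_intensity": res.total_intensity,
                    "volume_um3": res.volume,
                    "normalized": res.normalized,
                }
            )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute a full synthetic run and write per-cell CSVs plus a manifest.

    Returns a summary dict with the output paths, per-condition tables and
    the failure counts.  Raises ``RuntimeError`` if more than 50% of cells
    fail segmentation.
    """
    out = Path(config.out_dir)
    tables: dict[str, pd.DataFrame] = {}
    nucleus_frames = []
    total, failed = 0, 0
    for ci, condition in enumerate(config.conditions):
        preset = condition_preset(condition)
        preset = _apply_overrides(preset, config)
        preset.seed = simulate._child_seed(config.seed, ci)
        cells, _params = simulate.generate_population(preset, config.cells_per_condition)
        df, failures = analyze_nucleus_population(cells, config, condition)
        nucleus_frames.append(df)
        total += config.cells_per_condition
        failed += failures
    per_cell = pd.concat(nucleus_frames, ignore_index=True)
    tables["nucleus_per_cell"] = per_cell

    if config.brightfield_cells_per_condition > 0:
        streaks, truths = [], []
        for ci, condition in enumerate(config.conditions):
            s, t = analyze_migration(
                config, condition, config.brightfield_cells_per_condition,
                seed=simulate._child_seed(config.seed, 1000 + ci),
            )
            streaks.append(s)
            truths.append(t)
        tables["migration_streaks"] = pd.concat(streaks, ignore_index=True)
        tables["migration_truth"] = pd.concat(truths, ignore_index=True)

    if config.zstacks_per_condition > 0:
        cyto = [
            analyze_cytoskeleton(
                config, condition, config.zstacks_per_condition,
                seed=simulate._child_seed(config.seed, 2000 + ci),
            )
            for ci, condition in enumerate(config.conditions)
            if tuple(condition.rsplit("_", 1)) in simulate.CYTOSKELETON_DENSITY
        ]
        if cyto:
            tables["cytoskeleton_per_cell"] = pd.concat(cyto, ignore_index=True)

    if failed > 0.5 * total:
        raise RuntimeError(f"run failed: {failed}/{total} cells unsegmentable")

    summary = compare_conditions(per_cell)
    tables["condition_summary"] = summary["table"]
    paths = write_results(tables, out, config=config.effective())
    report = {
        "out_dir": str(out),
        "paths": {k: str(v) for k, v in paths.items()},
        "n_cells": total,
        "n_excluded": failed,
        "stats": summary["stats"],
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return {**report, "tables": tables}


def compare_conditions(per_cell: pd.DataFrame) -> dict:
    """Condition-level report: means +/- SE, ANOVA/Bonferroni on amplitude,
    per-arm normalized trajectory table, and the outlier-filtered
    amplitude-trajectory correlation."""
    if per_cell.empty:
        raise ValueError("no per-cell results to compare")
    grouped = per_cell.groupby("condition")
    table = grouped.agg(
        n=("amp_sd_pct", "count"),
        amp_sd_mean=("amp_sd_pct", "mean"),
        amp_sd_sem=("amp_sd_pct", "sem"),
        amp_var_mean=("amp_var_pct2", "mean"),
        traj_mean_um=("traj_len_um", "mean"),
        traj_sem_um=("traj_len_um", "sem"),
        c_mean=("c_mean", "mean"),
    ).reset_index()

    stats_out: dict = {}
    groups = {c: g["amp_sd_pct"].to_numpy() for c, g in grouped if len(g) >= 2}
    if len(groups) >= 2:
        cmp_res = anova_bonferroni(groups)
        stats_out["anova_F"] = cmp_res.anova_F
        stats_out["anova_p"] = cmp_res.anova_p
        stats_out["pairwise"] = {
            f"{a} vs {b}": v for (a, b), v in cmp_res.pairwise.items()
        }
    else:
        stats_out["note"] = "single condition: descriptive output only"

    # per-arm normalization to the 1 h baseline, where present
    norm_tables = []
    for arm in ("unstrained", "strained"):
        arm_df = per_cell[per_cell["condition"].str.startswith(arm)]
        baseline = f"{arm}_1h"
        if not arm_df.empty and baseline in set(arm_df["condition"]):
            norm_tables.append(
                tracking.normalize_trajectories(
                    arm_df, baseline, group_col="condition", value_col="traj_len_um"
                )
            )
    if norm_tables:
        norm = pd.concat(norm_tables, ignore_index=True)
        stats_out["normalized_trajectories"] = norm.to_dict(orient="records")

    if len(per_cell) >= 3:
        fit = filtered_pearson_fit(
            per_cell["amp_sd_pct"].to_numpy(), per_cell["traj_len_um"].to_numpy()
        )
        stats_out["amp_traj_correlation"] = {
            "pearson_r": fit.pearson_r,
            "n_in": fit.n_in,
            "n_removed": fit.n_removed,
            "valid": fit.valid,
        }
    return {"table": table, "stats": stats_out}
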