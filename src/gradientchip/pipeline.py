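"""End-to-end orchestration: simulate → synth → segment → track → profile →
analyze, with per-stage outputs on disk and a reproducibility manifest.

Each chamber is processed as an independent unit; multi-chamber experiments
are pooled only at the analysis stage, on per-cell mean exposure.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .cytometry import GradientProfile, measure, quantify_gradient, register_translation, segment, track
from .device import build_chamber_mask
from .dose import (
    HillThresholdModel,
    mean_exposure,
    monotonic_trend,
    morphology_delta,
    pool_and_bin,
)
from .errors import DegenerateDesignError, GradientChipError, InsufficientDataError, PipelineError
from .gradient import simulate_gradient, steady_state
from .io import RunManifest, config_hash
from .plotting import boxplot_binned, gradient_profile_figure
from .synth import footprint_mask_px, generate_dataset

log = logging.getLogger("gradientchip")


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def run_pipeline(config: PipelineConfig, outdir=None) -> RunManifest:
    """Execute the full pipeline described by ``config``.

    Returns the :class:`RunManifest`; stage outputs (TIFF stacks and CSV
    tables) land under ``outdir``.  Two runs with the same config and seed
    produce identical tables.  Any stage failure raises
    :class:`PipelineError` carrying the stage name; outputs of completed
    stages are preserved.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = RunManifest(
        config_hash=config_hash(config.to_dict()),
        seed=config.seed,
        software_version=__version__,
        started=_now(),
    )
    stage = "simulate-gradient"
    try:
        chamber = build_chamber_mask(config.geometry)
        times_min = np.asarray(config.imaging.time_points_min, float)
        if config.synth.mode == "gradient":
            if config.synth.gradient_time_offset_s is None:
                field = steady_state(config.geometry, config.fluid, config.perfusion, chamber=chamber)
            else:
                field = simulate_gradient(
                    config.geometry,
                    config.fluid,
                    config.perfusion,
                    config.synth.gradient_time_offset_s + times_min * 60.0,
                    chamber=chamber,
                )
            field.to_tiff(outdir / "field.tif")
            field.to_dataframe().to_csv(outdir / "field.csv", index=False)
            manifest.add_stage(stage, {"field_tif": outdir / "field.tif", "field_csv": outdir / "field.csv"})
        else:
            field = None
            manifest.add_stage(stage, {"skipped": "well mode"})
        log.info("stage %s done", stage)

        stage = "synth"
        dataset = generate_dataset(
            config.geometry,
            config.fluid,
            config.perfusion,
            config.dose_response,
            config.imaging,
            mode=config.synth.mode,
            n_cells=config.synth.n_cells,
            c_uniform_ug_ml=config.synth.c_uniform_ug_ml,
            sigma_step_um_per_15min=config.synth.sigma_step_um_per_15min,
            drift_px_per_frame=tuple(config.synth.drift_px_per_frame),
            gradient_time_offset_s=config.synth.gradient_time_offset_s,
            seed=config.seed,
            field=field,
            chamber=chamber,
        )
        manifest.add_stage(stage, dataset.save(outdir))
        log.info("stage %s done", stage)

        stage = "segment"
        green = dataset.green.astype(float)
        red = dataset.red.astype(float)
        shifts = [(0, 0)]
        for i in range(1, green.shape[0]):
            (dx, dy), reg = register_translation(green[0], green[i])
            green[i] = reg
            if dx or dy:
                from scipy import ndimage as _ndi

                red[i] = _ndi.shift(red[i], (-dy, -dx), order=0, mode="nearest")
            shifts.append((dx, dy))
        seg = config.segmentation
        frames = []
        for i in range(green.shape[0]):
            labels = segment(
                green[i],
                smoothing_sigma=seg.smoothing_sigma,
                min_area_px=seg.min_area_px,
                split_touching=seg.split_touching,
                min_distance_px=seg.min_distance_px,
            )
            m = measure(labels)
            m.insert(0, "frame", i)
            frames.append(m)
        measurements = pd.concat(frames, ignore_index=True)
        measurements.to_csv(outdir / "measurements.csv", index=False)
        manifest.add_stage(
            stage, {"measurements": outdir / "measurements.csv", "shifts": json.dumps(shifts)}
        )
        log.info("stage %s done (%d objects)", stage, len(measurements))

        stage = "track"
        per_frame = [measurements[measurements["frame"] == i].reset_index(drop=True) for i in range(green.shape[0])]
        tracks = track(per_frame, max_displacement_px=config.tracking.max_displacement_px)
        tracks["time_min"] = times_min[tracks["frame"].to_numpy()]
        tracks["x_um"] = config.imaging.px_to_um(tracks["x_px"].to_numpy())
        tracks["y_um"] = config.imaging.px_to_um(tracks["y_px"].to_numpy())
        tracks.to_csv(outdir / "tracks.csv", index=False)
        manifest.add_stage(stage, {"tracks": outdir / "tracks.csv"})
        log.info("stage %s done (%d tracks)", stage, tracks["track_id"].nunique())

        stage = "gradient-profile"
        c0 = config.perfusion.source_concentration_ug_ml
        profiles: dict[float, GradientProfile] = {}
        if config.synth.mode == "gradient":
            mask_px = footprint_mask_px(chamber, config.imaging)
            prof_rows = []
            for i, t in enumerate(times_min):
                if config.analysis.use_ground_truth_exposure and field is not None:
                    ti = min(i, field.conc.shape[0] - 1)
                    x_um, vals = field.central_profile(ti)
                    prof = GradientProfile(x_um.copy(), vals / c0 * 100.0 if c0 > 0 else vals)
                else:
                    prof = quantify_gradient(
                        red[i],
                        mask_px,
                        config.imaging.pixel_size_um,
                        origin_offset_px=config.imaging.pad_px,
                        ref_fraction=config.profile.ref_fraction,
                        median_size=config.profile.median_size,
                        noise_floor=config.profile.noise_floor,
                        edge_trim_px=config.profile.edge_trim_px,
                    )
                profiles[float(t)] = prof
                prof_rows.append(
                    pd.DataFrame(
                        {
                            "bin_center_um": prof.positions_um,
                            "time_min": float(t),
                            "intensity_pct": prof.intensity_pct,
                        }
                    )
                )
            pd.concat(prof_rows, ignore_index=True).to_csv(outdir / "profile.csv", index=False)
            gradient_profile_figure(profiles, outdir / "profile.png")
            manifest.add_stage(stage, {"profile": outdir / "profile.csv", "figure": outdir / "profile.png"})
        else:
            manifest.add_stage(stage, {"skipped": "well mode"})
        log.info("stage %s done", stage)

        stage = "analyze"
        t0 = config.analysis.t0_min
        eval_times = (
            [float(t) for t in config.analysis.times_min]
            if config.analysis.times_min is not None
            else [float(t) for t in times_min if t > t0]
        )
        usable = tracks if config.analysis.include_truncated else tracks[tracks["status"] == "complete"]
        pooled_rows = []
        for tid, tr in usable.groupby("track_id"):
            tr = tr.sort_values("time_min")
            base = tr[tr["time_min"] == t0]
            if base.empty:
                continue
            for t in eval_times:
                at_t = tr[tr["time_min"] == t]
                if at_t.empty:
                    continue
                try:
                    if config.synth.mode == "well":
                        mean_c = float(config.synth.c_uniform_ug_ml or 0.0)
                    else:
                        mean_c = mean_exposure(tr, profiles, c0, t0, t).mean_concentration_ug_ml
                    delta = morphology_delta(
                        base.iloc[0], at_t.iloc[0], eccentricity_mode=config.analysis.eccentricity_mode
                    )
                except (InsufficientDataError, GradientChipError):
                    continue
                pooled_rows.append(
                    {
                        "track_id": tid,
                        "time_min": t,
                        "mean_concentration_ug_ml": mean_c,
                        "delta_area": delta.delta_area,
                        "delta_eccentricity": delta.delta_eccentricity,
                    }
                )
        pooled = pd.DataFrame(
            pooled_rows,
            columns=["track_id", "time_min", "mean_concentration_ug_ml", "delta_area", "delta_eccentricity"],
        )
        pooled.to_csv(outdir / "exposures_deltas.csv", index=False)

        outputs = {"exposures_deltas": outdir / "exposures_deltas.csv"}
        if len(pooled):
            edges = np.linspace(0.0, c0 if c0 > 0 else 1.0, config.analysis.n_bins + 1)
            binned = pool_and_bin(pooled, edges, eval_times)
            binned.to_csv(outdir / "binned.csv", index=False)
            trend = pd.concat(
                [monotonic_trend(pooled, m) for m in ("delta_area", "delta_eccentricity")],
                ignore_index=True,
            )
            trend.to_csv(outdir / "trend.csv", index=False)
            boxplot_binned(binned, "delta_area", outdir / "boxplot_area.png")
            boxplot_binned(binned, "delta_eccentricity", outdir / "boxplot_eccentricity.png")
            outputs.update(
                {
                    "binned": outdir / "binned.csv",
                    "trend": outdir / "trend.csv",
                    "boxplot_area": outdir / "boxplot_area.png",
                    "boxplot_eccentricity": outdir / "boxplot_eccentricity.png",
                }
            )
            last_t = eval_times[-1]
            at_last = pooled[pooled["time_min"] == last_t]
            try:
                model = HillThresholdModel.from_dataframe(at_last)
                results = model.fit(n_bootstrap=config.analysis.bootstrap_reps, seed=config.seed)
                fit_payload = results.to_dict()
                fit_payload["time_min"] = last_t
            except DegenerateDesignError as exc:
                fit_payload = {"flags": ["degenerate-design"], "detail": str(exc), "time_min": last_t}
            (outdir / "fit.json").write_text(json.dumps(fit_payload, indent=2))
            outputs["fit"] = outdir / "fit.json"
        manifest.add_stage(stage, outputs)
        log.info("stage %s done (%d pooled rows)", stage, len(pooled))
    except GradientChipError as exc:
        manifest.finished = _now()
        manifest.write(outdir / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc

    manifest.finished = _now()
    manifest.write(outdir / "manifest.json")
    return manifest
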