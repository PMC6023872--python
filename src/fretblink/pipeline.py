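"""Stage-based pipeline: simulate -> detect -> trace -> hmm -> metrics,
plus standalone lifetime, fret, track and report stages.

Every artifact gets a provenance sidecar (``<name>.provenance.json``)
recording the stage, config hash, seed and library versions; per-stage
molecule/trace/trajectory counts are logged.  A stage that fails removes
its partial outputs and raises :class:`PipelineError` naming the missing
input where applicable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, blink_hmm, io, lifetime_fit, movie_analysis
from . import report as report_mod
from . import synthetic_data, tracking
from .config import RunConfig

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger("fretblink")

STAGES = (
    "simulate",
    "detect",
    "trace",
    "hmm",
    "metrics",
    "lifetime",
    "fret",
    "track",
    "report",
)


class PipelineError(RuntimeError):
    pass


def _sidecar(path: Path, cfg: RunConfig, stage: str, counts: dict):
    meta = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "fretblink_version": __version__,
        "numpy_version": np.__version__,
        "counts": counts,
    }
    io.write_json(meta, path.with_suffix(path.suffix + ".provenance.json"))


def _need(ctx: dict, cfg: RunConfig, key: str, filename: str):
    """Fetch a stage input from the in-memory context, config paths, or
    the default artifact location."""
    if key in ctx:
        return ctx[key]
    path = Path(cfg.paths.get(key, Path(cfg.out_dir) / filename))
    if not path.exists():
        raise PipelineError(f"stage input '{key}' missing (looked for {path})")
    return path


def _stage_simulate(cfg: RunConfig, ctx: dict, out: Path):
    opts = dict(cfg.simulate)
    params = synthetic_data.PhotophysicsParams(
        exposure=cfg.exposure, **opts.pop("params", {})
    )
    noise = synthetic_data.CameraNoiseParams(**opts.pop("noise", {}))
    stack, truth = synthetic_data.simulate_movie(
        params=params, noise=noise, seed=cfg.seed, **opts
    )
    stack_path = out / "movie.tif"
    io.write_stack(stack_path, stack)
    io.write_json(truth.to_jsonable(), out / "ground_truth.json")
    ctx["stack"] = stack
    ctx["truth"] = truth
    counts = {"molecules": len(truth.molecules), "frames": int(stack.shape[0])}
    logger.info("simulate: %s", counts)
    _sidecar(stack_path, cfg, "simulate", counts)
    return [stack_path, out / "ground_truth.json"]


def _stage_detect(cfg: RunConfig, ctx: dict, out: Path):
    stack = _need(ctx, cfg, "stack", "movie.tif")
    if isinstance(stack, Path):
        stack = io.read_stack(stack)
        ctx["stack"] = stack
    params = movie_analysis.DetectionParams(**cfg.detect)
    proj = movie_analysis.max_projection(stack, params.projection_frames)
    centers = movie_analysis.detect_peaks(proj, params)
    ctx["centers"] = centers
    rois_path = out / "rois.csv"
    pd.DataFrame(
        [{"id": i, "row": r, "col": c} for i, (r, c) in enumerate(centers)]
    ).to_csv(rois_path, index=False)
    counts = {"detections": len(centers)}
    logger.info("detect: %s", counts)
    _sidecar(rois_path, cfg, "detect", counts)
    return [rois_path]


def _stage_trace(cfg: RunConfig, ctx: dict, out: Path):
    stack = _need(ctx, cfg, "stack", "movie.tif")
    if isinstance(stack, Path):
        stack = io.read_stack(stack)
    centers = ctx.get("centers")
    if centers is None:
        rois = _need(ctx, cfg, "rois", "rois.csv")
        centers = [
            (int(r.row), int(r.col)) for r in pd.read_csv(rois).itertuples()
        ]
    traces = movie_analysis.extract_traces(stack, centers)
    ctx["traces"] = traces
    traces_path = out / "traces.csv"
    io.write_traces_csv(traces, traces_path, rois_path=out / "trace_rois.csv")
    counts = {"traces": len(traces)}
    logger.info("trace: %s", counts)
    _sidecar(traces_path, cfg, "trace", counts)
    return [traces_path, out / "trace_rois.csv"]


def _get_traces(cfg: RunConfig, ctx: dict):
    traces = ctx.get("traces")
    if traces is None:
        path = _need(ctx, cfg, "traces", "traces.csv")
        traces = [
            movie_analysis.RoiTrace(values=v) for v in io.read_traces_csv(path)
        ]
        ctx["traces"] = traces
    return traces


def _stage_hmm(cfg: RunConfig, ctx: dict, out: Path):
    traces = _get_traces(cfg, ctx)
    model = blink_hmm.fit_blink_model(
        traces, blink_hmm.BlinkModel(**cfg.hmm), seed=cfg.seed
    )
    paths = [blink_hmm.decode(t, model) for t in traces]
    ctx["model"] = model
    ctx["state_paths"] = paths
    states_path = out / "states.csv"
    pd.DataFrame({f"molecule_{i}": p for i, p in enumerate(paths)}).to_csv(
        states_path, index=False
    )
    counts = {"traces": len(paths)}
    logger.info("hmm: %s (on-state means %s)", counts, model.state_means[:2])
    _sidecar(states_path, cfg, "hmm", counts)
    return [states_path]


def _stage_metrics(cfg: RunConfig, ctx: dict, out: Path):
    paths = ctx.get("state_paths")
    if paths is None:
        states = _need(ctx, cfg, "states", "states.csv")
        paths = [s.astype(int) for s in io.read_traces_csv(states)]
    traces = ctx.get("traces", [None] * len(paths))
    camera = cfg.camera_model()
    records = [
        blink_hmm.blink_metrics(p, cfg.exposure, trace=t, camera=camera)
        for p, t in zip(paths, traces)
    ]
    ctx["records"] = records
    metrics_path = out / "metrics.csv"
    blink_hmm.metrics_table(records).to_csv(metrics_path, index=False)
    summary = blink_hmm.summarize_cohort(records)
    io.write_json(summary, out / "cohort_summary.json")
    counts = {
        "molecules": len(records),
        "valid": sum(r.valid for r in records),
    }
    logger.info("metrics: %s", counts)
    _sidecar(metrics_path, cfg, "metrics", counts)
    return [metrics_path, out / "cohort_summary.json"]


def _stage_lifetime(cfg: RunConfig, ctx: dict, out: Path):
    opts = dict(cfg.lifetime)
    window = tuple(opts.pop("window", lifetime_fit.DEFAULT_FIT_WINDOW))
    decay_path = _need(ctx, cfg, "decay", "decay.tsv")
    decay = lifetime_fit.DecayHistogram.from_text(decay_path, fit_window=window)
    fit = lifetime_fit.select_model(decay, **opts)
    result = {
        "order": fit.order,
        "background": fit.background,
        "components": [{"amplitude": a, "lifetime_ns": tau} for a, tau in fit.components],
        "amplitude_weighted_lifetime_ns": lifetime_fit.amplitude_weighted_lifetime(fit),
        "rss": fit.rss,
        "bic_table": {
            str(k): (None if v is None else {"bic": v[0], "rel_likelihood": v[1]})
            for k, v in fit.bic_table.items()  # type: ignore[attr-defined]
        },
    }
    fit_path = out / "lifetime_fit.json"
    io.write_json(result, fit_path)
    logger.info("lifetime: selected order %d", fit.order)
    _sidecar(fit_path, cfg, "lifetime", {"order": fit.order})
    return [fit_path]


def _stage_fret(cfg: RunConfig, ctx: dict, out: Path):
    from . import fret_core

    opts = cfg.fret
    result: dict = {}
    if "tau_d" in opts and "tau_da" in opts:
        result["efficiency"] = fret_core.efficiency_from_lifetime(
            opts["tau_d"], opts["tau_da"]
        )
    elif "i_d" in opts and "i_da" in opts:
        result["efficiency"] = fret_core.efficiency_from_intensity(
            opts["i_d"], opts["i_da"]
        )
    elif "efficiency" in opts:
        result["efficiency"] = opts["efficiency"]
    else:
        raise PipelineError(
            "fret stage needs tau_d/tau_da, i_d/i_da, or efficiency in config.fret"
        )
    if "r0" in opts and 0 < result["efficiency"] < 1:
        result["distance_nm"] = fret_core.distance_from_efficiency(
            result["efficiency"], opts["r0"]
        )
    fret_path = out / "fret.json"
    io.write_json(result, fret_path)
    _sidecar(fret_path, cfg, "fret", {})
    return [fret_path]


def _stage_track(cfg: RunConfig, ctx: dict, out: Path):
    locs = ctx.get("localizations")
    if locs is None:
        path = _need(ctx, cfg, "localizations", "localizations.csv")
        locs = io.read_localizations(path)
    opts = dict(cfg.track)
    reference = opts.pop("donor_only_mean_intensity", None)
    bin_width = opts.pop("bin_width", 2 * cfg.pixel_size)
    cutoff = opts.pop("cutoff", None)
    trajs = tracking.link(locs, exposure=cfg.exposure, **opts)
    if reference:
        for t in trajs:
            t.fret_efficiency = tracking.trajectory_fret(t, reference)
    ctx["trajectories"] = trajs
    rows = []
    for t in trajs:
        for f, x, y, i in zip(t.frames, t.x, t.y, t.intensity):
            rows.append(
                {"traj_id": t.traj_id, "frame": f, "x_nm": x, "y_nm": y,
                 "intensity_adu": i}
            )
    traj_path = out / "trajectories.csv"
    pd.DataFrame(rows).to_csv(traj_path, index=False)
    tracking.trajectory_table(trajs).to_csv(out / "trajectory_summary.csv", index=False)
    dmap = tracking.density_map(trajs, bin_width=bin_width, cutoff=cutoff)
    io.write_json(
        {
            "bin_width_nm": dmap.bin_width,
            "counts": dmap.counts,
            "mean_track_length_s": np.nan_to_num(dmap.mean_track_length, nan=-1.0),
            "cutoff_s": cutoff,
        },
        out / "density_map.json",
    )
    counts = {"localizations": len(locs), "trajectories": len(trajs)}
    logger.info("track: %s", counts)
    _sidecar(traj_path, cfg, "track", counts)
    return [traj_path, out / "trajectory_summary.csv", out / "density_map.json"]


def _stage_report(cfg: RunConfig, ctx: dict, out: Path):
    rep = report_mod.photophysics_report()
    report_path = out / "report.json"
    io.write_json(rep, report_path)
    _sidecar(report_path, cfg, "report", {"pairs": len(rep)})
    return [report_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "trace": _stage_trace,
    "hmm": _stage_hmm,
    "metrics": _stage_metrics,
    "lifetime": _stage_lifetime,
    "fret": _stage_fret,
    "track": _stage_track,
    "report": _stage_report,
}


def run_pipeline(config: RunConfig, stages) -> dict[str, list[Path]]:
    """Execute the given stages in order, returning artifact paths per
    stage.  Partial outputs of a failing stage are removed."""
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown} (choose from {STAGES})")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    artifacts: dict[str, list[Path]] = {}
    for stage in stages:
        before = {p for p in out.rglob("*")}
        try:
            artifacts[stage] = _STAGE_FUNCS[stage](config, ctx, out)
        except Exception:
            for p in {p for p in out.rglob("*")} - before:
                if p.is_file():
                    p.unlink(missing_ok=True)
            raise
    return artifacts
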