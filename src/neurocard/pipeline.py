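"""Reproducible analysis runs: stage registry, sidecar metadata, seeding.

Each stage reads its inputs, runs one library operation, and writes its
outputs into an output directory together with a ``run.json`` sidecar
(stage, parameters, seed, config hash, package version, durations).
Re-running a directory's sidecar reproduces it: deterministic stages
bit-exactly, stochastic stages exactly at the same seed.  Outputs are
staged in a temporary directory and moved into place only on success, so
a failing run leaves no partial outputs behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from ._rng import spawn_int
from .activation import (ClassifyThresholds, analyze_video,
                         compute_activation_times, extract_filtered_traces,
                         isochronal_map, wave_speed)
from .firing import (StimulationProtocol, detect_spikes,
                     normalized_firing_score)
from .medium import SimulationConfig, render_optical, simulate_monolayer
from .mosaic import BoundaryMask
from .motion import detect_beats, frame_crosscorrelation
from .trace import Trace
from .transects import random_transects
from .videostack import read_video, write_video

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline stage invocation."""

    stage: str
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # name -> path
    out_dir: str | Path = "run_out"
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            {"stage": self.stage, "params": self.params,
             "inputs": {k: str(v) for k, v in self.inputs.items()},
             "seed": self.seed}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    params = dict(cfg.params)
    modality = params.pop("modality", "voltage_like")
    noise_sd = params.pop("noise_sd", 0.0)
    blur_sigma = params.pop("blur_sigma", 0.0)
    sim = SimulationConfig(seed=spawn_int(cfg.seed, "simulate"), **params)
    video, truth = simulate_monolayer(sim)
    optical = render_optical(video, noise_sd=noise_sd,
                             blur_sigma=blur_sigma, modality=modality,
                             seed=sim.seed)
    write_video(optical, out / "video.tif", seed=cfg.seed)
    np.savez_compressed(
        out / "truth.npz",
        activation_times=truth.activation_times,
        singularity_count=truth.singularity_count)
    summary = {
        "regime": truth.regime_label,
        "true_plane_speed_mm_s": truth.true_plane_speed,
        "singularity_count_median": float(np.median(
            truth.singularity_count)) if truth.singularity_count.size else 0,
        "source_rc": truth.source_rc,
        "pacing_period_s": truth.pacing_period,
    }
    (out / "truth_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_motion(cfg: RunConfig, out: Path) -> dict:
    video = read_video(cfg.inputs["video"],
                       cfg.params.get("pixel_size"),
                       cfg.params.get("frame_interval"))
    trace = frame_crosscorrelation(video,
                                   cfg.params.get("reference_index", 0))
    trace.to_csv(out / "trace.csv")
    beats = detect_beats(trace,
                         **{k: cfg.params[k] for k in
                            ("smooth_window", "min_interval",
                             "threshold_frac", "rate_window")
                            if k in cfg.params})
    beats.to_csv(out / "beats.csv")
    summary = {"n_beats": beats.n_beats,
               "mean_rate_bpm": beats.mean_rate}
    (out / "beats.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_map(cfg: RunConfig, out: Path) -> dict:
    video = read_video(cfg.inputs["video"],
                       cfg.params.get("pixel_size"),
                       cfg.params.get("frame_interval"))
    ft = extract_filtered_traces(
        video, cfg.params.get("spatial_bin", 1),
        cfg.params.get("median_window", 2.0))
    amap = compute_activation_times(
        ft, cfg.params.get("threshold_frac", 0.5))
    wsf = wave_speed(amap, cfg.params.get("smoothing", 3.0))
    np.savez_compressed(out / "activation.npz", times=amap.times,
                        valid_mask=amap.valid_mask,
                        local_speed=wsf.local_speed)
    cycle = min(1, amap.n_cycles - 1)
    iso = isochronal_map(amap, cycle)
    _render_isochrone_png(iso, out / "isochrone.png", amap.pixel_size)
    summary = {"p90_speed_mm_s": wsf.p90_speed, "n_cycles": amap.n_cycles,
               "isochrone_cycle": cycle}
    (out / "map_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_classify(cfg: RunConfig, out: Path) -> dict:
    video = read_video(cfg.inputs["video"],
                       cfg.params.get("pixel_size"),
                       cfg.params.get("frame_interval"))
    th = ClassifyThresholds(**cfg.params.get("thresholds", {}))
    _, _, verdict = analyze_video(
        video, cfg.params.get("spatial_bin", 1),
        cfg.params.get("median_window", 2.0), thresholds=th)
    summary = {"regime": verdict.regime, "complexity": verdict.complexity,
               "status": verdict.status, "detail": verdict.detail,
               "singularity_count_median":
                   verdict.singularity_count_median,
               "wavefront_fragment_count_median":
                   verdict.wavefront_fragment_count_median}
    (out / "classification.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_score(cfg: RunConfig, out: Path) -> dict:
    trace = Trace.from_csv(cfg.inputs["trace"])
    protocol = StimulationProtocol.from_json(Path(cfg.inputs["protocol"]))
    spikes = detect_spikes(
        trace,
        median_window=cfg.params.get("median_window", 1.0),
        threshold_k=cfg.params.get("threshold_k", 5.0),
        refractory=cfg.params.get("refractory", 0.2),
        protocol=protocol)
    spikes.to_csv(out / "spikes.csv")
    result = normalized_firing_score(
        spikes, protocol, cfg.params.get("convention", "rate"))
    result.to_json(out / "score.json")
    return json.loads(result.to_json())


def _stage_transect(cfg: RunConfig, out: Path) -> dict:
    mask = BoundaryMask.load(cfg.inputs["mask"], cfg.params["pixel_size"])
    res = random_transects(mask,
                           cfg.params.get("length_um", 50.0),
                           cfg.params.get("n_transects", 100),
                           seed=spawn_int(cfg.seed, "transect"))
    np.savetxt(out / "counts.csv", res.counts, fmt="%d",
               header="crossings", comments="")
    summary = {"transect_length_um": res.transect_length,
               "n_transects": res.n_transects,
               "mean_N": res.mean_N, "sd_N": res.sd_N,
               "spacing_mean_um": res.spacing_mean,
               "spacing_sd_um": res.spacing_sd}
    (out / "transects.json").write_text(json.dumps(summary, indent=2))
    return summary


_STAGES = {
    "simulate": _stage_simulate,
    "motion": _stage_motion,
    "map": _stage_map,
    "classify": _stage_classify,
    "score": _stage_score,
    "transect": _stage_transect,
}


def _render_isochrone_png(iso: np.ndarray, path: Path,
                          pixel_size: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    extent = [0, iso.shape[1] * pixel_size / 1000.0,
              iso.shape[0] * pixel_size / 1000.0, 0]
    im = ax.imshow(iso * 1000.0, cmap="viridis", extent=extent)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.colorbar(im, ax=ax, label="activation time (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute one stage (or a ``pipeline`` of stages) reproducibly.

    Returns the stage summary dict.  Unknown stages raise a ValueError
    listing the registered stages; missing inputs raise before any
    output is written.
    """
    if config.stage == "pipeline":
        summaries = {}
        for i, sub in enumerate(config.params["stages"]):
            sub_cfg = RunConfig(
                stage=sub["stage"], params=sub.get("params", {}),
                inputs=sub.get("inputs", {}),
                out_dir=Path(config.out_dir) / sub["stage"],
                seed=config.seed)
            # later stages may consume earlier outputs by name
            for k, v in list(sub_cfg.inputs.items()):
                sub_cfg.inputs[k] = str(v).format(out=config.out_dir)
            summaries[f"{i}:{sub['stage']}"] = run_pipeline(sub_cfg)
        return summaries

    if config.stage not in _STAGES:
        raise ValueError(
            f"unknown stage {config.stage!r}; registered stages: "
            f"{sorted(_STAGES)} (or 'pipeline')")
    for name, p in config.inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(
                f"input {name!r} not found at {p}; nothing was written")

    out = Path(config.out_dir)
    tmp = out.parent / (out.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    t0 = time.time()
    try:
        summary = _STAGES[config.stage](config, tmp)
        sidecar = {
            "stage": config.stage, "params": config.params,
            "inputs": {k: str(v) for k, v in config.inputs.items()},
            "seed": config.seed, "config_hash": config.config_hash(),
            "version": __version__,
            "duration_s": round(time.time() - t0, 3),
        }
        (tmp / "run.json").write_text(json.dumps(sidecar, indent=2))
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    if out.exists():
        shutil.rmtree(out)
    tmp.rename(out)
    log.info("stage %s finished in %.1fs -> %s", config.stage,
             time.time() - t0, out)
    return summary
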