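"""End-to-end orchestration: simulate → acquire → deskew → segment →
analyze (and the paired PZT-on/off tracking comparison), with persisted
intermediates and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .flow import apply_focusing
from .geometry import ChannelGeometry
from .imaging import acquire_lateral_movie, acquire_stack, save_movie
from .mitotic import (ClassifyParams, Gate, classify_phase, count_dna_regions,
                      gate_positive, population_report)
from .reconstruct import DeskewCalibration, deskew
from .scene import sample_population
from .segment import count_check, detection_throughput, save_records, segment_cells
from .tracking import detect_movie, link_tracks, velocity_stats


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _scene_geometry(config: RunConfig) -> ChannelGeometry:
    return dataclasses.replace(config.flow.geometry, length_l=config.scene.length_l)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages and return the manifest (also written to
    ``manifest.json`` in ``outdir``).  A stage failure raises
    :class:`StageError` naming the stage; earlier outputs are kept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }
    files: dict[str, list[str]] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - stage isolation
                _write_manifest(outdir, manifest)
                raise StageError(name, exc) from exc
            manifest["stages"].append({
                "name": name,
                "outputs": [str(p) for p in out],
                "seconds": round(time.perf_counter() - t0, 3),
            })
            files[name] = out
            return out
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        pop = sample_population(
            config.scene.n_cells, _scene_geometry(config),
            phase_fractions=config.scene.phase_fractions,
            size_distribution=(config.scene.size_mean, config.scene.size_sd),
            seed=config.stage_seed("scene"))
        apply_focusing(pop, config.acoustics, config.flow,
                       seed=config.stage_seed("focusing"))
        path = outdir / "population.csv"
        pop.save(path)
        state["pop"] = pop
        return [path, path.with_suffix(".json")]

    @stage("acquire")
    def _acquire():
        stack = acquire_stack(state["pop"], config.optics,
                              config.acquire.n_frames,
                              channels=config.acquire.channels,
                              seed=config.stage_seed("acquire"))
        state["stack"] = stack
        return stack.save(outdir / "stack")

    @stage("deskew")
    def _deskew():
        stack = state["stack"]
        v = config.deskew.velocity or stack.motion
        calib = DeskewCalibration.from_optics(stack.optics, v,
                                              interpolation=config.deskew.interpolation)
        vol = deskew(stack, calib)
        state["volume"] = vol
        return vol.save(outdir / "volume")

    @stage("segment")
    def _segment():
        labels, records = segment_cells(state["volume"], "cyto", config.segmentation)
        state["labels"], state["records"] = labels, records
        import tifffile
        labels_path = outdir / "labels.tif"
        dtype = np.uint16 if labels.max() < 2 ** 16 else np.uint32
        tifffile.imwrite(labels_path, labels.astype(dtype))
        path = outdir / "records.csv"
        save_records(records, path)
        check_path = outdir / "count_check.json"
        stack = state["stack"]
        payload = {
            "count": len(records),
            "detection_throughput_cells_per_s":
                detection_throughput(len(records), stack.duration) if records else 0.0,
        }
        if records:
            chk = count_check(records)
            payload.update({"area_ratio": chk.ratio, "flagged": chk.flagged})
        check_path.write_text(json.dumps(payload, indent=2))
        return [labels_path, path, check_path]

    @stage("analyze")
    def _analyze():
        records, labels, vol = state["records"], state["labels"], state["volume"]
        gate = Gate(marker_threshold=config.analysis.marker_threshold)
        positives, scatter = gate_positive(records, gate)
        regions = {r.label: count_dna_regions(
            r, labels, vol,
            region_threshold=config.analysis.region_threshold,
            min_region_volume=config.analysis.min_region_volume) for r in positives}
        calls = classify_phase(positives, regions, ClassifyParams(
            ratio_threshold=config.analysis.ratio_threshold,
            pair_distance=config.analysis.pair_distance))
        report = population_report(calls, records, state["stack"].duration)
        scatter_path = outdir / "scatter.csv"
        scatter.to_csv(scatter_path, index=False)
        calls_path = outdir / "phase_calls.csv"
        import pandas as pd
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(calls_path, index=False)
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        return [scatter_path, calls_path, report_path]

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def track_movie_stats(config: RunConfig, pzt_on: bool, outdir: Path | None = None):
    """Simulate a lateral movie under one PZT state and run velocimetry."""
    acoustics = dataclasses.replace(config.acoustics, pzt_on=pzt_on)
    pop = sample_population(
        config.scene.n_cells, _scene_geometry(config),
        phase_fractions=config.scene.phase_fractions,
        size_distribution=(config.scene.size_mean, config.scene.size_sd),
        seed=config.stage_seed("scene"))
    apply_focusing(pop, acoustics, config.flow, seed=config.stage_seed("focusing"))
    movie = config.movie
    frames = acquire_lateral_movie(pop, movie, config.tracking.n_frames,
                                   seed=config.stage_seed("movie"))
    dets = detect_movie(frames, px=movie.px, params=config.detect)
    tracks = link_tracks(dets, max_displacement=config.tracking.max_displacement,
                         memory=config.tracking.memory)
    stats = velocity_stats(tracks, movie.frame_rate)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = "on" if pzt_on else "off"
        save_movie(frames, movie, outdir / f"movie_pzt_{tag}")
        (outdir / f"velocity_stats_pzt_{tag}.json").write_text(
            json.dumps(stats.to_dict(), indent=2))
    return stats


def compare_pzt_modes(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Paired PZT-on/off velocimetry with identical cell identities (same
    scene seed); only the focusing state differs.  Returns both stats and
    their CV pair."""
    out = Path(outdir) if outdir is not None else None
    stats_on = track_movie_stats(config, pzt_on=True, outdir=out)
    stats_off = track_movie_stats(config, pzt_on=False, outdir=out)
    result = {
        "pzt_on": stats_on.to_dict(),
        "pzt_off": stats_off.to_dict(),
        "cv_on": stats_on.cv,
        "cv_off": stats_off.cv,
    }
    if out is not None:
        (out / "pzt_comparison.json").write_text(json.dumps(result, indent=2))
    return result
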