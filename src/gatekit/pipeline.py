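"""Reproducible end-to-end pipelines behind the command-line interface.

Two orchestrations: the trace pipeline (simulate or ingest → filter →
window → idealize → QC → kinetics report) and the movie pipeline
(simulate or ingest → drift-correct → iterative correlation averaging →
mean/std maps).  Every run writes the fully resolved configuration and
seed next to its outputs so any artifact can be regenerated exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import movie as movie_mod
from . import particles as part
from .idealize import write_idealized_csv
from .model import TwoStateGatingModel
from .synthetic import (EPHYS_PRESETS, HS_PRESETS, TelegraphConfig,
                        simulate_ephys_trace, simulate_height_trace,
                        simulate_telegraph, write_events_csv)
from .trace import read_trace_binary, read_trace_text

__all__ = ["ConfigError", "run_hs_pipeline", "run_afm_pipeline"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


def _resolve_seed(config: dict, default: int = 0) -> int:
    return int(config.get("seed", default))


def _dump_config(config: dict, outdir: Path) -> None:
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)


def _load_or_simulate_trace(config: dict, seed: int):
    """Return a list of TimeTrace from config (inputs or simulation)."""
    if "input" in config:
        paths = config["input"]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        traces = []
        for p in paths:
            p = Path(p)
            if not p.exists():
                raise ConfigError(f"input path does not exist: {p}")
            if p.suffix in (".txt", ".dat", ".csv", ".tsv"):
                traces.append(read_trace_text(p))
            else:
                traces.append(read_trace_binary(p))
        return traces, None
    sim = config.get("simulate")
    if sim is None:
        raise ConfigError("config needs either 'input' or 'simulate'")
    duration = float(sim.get("duration", 10.0))
    preset = sim.get("preset")
    overrides = sim.get("overrides", {})
    if preset in HS_PRESETS:
        trace, path = simulate_height_trace(preset, overrides, seed=seed,
                                            duration=duration)
    elif preset in EPHYS_PRESETS:
        trace, path = simulate_ephys_trace(preset, overrides, seed=seed,
                                           duration=duration)
    elif preset is None:
        cfg = TelegraphConfig(seed=seed, duration=duration,
                              **sim.get("telegraph", {}))
        trace, path = simulate_telegraph(cfg)
    else:
        raise ConfigError(
            f"unknown preset {preset!r}; available: "
            f"{sorted(HS_PRESETS) + sorted(EPHYS_PRESETS)}")
    return [trace], path


def run_hs_pipeline(config: dict, outdir) -> dict:
    """Trace pipeline: (simulate|ingest) → filter → window → idealize →
    QC → kinetics.  Writes event tables, dwell tables, histograms and a
    summary JSON; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = _resolve_seed(config)
    _dump_config(config, outdir)
    log.info("trace pipeline: seed=%d outdir=%s", seed, outdir)

    traces, truth = _load_or_simulate_trace(config, seed)
    if truth is not None:
        write_events_csv(truth, outdir / "true_events.csv")

    params = config.get("analysis", {})
    model = TwoStateGatingModel(
        traces,
        cutoff_hz=params.get("cutoff_hz", 20_000.0),
        window_s=params.get("window_s", 0.5),
        t_crit=params.get("t_crit", 4.5),
        min_len=params.get("min_len", 3),
        dead_time_s=params.get("dead_time_us", 0.0) * 1e-6,
        min_separation=params.get("min_sep", 0.25),
        max_components=params.get("components", 2),
        temperature_k=params.get("temperature_k", 298.0),
    )
    results = model.fit(n_bootstrap=params.get("n_bootstrap", 200),
                        seed=seed)

    for i, ideal in enumerate(results.idealized):
        write_idealized_csv(ideal, outdir / f"idealized_{i:04d}.csv")
    results.dwells.to_frame().to_csv(outdir / "dwells.csv", index=False)
    for state in ("open", "closed"):
        d = results.dwells.durations(state)
        if d.size:
            results.dwell_histogram(
                state, params.get("bins_per_decade", 10)
            ).to_frame().to_csv(outdir / f"hist_{state}.csv", index=False)
    results.to_json(outdir / "summary.json")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    log.info("trace pipeline done: P_open=%.3f tau_open=%.3g s",
             results.p_open, results.tau_open)
    return results.to_dict()


def _seed_window_from_movie(movie, window_px: int):
    """Auto-select a seed particle window around the highest topography
    point of the time-averaged movie (away from the borders)."""
    mean_frame = movie.frames.mean(axis=0)
    half = window_px // 2
    inner = mean_frame[half:-half or None, half:-half or None]
    i, j = np.unravel_index(int(np.argmax(inner)), inner.shape)
    i, j = i + half, j + half
    return movie.frames[0][i - half:i + half + 1, j - half:j + half + 1]


def run_afm_pipeline(config: dict, outdir) -> dict:
    """Movie pipeline: (simulate|ingest) → register → iterative
    correlation averaging → average/std maps.  Returns diagnostics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = _resolve_seed(config)
    _dump_config(config, outdir)

    if "input" in config:
        p = Path(config["input"])
        if not p.exists():
            raise ConfigError(f"input path does not exist: {p}")
        mv = movie_mod.read_movie(p)
        truth = None
    else:
        sim = config.get("simulate")
        if sim is None:
            raise ConfigError("config needs either 'input' or 'simulate'")
        cfg = movie_mod.MovieConfig(seed=seed, **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in sim.items()})
        mv, truth = movie_mod.simulate_afm_movie(cfg)
        movie_mod.write_movie(mv, outdir / "movie.tif")
        truth.to_csv(outdir / "true_particles.csv", index=False)

    params = config.get("analysis", {})
    window_px = int(params.get("window_px", 37))
    if window_px % 2 == 0:
        raise ConfigError("window_px must be odd")
    registered, drifts = (part.register_frames(mv) if mv.n_frames > 1
                          else (mv, np.zeros((1, 2))))
    pd.DataFrame(drifts, columns=["dy_px", "dx_px"]).to_csv(
        outdir / "drift.csv", index=False)

    seed_win = _seed_window_from_movie(registered, window_px)
    avg, std, stack, diag = part.iterative_average(
        registered, seed_win,
        rounds=int(params.get("rounds", 2)),
        threshold=float(params.get("threshold", 0.7)))

    part.write_map(avg, outdir / "average_map.tif", png=True)
    part.write_map(std, outdir / "std_map.tif", png=True)
    stack.records.to_csv(outdir / "picks.csv", index=False)
    out = {"n_particles_per_round": diag["n_particles"],
           "mean_score_per_round": diag["mean_score"],
           "n_frames": mv.n_frames, "window_px": window_px}
    with open(outdir / "afm_summary.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    log.info("movie pipeline done: %d particles in final round",
             stack.n_particles)
    return out
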