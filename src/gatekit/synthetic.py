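"""Seeded generators for two-state gating signals with ground truth.

The core generator draws an alternating renewal (telegraph) process: the
molecule dwells in the *low* and *high* signal levels for exponentially
distributed times, optionally with a second, short-lived ("flicker")
component mixed into one state's dwell distribution.  Event boundaries are
drawn in continuous time and then rasterized onto the sampling grid, so no
per-sample geometric approximation is involved.  Gaussian noise and a slow
baseline drift (sinusoid by default, random walk optionally) are added on
top.

Presets reproduce the two experimental signal classes analysed downstream:

* height-spectroscopy traces — ~0.5 nm level separation, 0.1 nm noise,
  open state at the LOW level (the probe descends into the open pore);
* single-channel current traces — 40 pA open level, 0 pA closed, open at
  the HIGH level, 5 kHz low-pass at 100 kHz sampling.

Every generator returns the ground-truth state path alongside the trace so
recovery of dwell constants and occupancies can be tested without any
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .trace import TimeTrace

__all__ = [
    "TelegraphConfig",
    "TruePath",
    "PathEvent",
    "simulate_telegraph",
    "simulate_ephys_trace",
    "simulate_height_trace",
    "EPHYS_PRESETS",
    "HS_PRESETS",
    "write_events_csv",
    "read_events_csv",
]

LOW, HIGH = "low", "high"


@dataclass(frozen=True)
class PathEvent:
    """One ground-truth dwell: state label, start sample, length in samples."""
    state: str
    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass
class TruePath:
    """Ground-truth piecewise-constant state path on the sampling grid.

    Events tile ``[0, n_samples)`` half-open with no gaps or overlaps and
    adjacent events carry different state labels.  ``components`` records,
    for each event, which dwell-mixture component generated it ("main" or
    "flicker"); it is aligned with ``events``.
    """

    events: list
    n_samples: int
    components: list = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = 0
        for i, ev in enumerate(self.events):
            if ev.start != pos or ev.length <= 0:
                raise ValueError("events must tile [0, N) without gaps")
            if i and ev.state == self.events[i - 1].state:
                raise ValueError("adjacent events must differ in state")
            pos = ev.stop
        if pos != self.n_samples:
            raise ValueError("events must end at n_samples")
        if self.components and len(self.components) != len(self.events):
            raise ValueError("components must align with events")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def occupancy(self, state: str) -> float:
        """Fraction of samples spent in ``state``."""
        tot = sum(ev.length for ev in self.events if ev.state == state)
        return tot / self.n_samples

    def state_per_sample(self) -> np.ndarray:
        """Expand events to an integer array (0 = low, 1 = high)."""
        out = np.empty(self.n_samples, dtype=np.int8)
        for ev in self.events:
            out[ev.start:ev.stop] = 0 if ev.state == LOW else 1
        return out


@dataclass
class TelegraphConfig:
    """Parameters of the two-state telegraph generator.

    ``tau_low``/``tau_high`` are the mean dwell times (s) of the low and
    high signal levels.  ``flicker`` optionally mixes a short-lived
    exponential component (weight, tau_s) into the dwell distribution of
    ``flicker_state``, emulating sub-100-µs closures.  Noise is i.i.d.
    Gaussian; baseline drift is a sinusoid of given amplitude and period
    (or a random walk when ``drift_model="random_walk"``).
    """

    tau_low: float = 2.16e-3
    tau_high: float = 0.23e-3
    level_low: float = 0.0
    level_high: float = 0.5
    flicker: Optional[tuple] = None     # (weight in [0,1], tau_flicker_s)
    flicker_state: str = HIGH
    noise_sigma: float = 0.1
    drift_amplitude: float = 0.0
    drift_period: float = 1.0
    drift_model: str = "sine"           # "sine" | "random_walk"
    sample_rate: float = 100_000.0
    duration: float = 1.0
    units: str = "nm"
    polarity: str = "open_is_low"
    seed: int = 0

    def validate(self) -> None:
        for name in ("tau_low", "tau_high", "sample_rate", "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.level_low == self.level_high:
            raise ValueError("level_low must differ from level_high")
        if self.flicker is not None:
            w, tf = self.flicker
            if not 0.0 <= w <= 1.0:
                raise ValueError("flicker weight must be in [0, 1]")
            if not tf > 0:
                raise ValueError("flicker tau must be > 0")
        if self.flicker_state not in (LOW, HIGH):
            raise ValueError("flicker_state must be 'low' or 'high'")
        if self.drift_model not in ("sine", "random_walk"):
            raise ValueError("drift_model must be 'sine' or 'random_walk'")
        if self.drift_model == "sine" and not self.drift_period > 0:
            raise ValueError("drift_period must be > 0")


def _draw_dwell(rng, state, cfg):
    """Sample one dwell duration; returns (duration_s, component_label)."""
    tau = cfg.tau_low if state == LOW else cfg.tau_high
    if cfg.flicker is not None and state == cfg.flicker_state:
        w, tau_f = cfg.flicker
        if rng.random() < w:
            return rng.exponential(tau_f), "flicker"
    return rng.exponential(tau), "main"


def simulate_telegraph(config: TelegraphConfig):
    """Simulate a two-state telegraph trace with ground truth.

    Dwells are drawn in continuous time from the configured exponential
    (or two-component exponential) distributions, starting from the
    stationary state distribution; event boundaries are rounded to the
    nearest sample.  Returns ``(TimeTrace, TruePath)``.  The same config
    and seed give bit-identical output.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sample_rate))
    if n < 1:
        raise ValueError("duration too short for one sample")

    p_low = cfg.tau_low / (cfg.tau_low + cfg.tau_high)
    state = LOW if rng.random() < p_low else HIGH

    # continuous-time event list: (state, t_start, component)
    t = 0.0
    cont = []
    while t < cfg.duration:
        dur, comp = _draw_dwell(rng, state, cfg)
        cont.append((state, t, comp))
        t += dur
        state = HIGH if state == LOW else LOW

    # rasterize: boundary sample = round(t * fs); drop empty, merge equals
    events, comps = [], []
    for i, (st, t0, comp) in enumerate(cont):
        b0 = int(round(t0 * cfg.sample_rate))
        t1 = cont[i + 1][1] if i + 1 < len(cont) else cfg.duration
        b1 = int(round(t1 * cfg.sample_rate))
        b0, b1 = min(b0, n), min(b1, n)
        if b1 <= b0:
            continue
        if events and events[-1].state == st:
            prev = events.pop()
            comps.pop()
            b0 = prev.start
        events.append(PathEvent(st, b0, b1 - b0))
        comps.append(comp)
    path = TruePath(events, n, comps)

    levels = {LOW: cfg.level_low, HIGH: cfg.level_high}
    values = np.array([levels[LOW], levels[HIGH]],
                      dtype=float)[path.state_per_sample()]
    if cfg.noise_sigma > 0:
        values = values + rng.normal(0.0, cfg.noise_sigma, n)
    if cfg.drift_amplitude > 0:
        if cfg.drift_model == "sine":
            tt = np.arange(n) / cfg.sample_rate
            values = values + cfg.drift_amplitude * np.sin(
                2 * math.pi * tt / cfg.drift_period)
        else:
            step = cfg.drift_amplitude / math.sqrt(n)
            values = values + np.cumsum(rng.normal(0.0, step, n))

    trace = TimeTrace(values, cfg.sample_rate, cfg.units, cfg.polarity,
                      metadata={"seed": cfg.seed, "generator": "telegraph",
                                "tau_low": cfg.tau_low,
                                "tau_high": cfg.tau_high})
    return trace, path


# --- presets -----------------------------------------------------------------
# Single-channel current recordings: open = 40 pA (high), closed = 0 pA (low);
# flicker component lives in the closed (low-current) dwell distribution.
EPHYS_PRESETS = {
    "pH7.6": dict(tau_open=11.5e-3, tau_closed=0.8e-3,
                  flicker=(0.3, 50e-6)),
    "pH5.0": dict(tau_open=1.9e-3, tau_closed=6.3e-3,
                  flicker=(0.3, 50e-6)),
}

# Height-spectroscopy traces: open = low height (probe in the pore).
HS_PRESETS = {
    "pH7.6-hs": dict(tau_open=2.16e-3, tau_closed=0.23e-3),
    "pH5.0-hs": dict(tau_open=0.77e-3, tau_closed=1.52e-3),
}


def simulate_ephys_trace(preset: str, overrides: Optional[dict] = None,
                         seed: int = 0, duration: float = 10.0,
                         lowpass_hz: Optional[float] = 5_000.0):
    """Simulate a single-channel current trace for a pH preset.

    Open level 40 pA (high), closed 0 pA, 100 kHz sampling, optional 5 kHz
    low-pass (``lowpass_hz=None`` disables filtering).  ``overrides`` are
    applied to the underlying :class:`TelegraphConfig` (e.g.
    ``{"noise_sigma": 0.0, "flicker": None}``).
    """
    if preset not in EPHYS_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(EPHYS_PRESETS)}")
    p = EPHYS_PRESETS[preset]
    cfg = TelegraphConfig(
        tau_low=p["tau_closed"], tau_high=p["tau_open"],
        level_low=0.0, level_high=40.0,
        flicker=p["flicker"], flicker_state=LOW,
        noise_sigma=1.0, sample_rate=100_000.0, duration=duration,
        units="pA", polarity="open_is_high", seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    trace, path = simulate_telegraph(cfg)
    if lowpass_hz is not None:
        from .preprocess import lowpass_filter
        trace = lowpass_filter(trace, lowpass_hz)
    trace.metadata.update(preset=preset, tau_open=p["tau_open"],
                          tau_closed=p["tau_closed"])
    return trace, path


def simulate_height_trace(preset: str, overrides: Optional[dict] = None,
                          seed: int = 0, duration: float = 10.0):
    """Simulate a height-spectroscopy trace for a pH preset.

    Open = low height; 0.5 nm level separation, 0.1 nm noise, 500 kHz
    acquisition by default (filter downstream with
    :func:`gatekit.preprocess.lowpass_filter`).
    """
    if preset not in HS_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(HS_PRESETS)}")
    p = HS_PRESETS[preset]
    cfg = TelegraphConfig(
        tau_low=p["tau_open"], tau_high=p["tau_closed"],
        level_low=0.0, level_high=0.5,
        noise_sigma=0.1, sample_rate=500_000.0, duration=duration,
        units="nm", polarity="open_is_low", seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    trace, path = simulate_telegraph(cfg)
    trace.metadata.update(preset=preset, tau_open=p["tau_open"],
                          tau_closed=p["tau_closed"])
    return trace, path


def write_events_csv(path_obj: TruePath, path) -> None:
    """Write a ground-truth event table as CSV (state,start_sample,length)."""
    rows = [{"state": ev.state, "start_sample": ev.start,
             "length": ev.length,
             "component": (path_obj.components[i]
                           if path_obj.components else "main")}
            for i, ev in enumerate(path_obj.events)]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_events_csv(path) -> TruePath:
    """Read an event table written by :func:`write_events_csv`."""
    df = pd.read_csv(Path(path))
    events = [PathEvent(r.state, int(r.start_sample), int(r.length))
              for r in df.itertuples()]
    comps = (df["component"].tolist() if "component" in df.columns else [])
    n = events[-1].stop if events else 0
    return TruePath(events, n, comps)
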