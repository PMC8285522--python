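"""Model/Results interface for two-state gating analysis.

:class:`TwoStateGatingModel` bundles the full analysis chain — low-pass
filter, drift-defeating windowing, change-point + MDL idealization,
quality control, dwell extraction and exponential-mixture fitting — behind
the familiar ``model.fit() -> results`` pattern.  The returned
:class:`GatingResults` carries the open probability, per-state time
constants with bootstrap standard errors, rate constants, the equilibrium
free-energy difference, and a ``summary()`` table.

Example
-------
>>> from gatekit.synthetic import simulate_height_trace
>>> from gatekit.model import TwoStateGatingModel
>>> trace, _ = simulate_height_trace("pH7.6-hs", seed=1, duration=5.0)
>>> res = TwoStateGatingModel(trace).fit()
>>> round(res.p_open, 2)   # doctest: +SKIP
0.9
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import kinetics as kin
from .idealize import idealize, qc_min_separation
from .kinetics import (DwellSet, ExpMixFit, KineticsSummary,
                       choose_n_components, extract_dwells, fit_exp_mixture,
                       state_probability, summarize)
from .preprocess import lowpass_filter, segment_trace
from .trace import TimeTrace

__all__ = ["TwoStateGatingModel", "GatingResults"]


class TwoStateGatingModel:
    """Two-state gating kinetics estimated from one or more traces.

    Parameters
    ----------
    traces : TimeTrace or sequence of TimeTrace
        Raw (unfiltered) height or current traces.  All traces must share
        units and polarity.
    cutoff_hz : float
        Low-pass corner frequency (−3 dB); ``None`` skips filtering.
        Default 20 kHz, the effective height-spectroscopy bandwidth.
    window_s : float
        Analysis window length; each window is idealized independently so
        slow baseline drift cannot masquerade as extra states.
    t_crit, min_len : float, int
        Change-point acceptance threshold (t statistic) and minimum
        segment length in samples.
    dead_time_s : float
        Events shorter than this are absorbed into the longer neighbour
        (0 = keep everything, resolving sub-100-µs flickers).
    min_separation : float
        QC gate: windows whose two fitted levels are closer than this
        (signal units; default 0.25 nm = 2.5 Å) are excluded.
    max_components : int
        Per-state exponential components to consider (1 or 2); with 2 the
        second component is kept only on a decisive likelihood-ratio
        improvement.
    temperature_k : float
        Temperature for the ΔG conversion (default 298 K, RT ≈ 0.593
        kcal/mol).
    """

    def __init__(self, traces, *, cutoff_hz: Optional[float] = 20_000.0,
                 window_s: float = 0.5, t_crit: float = 4.5,
                 min_len: int = 3, dead_time_s: float = 0.0,
                 min_separation: Optional[float] = None,
                 max_components: int = 2, lr_threshold: float = 6.0,
                 temperature_k: float = 298.0,
                 dead_time_correction: bool = True):
        if isinstance(traces, TimeTrace):
            traces = [traces]
        if not traces:
            raise ValueError("need at least one trace")
        polarities = {t.polarity for t in traces}
        if len(polarities) != 1:
            raise ValueError("all traces must share polarity")
        self.traces = list(traces)
        self.polarity = polarities.pop()
        units = {t.units for t in self.traces}
        if min_separation is None:
            # resolvability floor: half the expected step, mirroring the
            # 2.5 A rule for a 5 A height step: 0.25 nm for height
            # traces, 20 pA for ~40 pA current traces
            min_separation = 0.25 if units == {"nm"} else 20.0
        self.cutoff_hz = cutoff_hz
        self.window_s = window_s
        self.t_crit = t_crit
        self.min_len = min_len
        self.dead_time_s = dead_time_s
        self.min_separation = min_separation
        self.max_components = max_components
        self.lr_threshold = lr_threshold
        self.temperature_k = temperature_k
        self.dead_time_correction = dead_time_correction

    @property
    def resolution_dead_time_s(self) -> float:
        """Effective time resolution of the idealizer, used for the
        first-order missed-event correction: the larger of the filter
        rise time (~0.34/f_c for a Gaussian) and the shortest detectable
        event (~2.5 samples)."""
        if not self.dead_time_correction:
            return 0.0
        fs = min(t.sample_rate for t in self.traces)
        td = 2.5 / fs
        if self.cutoff_hz is not None and self.cutoff_hz < fs / 2.0:
            td = max(td, 0.34 / self.cutoff_hz)
        return td

    @classmethod
    def from_files(cls, paths, reader=None, **kwargs):
        """Build a model from trace files (text or raw binary)."""
        from .trace import read_trace_binary, read_trace_text
        traces = []
        for p in paths:
            p = str(p)
            if reader is not None:
                traces.append(reader(p))
            elif p.endswith((".txt", ".dat", ".csv", ".tsv")):
                traces.append(read_trace_text(p))
            else:
                traces.append(read_trace_binary(p))
        return cls(traces, **kwargs)

    def fit(self, n_bootstrap: int = 200, seed: int = 0) -> "GatingResults":
        """Run the full chain and estimate the gating kinetics."""
        per_trace_ideals = []   # list of lists of IdealizedTrace
        n_windows = n_rejected = 0
        for trace in self.traces:
            filtered = trace
            if self.cutoff_hz is not None and \
               self.cutoff_hz < trace.sample_rate / 2.0:
                filtered = lowpass_filter(trace, self.cutoff_hz)
            ideals = []
            for window in segment_trace(filtered, self.window_s):
                ideal, smodel = idealize(
                    window, t_crit=self.t_crit, min_len=self.min_len,
                    dead_time_s=self.dead_time_s,
                    min_level_sep=self.min_separation)
                n_windows += 1
                if qc_min_separation(smodel, self.min_separation):
                    ideals.append(ideal)
                else:
                    n_rejected += 1
            if ideals:
                per_trace_ideals.append(ideals)
        if not per_trace_ideals:
            raise RuntimeError(
                "no window passed QC "
                f"(min_separation={self.min_separation}); nothing to fit")

        # occupancy: pool windows within each trace, SE across traces
        per_trace_p = []
        tot_open = tot_all = 0.0
        dwells = DwellSet()
        for ideals in per_trace_ideals:
            p, _, _ = state_probability(ideals, self.polarity)
            per_trace_p.append(p)
            for ideal in ideals:
                ds = extract_dwells(ideal, self.polarity)
                tot_open += ds.total_time("open")
                tot_all += ds.total_time("open") + ds.total_time("closed")
                dwells.extend(ds)
        p_open = tot_open / tot_all
        per_trace_p = np.array(per_trace_p)
        if per_trace_p.size > 1:
            p_se = float(per_trace_p.std(ddof=1))
        else:
            # fall back to between-window spread for a single trace
            window_p = [state_probability([i], self.polarity)[0]
                        for i in per_trace_ideals[0]]
            p_se = float(np.std(window_p, ddof=1)) if len(window_p) > 1 \
                else float("nan")

        fits = {}
        for state in ("open", "closed"):
            d = dwells.durations(state)
            if self.max_components >= 2 and d.size >= 20:
                fits[state] = choose_n_components(
                    d, lr_threshold=self.lr_threshold,
                    n_bootstrap=n_bootstrap, seed=seed)
            else:
                fits[state] = fit_exp_mixture(d, 1, n_bootstrap=n_bootstrap,
                                              seed=seed)

        summary = summarize(p_open, p_se, fits["open"], fits["closed"],
                            temperature=self.temperature_k,
                            n_traces=len(per_trace_ideals),
                            dead_time_s=self.resolution_dead_time_s)
        return GatingResults(
            model=self, kinetics=summary, dwells=dwells,
            idealized=[i for ids in per_trace_ideals for i in ids],
            per_trace_p_open=per_trace_p, n_windows=n_windows,
            n_windows_rejected=n_rejected)


@dataclass
class GatingResults:
    """Fitted two-state gating kinetics with uncertainties."""

    model: TwoStateGatingModel
    kinetics: KineticsSummary
    dwells: DwellSet
    idealized: list
    per_trace_p_open: np.ndarray
    n_windows: int
    n_windows_rejected: int

    # -- convenience accessors -------------------------------------------
    @property
    def p_open(self) -> float:
        return self.kinetics.p_open

    @property
    def p_open_se(self) -> float:
        return self.kinetics.p_open_se

    @property
    def tau_open(self) -> float:
        """Gating (slowest-component) open time constant, seconds."""
        return self.kinetics.tau_open

    @property
    def tau_closed(self) -> float:
        """Gating (slowest-component) closed time constant, seconds."""
        return self.kinetics.tau_closed

    @property
    def k_open_to_closed(self) -> float:
        return self.kinetics.k_open_to_closed

    @property
    def k_closed_to_open(self) -> float:
        return self.kinetics.k_closed_to_open

    @property
    def delta_g(self) -> float:
        """ΔG (kcal/mol), positive when the open state is favoured."""
        return self.kinetics.delta_g_kcal

    def dwell_histogram(self, state: str, bins_per_decade: int = 10):
        """Log-binned histogram of the uncensored dwells of one state."""
        return kin.log_bin(self.dwells.durations(state), bins_per_decade)

    def to_dict(self) -> dict:
        out = self.kinetics.to_dict()
        out.update(n_windows=self.n_windows,
                   n_windows_rejected=self.n_windows_rejected,
                   per_trace_p_open=[float(p) for p in self.per_trace_p_open])
        for state in ("open", "closed"):
            fit = getattr(self.kinetics, f"{state}_fit")
            if fit.tau_se is not None:
                out[f"tau_{state}_se_s"] = [float(s) for s in fit.tau_se]
        return out

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        """Human-readable report of the fitted gating kinetics."""
        k = self.kinetics
        lines = []
        w = 58
        lines.append("Two-State Gating Model Results".center(w))
        lines.append("=" * w)
        lines.append(f"{'No. traces:':<28}{k.n_traces:>10d}")
        lines.append(f"{'Windows (accepted/total):':<28}"
                     f"{self.n_windows - self.n_windows_rejected:>5d} /"
                     f"{self.n_windows:>4d}")
        nd = len(self.dwells.durations("open")) + \
            len(self.dwells.durations("closed"))
        lines.append(f"{'Uncensored dwells:':<28}{nd:>10d}")
        lines.append(f"{'Temperature (K):':<28}{k.temperature_k:>10.1f}")
        lines.append("-" * w)
        se = f" +/- {k.p_open_se:.3f}" if np.isfinite(k.p_open_se) else ""
        lines.append(f"P_open                {k.p_open:>10.3f}{se}")
        for state in ("open", "closed"):
            fit: ExpMixFit = getattr(k, f"{state}_fit")
            for i, (tau, wt) in enumerate(zip(fit.taus, fit.weights)):
                se_txt = (f" +/- {fit.tau_se[i] * 1e3:.3f}"
                          if fit.tau_se is not None else "")
                lines.append(f"tau_{state}[{i}] (ms)     "
                             f"{tau * 1e3:>10.3f}{se_txt}"
                             f"   (weight {wt:.2f})")
        lines.append(f"k_open->closed (1/s)  {k.k_open_to_closed:>10.1f}")
        lines.append(f"k_closed->open (1/s)  {k.k_closed_to_open:>10.1f}")
        lines.append(f"Delta G (kcal/mol)    {k.delta_g_kcal:>10.2f}")
        lines.append("=" * w)
        return "\n".join(lines)
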