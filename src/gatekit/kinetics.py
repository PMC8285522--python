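"""Dwell-time kinetics: distributions, exponential mixtures, rates, ΔG.

From an idealized two-state trace the module extracts per-state dwell
durations (flagging window-boundary dwells as censored), fits exponential
or two-component exponential mixtures by maximum likelihood, and converts
the results into the standard equilibrium quantities of channel gating:

* open probability  P_open = open time / total time (censored dwells
  counted — they still occupy time);
* rate constants    k = 1/τ for each exponential component;
* free energy       ΔG = RT · ln(P_open / (1 − P_open)), positive when
  the open state is favoured.

Dwell fits are maximum likelihood on the raw durations, never least
squares on histograms — the log-spaced histogram (√count ordinate, on
which an exponential component appears as a peak at its time constant) is
kept for visualization only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .idealize import IdealizedTrace

__all__ = [
    "Dwell",
    "DwellSet",
    "LogHistogram",
    "ExpMixFit",
    "KineticsSummary",
    "extract_dwells",
    "log_bin",
    "fit_exp_mixture",
    "choose_n_components",
    "state_probability",
    "correct_dead_time",
    "rate_from_tau",
    "delta_g",
    "summarize",
    "GAS_CONSTANT_KCAL",
]

#: molar gas constant in kcal/(mol·K)
GAS_CONSTANT_KCAL = 1.987204e-3


@dataclass(frozen=True)
class Dwell:
    """One dwell: duration in seconds and a censoring flag.

    Censored dwells (truncated by a window or recording boundary) are
    excluded from distribution fits but included in occupancy time.
    """
    duration: float
    censored: bool = False


@dataclass
class DwellSet:
    """Per-state dwell durations for a two-state trace."""

    open: list = field(default_factory=list)
    closed: list = field(default_factory=list)

    def durations(self, state: str, include_censored: bool = False):
        dwells = getattr(self, state)
        return np.array([d.duration for d in dwells
                         if include_censored or not d.censored])

    def extend(self, other: "DwellSet") -> None:
        self.open.extend(other.open)
        self.closed.extend(other.closed)

    def total_time(self, state: str) -> float:
        return float(sum(d.duration for d in getattr(self, state)))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"state": st, "duration_s": d.duration,
                 "censored": d.censored}
                for st in ("open", "closed") for d in getattr(self, st)]
        return pd.DataFrame(rows)


def extract_dwells(ideal: IdealizedTrace, polarity: str) -> DwellSet:
    """Convert idealized events into per-state dwell durations.

    ``polarity`` maps the low/high state labels onto open/closed:
    height traces are ``open_is_low`` (probe descends into the open
    pore), current traces ``open_is_high``.  The first and last event of
    the trace (window) are flagged censored.
    """
    labels = ideal.state_labels
    if any(lb not in ("low", "high") for lb in labels):
        raise ValueError("trace has more than two states; "
                         "apply qc_min_separation before kinetics")
    if polarity == "open_is_low":
        state_of = {"low": "open", "high": "closed"}
    elif polarity == "open_is_high":
        state_of = {"low": "closed", "high": "open"}
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    out = DwellSet()
    last = ideal.n_events - 1
    for i, ev in enumerate(ideal.events):
        dwell = Dwell(ev.length / ideal.sample_rate,
                      censored=(i == 0 or i == last))
        getattr(out, state_of[ev.state]).append(dwell)
    return out


@dataclass
class LogHistogram:
    """Log-binned dwell histogram with √count ordinate."""

    edges: np.ndarray    # seconds, strictly increasing
    counts: np.ndarray

    @property
    def sqrt_counts(self) -> np.ndarray:
        return np.sqrt(self.counts)

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers (seconds)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_lo_s": self.edges[:-1],
                             "t_hi_s": self.edges[1:],
                             "count": self.counts,
                             "sqrt_count": self.sqrt_counts})

    def plot(self, ax=None, **kwargs):
        """Bar plot of √count vs log t (visualization convention under
        which an exponential component peaks at its time constant)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.centers, self.sqrt_counts,
               width=np.diff(self.edges), align="center", **kwargs)
        ax.set_xscale("log")
        ax.set_xlabel("dwell time (s)")
        ax.set_ylabel(r"$\sqrt{\mathrm{count}}$")
        return ax


def log_bin(durations: Sequence[float],
            bins_per_decade: int = 10) -> LogHistogram:
    """Histogram dwell durations into logarithmically spaced bins.

    Edges sit at ``10^(k / bins_per_decade)`` spanning the data range;
    counts are conserved (every dwell falls in exactly one bin).
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no uncensored dwells to bin")
    if np.any(d <= 0):
        raise ValueError("durations must be > 0")
    lo = math.floor(bins_per_decade * math.log10(d.min()))
    hi = math.floor(bins_per_decade * math.log10(d.max())) + 1
    edges = 10.0 ** (np.arange(lo, hi + 1) / bins_per_decade)
    # guard against float rounding pushing extremes outside the range
    edges[0] = min(edges[0], d.min())
    edges[-1] = max(edges[-1], d.max() * (1 + 1e-12))
    counts, _ = np.histogram(d, bins=edges)
    return LogHistogram(edges, counts)


@dataclass
class ExpMixFit:
    """Maximum-likelihood exponential mixture fit of dwell durations.

    ``taus`` sorted ascending, ``weights`` summing to one; standard
    errors are seeded-bootstrap estimates.
    """

    taus: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n: int
    converged: bool = True
    tau_se: Optional[np.ndarray] = None
    weight_se: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.taus <= 0):
            raise ValueError("taus must be > 0")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")

    @property
    def n_components(self) -> int:
        return self.taus.size

    @property
    def slowest_tau(self) -> float:
        """Time constant of the slowest (gating) component."""
        return float(self.taus[-1])


def _exp_mix_loglik(d, taus, weights):
    dens = np.sum(weights / taus * np.exp(-d[:, None] / taus), axis=1)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def _fit_exp_mixture_core(d, n_components, max_iter=500, tol=1e-10):
    if n_components == 1:
        tau = float(d.mean())  # exact MLE
        return np.array([tau]), np.array([1.0]), \
            _exp_mix_loglik(d, np.array([tau]), np.array([1.0])), True

    # moments-based start: split at the geometric mean
    g = math.exp(float(np.mean(np.log(d))))
    lo, hi = d[d <= g], d[d > g]
    if lo.size == 0 or hi.size == 0:
        lo, hi = d[d <= np.median(d)], d[d > np.median(d)]
    taus = np.array([max(lo.mean(), 1e-12), max(hi.mean(), 1e-12)])
    weights = np.array([lo.size, hi.size], dtype=float) / d.size
    if taus[0] == taus[1]:
        taus = taus * np.array([0.5, 1.5])

    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = weights / taus * np.exp(-d[:, None] / taus)
        tot = np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)
        resp = dens / tot
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        taus = resp.T @ d / nk
        taus = np.maximum(taus, 1e-12)
        weights = nk / d.size
        ll = _exp_mix_loglik(d, taus, weights)
        if abs(ll - ll_old) <= tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll
    order = np.argsort(taus)
    return taus[order], weights[order], ll, converged


def fit_exp_mixture(durations: Sequence[float], n_components: int = 1,
                    n_bootstrap: int = 200, seed: int = 0,
                    max_iter: int = 500) -> ExpMixFit:
    """Fit a mixture of exponentials to dwell durations by EM.

    For one component the MLE is the sample mean (exact).  For two,
    expectation-maximization from a moments-based initializer (split at
    the geometric mean) — deterministic given the data.  Standard errors
    come from a seeded bootstrap (``n_bootstrap`` resamples; 0 disables).
    """
    d = np.asarray(durations, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if d.size < 10 * n_components:
        raise ValueError(
            f"need >= {10 * n_components} uncensored dwells, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("durations must be > 0")

    taus, weights, ll, converged = _fit_exp_mixture_core(
        d, n_components, max_iter=max_iter)

    tau_se = weight_se = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot_taus = np.empty((n_bootstrap, n_components))
        boot_w = np.empty((n_bootstrap, n_components))
        for b in range(n_bootstrap):
            sample = rng.choice(d, size=d.size, replace=True)
            bt, bw, _, _ = _fit_exp_mixture_core(sample, n_components,
                                                 max_iter=max_iter)
            boot_taus[b], boot_w[b] = bt, bw
        tau_se = boot_taus.std(axis=0, ddof=1)
        weight_se = boot_w.std(axis=0, ddof=1)

    return ExpMixFit(taus, weights, ll, d.size, converged,
                     tau_se, weight_se)


def choose_n_components(durations: Sequence[float],
                        lr_threshold: float = 6.0,
                        n_bootstrap: int = 200, seed: int = 0) -> ExpMixFit:
    """Fit 1- and 2-component mixtures and keep the second component only
    if it improves the fit decisively (2·Δln L > ``lr_threshold``)."""
    d = np.asarray(durations, dtype=float)
    fit1 = fit_exp_mixture(d, 1, n_bootstrap=n_bootstrap, seed=seed)
    if d.size < 20:
        return fit1
    fit2 = fit_exp_mixture(d, 2, n_bootstrap=n_bootstrap, seed=seed)
    if 2.0 * (fit2.log_likelihood - fit1.log_likelihood) > lr_threshold:
        return fit2
    return fit1


def state_probability(ideals: Sequence[IdealizedTrace], polarity: str):
    """Pooled open probability across traces, with between-trace SE.

    P_open = total open time / total time, censored dwells included.
    Returns ``(p_open, se, per_trace_p)``; the SE is the standard
    deviation of the per-trace values (nan for a single trace).
    """
    if not ideals:
        raise ValueError("no traces")
    per_trace = []
    tot_open = tot_all = 0.0
    for ideal in ideals:
        ds = extract_dwells(ideal, polarity)
        t_open = ds.total_time("open")
        t_all = t_open + ds.total_time("closed")
        if t_all <= 0:
            raise ValueError("trace with zero total time")
        per_trace.append(t_open / t_all)
        tot_open += t_open
        tot_all += t_all
    p = tot_open / tot_all
    per_trace = np.array(per_trace)
    se = float(per_trace.std(ddof=1)) if per_trace.size > 1 else float("nan")
    return p, se, per_trace


def correct_dead_time(tau_open_obs: float, tau_closed_obs: float,
                      dead_time_s: float, n_iter: int = 4):
    """First-order missed-event correction of observed dwell constants.

    An idealizer with time resolution (dead time) t_d misses events
    shorter than t_d: a missed closure concatenates the flanking open
    dwells, and detected dwells are length-biased by the threshold, so
    the observed mean dwell is approximately
    ``τ̂_o ≈ (τ_o + t_d) · exp(t_d / τ_c)`` (and symmetrically for the
    closed state).  This inverts both relations by fixed-point
    iteration.  Accurate to first order in t_d/τ — the full
    missed-event likelihood treatment is out of scope.
    """
    if dead_time_s <= 0:
        return tau_open_obs, tau_closed_obs
    to, tc = tau_open_obs, tau_closed_obs
    for _ in range(n_iter):
        tc_new = tau_closed_obs * math.exp(-dead_time_s / max(to, 1e-12)) \
            - dead_time_s
        to_new = tau_open_obs * math.exp(-dead_time_s / max(tc_new, 1e-12)) \
            - dead_time_s
        if to_new <= 0 or tc_new <= 0:   # correction exceeds estimate
            return tau_open_obs, tau_closed_obs
        to, tc = to_new, tc_new
    return to, tc


def rate_from_tau(tau: float) -> float:
    """Transition rate constant k = 1/τ (s⁻¹)."""
    if not tau > 0:
        raise ValueError("tau must be > 0")
    return 1.0 / tau


def delta_g(p_open: float, temperature: float = 298.0) -> float:
    """Equilibrium free-energy difference between open and closed states.

    ΔG = RT · ln(P_open / (1 − P_open)), in kcal/mol; positive when the
    open state is favoured.  RT ≈ 0.593 kcal/mol at 298 K.
    """
    if not 0.0 < p_open < 1.0:
        raise ValueError("p_open must be strictly between 0 and 1")
    rt = GAS_CONSTANT_KCAL * temperature
    return rt * math.log(p_open / (1.0 - p_open))


@dataclass
class KineticsSummary:
    """Assembled gating kinetics of a two-state channel."""

    p_open: float
    p_open_se: float
    open_fit: ExpMixFit
    closed_fit: ExpMixFit
    k_open_to_closed: float
    k_closed_to_open: float
    delta_g_kcal: float
    temperature_k: float
    n_traces: int = 1
    dead_time_s: float = 0.0
    tau_open_gating: Optional[float] = None
    tau_closed_gating: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tau_open_gating is None:
            self.tau_open_gating = self.open_fit.slowest_tau
        if self.tau_closed_gating is None:
            self.tau_closed_gating = self.closed_fit.slowest_tau

    @property
    def rt_kcal(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature_k

    @property
    def tau_open(self) -> float:
        """Gating open time constant (dead-time corrected if enabled)."""
        return self.tau_open_gating

    @property
    def tau_closed(self) -> float:
        """Gating closed time constant (dead-time corrected if enabled)."""
        return self.tau_closed_gating

    def to_dict(self) -> dict:
        return {
            "p_open": self.p_open,
            "p_open_se": self.p_open_se,
            "tau_open_s": [float(t) for t in self.open_fit.taus],
            "tau_open_weights": [float(w) for w in self.open_fit.weights],
            "tau_closed_s": [float(t) for t in self.closed_fit.taus],
            "tau_closed_weights": [float(w) for w in self.closed_fit.weights],
            "tau_open_gating_s": self.tau_open_gating,
            "tau_closed_gating_s": self.tau_closed_gating,
            "dead_time_s": self.dead_time_s,
            "k_open_to_closed_per_s": self.k_open_to_closed,
            "k_closed_to_open_per_s": self.k_closed_to_open,
            "delta_g_kcal_per_mol": self.delta_g_kcal,
            "temperature_k": self.temperature_k,
            "rt_kcal_per_mol": self.rt_kcal,
            "n_traces": self.n_traces,
        }


def summarize(p_open: float, p_open_se: float, open_fit: ExpMixFit,
              closed_fit: ExpMixFit, temperature: float = 298.0,
              n_traces: int = 1,
              dead_time_s: float = 0.0) -> KineticsSummary:
    """Assemble the kinetics report from fits and occupancy.

    Rate constants are taken from the slowest component of each state's
    dwell distribution — when a flicker component is present the slower
    closed component represents the actual gating transition, so
    k_closed→open = 1/τ_closed(slow).  A non-zero ``dead_time_s``
    applies :func:`correct_dead_time` to the gating time constants (the
    raw fitted components stay untouched in the fits).
    """
    tau_o, tau_c = correct_dead_time(open_fit.slowest_tau,
                                     closed_fit.slowest_tau, dead_time_s)
    return KineticsSummary(
        p_open=p_open, p_open_se=p_open_se,
        open_fit=open_fit, closed_fit=closed_fit,
        k_open_to_closed=rate_from_tau(tau_o),
        k_closed_to_open=rate_from_tau(tau_c),
        delta_g_kcal=delta_g(p_open, temperature),
        temperature_k=temperature, n_traces=n_traces,
        dead_time_s=dead_time_s,
        tau_open_gating=tau_o, tau_closed_gating=tau_c)
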