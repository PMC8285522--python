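"""Change-point detection, MDL state selection and idealization.

Independent oracles used here:

* exhaustive single-change-point maximum-likelihood scan (for the
  bisection detector on single-step data);
* exhaustive enumeration of all set partitions of the segments, scored
  with the same MDL formula (for the agglomerative state selection).
"""

import itertools

import numpy as np
import pytest

from gatekit.idealize import (ChangePointSet, detect_change_points, idealize,
                              mdl_score, qc_min_separation,
                              read_idealized_csv, select_states,
                              threshold_idealize, write_idealized_csv)
from gatekit.kinetics import extract_dwells
from gatekit.preprocess import lowpass_filter, segment_trace
from gatekit.synthetic import TelegraphConfig, simulate_telegraph
from gatekit.trace import TimeTrace


def _trace(values, fs=10_000.0):
    return TimeTrace(np.asarray(values, dtype=float), fs)


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def single_cp_ml_scan(x):
    """Exhaustive max-likelihood location of one change point: the split
    minimizing total RSS (equivalently maximizing the mean-contrast)."""
    n = x.size
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x ** 2)])
    ks = np.arange(1, n)
    rss = ((cum2[ks] - cum[ks] ** 2 / ks)
           + (cum2[n] - cum2[ks] - (cum[n] - cum[ks]) ** 2 / (n - ks)))
    return int(ks[np.argmin(rss)])


def enumerate_partitions(items):
    """All set partitions (Bell-number many; fine for <= 6 items)."""
    if len(items) == 1:
        yield [[items[0]]]
        return
    head, rest = items[0], items[1:]
    for part in enumerate_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


def best_partition_by_mdl(cps: ChangePointSet, seg_rss_within=0.0):
    """Brute-force best state model over every partition of segments."""
    m = cps.n_segments
    best = None
    lengths = cps.seg_lengths.astype(float)
    for part in enumerate_partitions(list(range(m))):
        levels = {}
        for group in part:
            idx = np.array(group)
            levels_val = np.average(cps.seg_means[idx], weights=lengths[idx])
            for i in group:
                levels[i] = levels_val
        fitted = np.array([levels[i] for i in range(m)])
        rss = seg_rss_within + float(
            np.sum(lengths * (cps.seg_means - fitted) ** 2))
        trans = int(np.count_nonzero(np.diff(fitted) != 0))
        score = mdl_score(rss, cps.n_samples, len(part), trans)
        if best is None or score < best[0]:
            best = (score, len(part), sorted(set(fitted.tolist())))
    return best


# --------------------------------------------------------------------------
# change-point detection
# --------------------------------------------------------------------------

class TestDetectChangePoints:
    def test_noiseless_step_found_exactly(self):
        x = np.concatenate([np.zeros(500), np.full(500, 5.0)])
        cps = detect_change_points(_trace(x), sigma=0.0)
        assert cps.boundaries.tolist() == [500]
        assert cps.seg_means.tolist() == [0.0, 5.0]

    def test_constant_trace_no_boundaries(self):
        cps = detect_change_points(_trace(np.full(1000, 2.0)), sigma=0.0)
        assert cps.boundaries.size == 0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_change_points(_trace([]), sigma=1.0)

    def test_single_step_localization_matches_ml_scan(self):
        """5-sigma step at a random position in 10^4 noisy samples:
        boundary within +/-2 samples of truth in >= 95% of replicates,
        and agreeing with the exhaustive ML scan."""
        hits = agree = 0
        n_rep = 100
        for r in range(n_rep):
            rng = np.random.default_rng(r)
            n = 10_000
            k_true = int(rng.integers(100, n - 100))
            x = np.where(np.arange(n) < k_true, 0.0, 5.0) + rng.normal(
                0.0, 1.0, n)
            cps = detect_change_points(_trace(x), sigma=1.0)
            k_oracle = single_cp_ml_scan(x)
            if cps.boundaries.size:
                k_det = int(cps.boundaries[
                    np.argmin(np.abs(cps.boundaries - k_true))])
                hits += abs(k_det - k_true) <= 2
                agree += abs(k_det - k_oracle) <= 1
        assert hits >= 95
        assert agree >= 95

    def test_deterministic(self, noise_trace):
        a = detect_change_points(noise_trace, sigma=1.0)
        b = detect_change_points(noise_trace, sigma=1.0)
        assert np.array_equal(a.boundaries, b.boundaries)

    def test_pure_noise_low_false_split_rate(self):
        """t_crit=4.5 keeps the false-split rate on 10^4-sample pure-noise
        windows below a few percent."""
        n_split = 0
        for r in range(50):
            rng = np.random.default_rng(10_000 + r)
            tr = _trace(rng.normal(0.0, 1.0, 10_000))
            n_split += detect_change_points(tr, sigma=1.0).boundaries.size > 0
        assert n_split <= 2


# --------------------------------------------------------------------------
# state selection
# --------------------------------------------------------------------------

class TestSelectStates:
    def _cps_from_segments(self, means, lengths, sigma, seed=0):
        rng = np.random.default_rng(seed)
        parts = [rng.normal(m, sigma, ln) for m, ln in zip(means, lengths)]
        x = np.concatenate(parts)
        bounds = np.cumsum(lengths)[:-1]
        seg_means = [p.mean() for p in parts]
        cps = ChangePointSet(np.array(bounds), np.array(seg_means),
                             np.array(lengths), x.size)
        return _trace(x), cps

    def test_two_state_grouping_matches_partition_enumeration(self):
        """Segments at {0, 5, 0.1, 4.9}: best model has 2 states at the
        length-weighted means; oracle = all 15 partitions."""
        trace, cps = self._cps_from_segments(
            [0.0, 5.0, 0.1, 4.9], [400, 400, 400, 400], sigma=1.0)
        models = select_states(trace, cps)
        best = models[0]
        seg_rss = best.rss - float(np.sum(
            cps.seg_lengths * (cps.seg_means
                               - best.levels[best.assignment]) ** 2))
        score, k_oracle, levels_oracle = best_partition_by_mdl(cps, seg_rss)
        assert best.n_states == k_oracle == 2
        assert best.levels == pytest.approx(levels_oracle, abs=1e-12)
        assert best.mdl == pytest.approx(score, abs=1e-8)
        # levels are near the length-weighted two-group means
        assert best.levels == pytest.approx([0.05, 4.95], abs=0.2)

    def test_pure_noise_segments_collapse_to_one_state(self):
        """Spurious segments of a stepless trace: MDL penalty dominates;
        verified against enumeration of all partitions of 5 segments."""
        trace, cps = self._cps_from_segments(
            [0.0] * 5, [300, 250, 350, 300, 280], sigma=1.0, seed=3)
        models = select_states(trace, cps)
        best = models[0]
        seg_rss = best.rss - float(np.sum(
            cps.seg_lengths * (cps.seg_means
                               - best.levels[best.assignment]) ** 2))
        _, k_oracle, _ = best_partition_by_mdl(cps, seg_rss)
        assert best.n_states == k_oracle == 1

    def test_rss_monotone_in_n_states(self, telegraph_snr5):
        trace, _ = telegraph_snr5
        from gatekit.preprocess import estimate_noise_sigma
        cps = detect_change_points(trace, estimate_noise_sigma(trace))
        models = select_states(trace, cps)
        by_k = sorted(models, key=lambda m: m.n_states)
        rss = [m.rss for m in by_k]
        assert all(a >= b - 1e-9 for a, b in zip(rss[:-1], rss[1:]))

    def test_two_level_trace_best_model_two_states(self, telegraph_snr5):
        trace, _ = telegraph_snr5
        _, model = idealize(trace)
        assert model.n_states == 2
        assert model.levels == pytest.approx([0.0, 0.5], abs=0.05)


class TestMdlConsistency:
    @pytest.mark.parametrize("k_true", [1, 2, 3])
    def test_selected_state_count_matches_truth(self, k_true):
        """k well-separated levels (>= 5 sigma): selected n_states == k in
        >= 95% of 50 seeded replicates."""
        correct = 0
        for seed in range(50):
            rng = np.random.default_rng(seed * 7 + k_true)
            seq = rng.integers(0, k_true, 40)
            seq[0] = 0  # ensure every level present for k=1 degenerate case
            x = np.repeat(seq * 0.5, 200).astype(float)
            x += rng.normal(0.0, 0.1, x.size)
            _, model = idealize(_trace(x, fs=50_000.0))
            correct += model.n_states == len(set(seq.tolist()))
        assert correct >= 48


# --------------------------------------------------------------------------
# full idealization
# --------------------------------------------------------------------------

class TestIdealize:
    def test_noiseless_square_wave_recovered_exactly(self):
        cfg = TelegraphConfig(tau_low=2e-3, tau_high=2e-3, noise_sigma=0.0,
                              level_low=0.0, level_high=0.5,
                              sample_rate=50_000.0, duration=0.2, seed=1)
        trace, path = simulate_telegraph(cfg)
        ideal, model = idealize(trace)
        assert model.n_states == 2
        got = [(ev.state, ev.start, ev.length) for ev in ideal.events]
        want = [(ev.state, ev.start, ev.length) for ev in path.events]
        assert got == want
        # perfect reconstruction on noiseless input
        assert np.allclose(ideal.values(), trace.values)

    def test_pure_noise_single_event(self, rng):
        tr = _trace(rng.normal(0.0, 1.0, 20_000))
        ideal, model = idealize(tr)
        assert model.n_states == 1
        assert ideal.n_events == 1
        assert ideal.events[0].length == 20_000

    def test_event_lengths_tile_trace(self, telegraph_snr5):
        trace, _ = telegraph_snr5
        ideal, _ = idealize(trace)
        assert sum(ev.length for ev in ideal.events) == trace.n_samples

    def test_transition_count_close_to_truth(self):
        cfg = TelegraphConfig(tau_low=2.16e-3, tau_high=0.23e-3,
                              level_low=0.0, level_high=0.5,
                              noise_sigma=0.1, sample_rate=100_000.0,
                              duration=10.0, seed=21)
        trace, path = simulate_telegraph(cfg)
        filtered = lowpass_filter(trace, 20_000.0)
        n_det = 0
        for window in segment_trace(filtered, 0.5):
            ideal, _ = idealize(window)
            n_det += ideal.n_events - 1
        assert n_det == pytest.approx(path.n_events - 1, rel=0.10)

    def test_dead_time_merges_short_events(self):
        x = np.concatenate([np.zeros(1000), np.full(3, 5.0),
                            np.zeros(1000)])
        ideal, _ = idealize(_trace(x, fs=10_000.0), dead_time_s=1e-3)
        assert ideal.n_events == 1

    def test_csv_roundtrip(self, telegraph_snr5, tmp_path):
        trace, _ = telegraph_snr5
        ideal, _ = idealize(trace)
        f = tmp_path / "ideal.csv"
        write_idealized_csv(ideal, f)
        back = read_idealized_csv(f, trace.sample_rate)
        assert [(e.state, e.start, e.length) for e in back.events] == \
            [(e.state, e.start, e.length) for e in ideal.events]
        assert np.allclose([e.level for e in back.events],
                           [e.level for e in ideal.events])


class TestThresholdIdealize:
    def test_clean_square_wave_exact(self):
        cfg = TelegraphConfig(tau_low=1e-3, tau_high=1e-3, noise_sigma=0.0,
                              level_low=0.0, level_high=0.5,
                              sample_rate=50_000.0, duration=0.1, seed=2)
        trace, path = simulate_telegraph(cfg)
        ideal = threshold_idealize(trace, 0.0, 0.5)
        got = [(ev.state, ev.start, ev.length) for ev in ideal.events]
        want = [(ev.state, ev.start, ev.length) for ev in path.events]
        assert got == want

    def test_constant_low_single_event(self):
        ideal = threshold_idealize(_trace(np.zeros(500)), 0.0, 1.0)
        assert ideal.n_events == 1
        assert ideal.events[0].state == "low"

    def test_equal_levels_rejected(self):
        with pytest.raises(ValueError, match="level_low"):
            threshold_idealize(_trace(np.zeros(10)), 1.0, 1.0)

    def test_agrees_with_mdl_idealizer_on_occupancy(self):
        cfg = TelegraphConfig(tau_low=2e-3, tau_high=2e-3, level_low=0.0,
                              level_high=0.5, noise_sigma=0.1,
                              sample_rate=50_000.0, duration=2.0, seed=13)
        trace, _ = simulate_telegraph(cfg)
        i_mdl, model = idealize(trace)
        i_thr = threshold_idealize(trace, *model.levels)
        p_mdl = extract_dwells(i_mdl, "open_is_low").total_time("open")
        p_thr = extract_dwells(i_thr, "open_is_low").total_time("open")
        assert p_thr / trace.duration == pytest.approx(
            p_mdl / trace.duration, abs=0.02)


class TestQc:
    def test_half_nm_separation_passes(self, telegraph_snr5):
        trace, _ = telegraph_snr5
        _, model = idealize(trace)
        assert qc_min_separation(model) is True

    def test_sub_threshold_separation_fails(self):
        rng = np.random.default_rng(0)
        x = np.repeat(np.tile([0.0, 0.2], 20), 500)
        x = x + rng.normal(0.0, 0.02, x.size)
        _, model = idealize(_trace(x, fs=50_000.0), min_level_sep=0.05)
        assert model.n_states == 2
        assert qc_min_separation(model) is False

    def test_three_state_model_fails_two_state_gate(self):
        rng = np.random.default_rng(1)
        seq = np.tile([0, 1, 2, 1], 10)
        x = np.repeat(seq * 0.5, 400) + rng.normal(0.0, 0.1, 16_000)
        _, model = idealize(_trace(x, fs=50_000.0))
        assert model.n_states == 3
        assert qc_min_separation(model) is False
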