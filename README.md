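# gatekit

Single-molecule gating kinetics from height-spectroscopy and
single-channel current traces, plus correlation averaging of high-speed
AFM (HS-AFM) topography movies.

## The problem

A pH-gated β-barrel porin such as OmpG opens and closes its pore when a
single extracellular loop (loop-6) folds over the barrel lumen.  Two
complementary single-molecule measurements see this process:

* **single-channel electrophysiology** records the ionic current through
  one channel (~40 pA open, 0 pA closed, 100 kHz sampling, 5 kHz filter);
* **HS-AFM height spectroscopy** parks the AFM probe over one molecule
  and records the height under the tip at ~10 µs resolution — the probe
  descends into the open pore, so *low* height means *open*, a ~5 Å step
  against a ±1 Å noise floor.

Both produce a noisy two-state telegraph signal.  The scientific
quantities are the open probability `P_open`, the per-state dwell-time
constants τ, the rate constants `k = 1/τ`, and the equilibrium
free-energy difference

```
ΔG = RT · ln( P_open / (1 − P_open) )        (RT ≈ 0.593 kcal/mol at 298 K)
```

`gatekit` turns raw traces into these numbers:

1. **preprocess** — zero-phase Gaussian low-pass (−3 dB at the chosen
   corner, 20 kHz by default), segmentation into ~0.5 s windows so slow
   baseline drift cannot masquerade as extra states, robust
   first-difference (Haar/MAD) noise estimation;
2. **idealize** — change-point detection by recursive bisection with a
   Student-t statistic, a short-pulse rescue scan for brief events,
   agglomerative grouping of segment levels, and minimum-description-
   length (MDL) selection of the number of states, with a 2.5 Å
   minimum-separation resolvability rule; a half-amplitude threshold
   idealizer with hysteresis is included as the electrophysiology-style
   alternative;
3. **kinetics** — censoring-aware dwell extraction, log-binned dwell
   histograms (√count ordinate), maximum-likelihood exponential-mixture
   fits (EM, seeded bootstrap errors), first-order missed-event
   correction, `P_open`, rates and ΔG;
4. **particles** — drift correction by normalized cross-correlation,
   iterative particle picking with two-fold (dimer) symmetrization, and
   per-pixel average and standard-deviation maps that highlight mobile
   loops on otherwise rigid barrels.

Because raw recordings of this kind are rarely deposited, the package
ships a first-class synthetic-data generator (`gatekit.synthetic`,
`gatekit.movie`) producing seeded telegraph traces and lattice topography
movies with full ground truth, so every stage is testable end to end.

## Worked example

```python
from gatekit.synthetic import simulate_height_trace
from gatekit.model import TwoStateGatingModel

# 5 s height-spectroscopy-like trace at the neutral-pH dwell constants
# (tau_open 2.16 ms, tau_closed 0.23 ms), 5 A step, 1 A noise, 100 kHz
trace, truth = simulate_height_trace(
    "pH7.6-hs", overrides={"sample_rate": 100_000.0}, seed=1, duration=5.0)

res = TwoStateGatingModel(trace).fit(seed=0)
print(res.summary())
```

```
              Two-State Gating Model Results
==========================================================
No. traces:                          1
Windows (accepted/total):      10 /  10
Uncensored dwells:                3785
Temperature (K):                 298.0
----------------------------------------------------------
P_open                     0.906 +/- 0.008
tau_open[0] (ms)          2.380 +/- 0.050   (weight 1.00)
tau_closed[0] (ms)          0.246 +/- 0.005   (weight 1.00)
k_open->closed (1/s)       476.6
k_closed->open (1/s)      4575.3
Delta G (kcal/mol)          1.34
==========================================================
```

The generator's ground truth for this seed has an open-state occupancy
of 0.907; the fitted `P_open` is 0.906.  The fitted dwell components are
the raw maximum-likelihood values; the rate constants and
`res.tau_open`/`res.tau_closed` (2.10 ms / 0.219 ms here) additionally
carry the first-order missed-event correction for the ~25 µs time
resolution of the idealizer at this bandwidth.  ΔG = 1.34 kcal/mol says
the open state is favoured by a bit over 2 RT.

The same analysis is scriptable from the shell:

```bash
gatekit simulate-trace --preset pH7.6-hs --duration-s 5 --seed 1 --out data/trace
gatekit idealize data/trace.f32 --cutoff-hz 20000 --out out/ideal
gatekit kinetics out/ideal/idealized_*.csv --sample-rate-hz 500000 --out out/kin
gatekit simulate-movie --n-frames 50 --seed 2 --out data/movie
gatekit afm-average data/movie.tif --rounds 2 --threshold 0.7 --out out/afm
```

or driven from a single YAML config with `gatekit run --config cfg.yaml
--out out/` (see `gatekit run --help`).

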