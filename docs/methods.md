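# Methods

## Statistical model

The signal model throughout is a stationary two-state alternating
renewal ("telegraph") process: a molecule dwells in an *open* and a
*closed* conformation for independent, exponentially distributed times
with means τ_open and τ_closed, producing a piecewise-constant level
sequence.  Measured on top of it are

* a level for each state (height: ~0 and ~0.5 nm, open low; current:
  ~40 pA and 0 pA, open high),
* additive iid Gaussian noise,
* slow baseline drift,
* band-limiting by the acquisition chain.

Under this model the stationary open probability is
`P_open = τ_open / (τ_open + τ_closed)`, the transition rates are
`k = 1/τ`, and the equilibrium free-energy difference is
`ΔG = RT·ln(P_open/(1−P_open))`, positive when open is favoured.  ΔG is
reported at T = 298 K (RT = 0.592 kcal/mol with R = 1.987204×10⁻³
kcal mol⁻¹ K⁻¹); the temperature is configurable but 298 K reproduces
published ΔG values from published probabilities to the printed digit,
so it is the default.

A second, short-lived exponential component ("flicker", < 100 µs) may be
mixed into the closed-dwell distribution; it models brief ion-flow
interruptions by side-chain fluctuations rather than full loop gating.
When present, the *slower* closed component is the gating component and
defines k_closed→open.

## Synthetic data

`gatekit.synthetic` draws dwell sequences in continuous time from the
stationary state distribution and rasterizes event boundaries to the
nearest sample, avoiding the geometric-approximation bias of per-sample
state flipping.  Defaults encode the two experimental signal classes:

| preset | τ_open | τ_closed | levels | noise σ | rate |
|---|---|---|---|---|---|
| `pH7.6-hs` | 2.16 ms | 0.23 ms | 0 / 0.5 nm (open low) | 0.1 nm | 500 kHz |
| `pH5.0-hs` | 0.77 ms | 1.52 ms | 0 / 0.5 nm | 0.1 nm | 500 kHz |
| `pH7.6` | 11.5 ms | 0.8 ms (+flicker) | 0 / 40 pA (open high) | 1 pA | 100 kHz, 5 kHz LP |
| `pH5.0` | 1.9 ms | 6.3 ms (+flicker) | 0 / 40 pA | 1 pA | 100 kHz, 5 kHz LP |

The flicker mixture defaults to weight 0.3 with τ = 50 µs — the weight
is not a published quantity; it was fixed once at a value that makes the
closed-dwell histogram visibly bimodal, and every quantitative recovery
check runs with the flicker off.  The 1 pA current noise is likewise a
one-time realism choice (SNR 40 at a 40 pA amplitude).  Drift is a
single sinusoid (amplitude, period), the simplest model that defeats
naive global thresholding and motivates windowed analysis; a random-walk
drift is available as `drift_model="random_walk"`.

`gatekit.movie` renders a 2D crystal of dimeric pore proteins: each
molecule is a ring (the barrel wall, rim height 1.25 nm above the
membrane) plus a Gaussian blob for the gating loop that sits over the
pore when closed and extends outward when open.  Dimer partners are
related by a 180° rotation and placed so every dimer midpoint is an
*exact* two-fold symmetry center of the lattice — the natural particle
for C2 correlation averaging.  The in-cell partner spacing (3.0 nm)
deliberately differs from the spacing across the cell boundary (4.5 nm)
so that midpoints *between* dimers are not spurious pseudo-C2 matches.
Per-frame states come from the exact discrete-time transition kernel of
the two-state chain at the frame interval (200 ms by default).  Optional
first-order tip convolution is a grey-scale dilation with a
spherical-cap structuring element (off by default).  The lattice
constants are not published; the defaults are plausible for a tightly
packed 14-strand β-barrel (~3.4 nm barrel diameter) and are free
parameters.  The default pixel size (0.25 nm) puts dimer centers on the
pixel grid, which makes noiseless recovery tests exact; nothing in the
analysis relies on that alignment (sub-pixel drift and extraction are
exercised separately).

What the generator does *not* emulate: scan-line acquisition and
feedback artifacts, spatially correlated noise, tip changes, lattice
defects and disorder, partial penetration of a blunt tip into the pore
(amplitude attenuation at acidic pH), and non-Markovian gating.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every artifact of real recordings.

## Preprocessing

*Filter.*  Zero-phase Gaussian low-pass; the kernel width is chosen so
the −3 dB point sits at the requested corner (σ_t = √(ln 2)/(2π f_c)).
The analysis is offline, so a symmetric kernel with no phase distortion
of dwell boundaries is preferable to a causal Bessel; only the corner
frequency (20 kHz for height data, 5 kHz for current data) is treated as
given.

*Windows.*  Traces are cut into non-overlapping 0.5 s windows (midpoint
of the 0.4–0.6 s range used in this kind of analysis); a trailing
partial window is kept if at least half length.  Each window is
idealized independently, which bounds the drift any single fit must
absorb.

*Noise.*  σ is estimated from first differences,
`σ = median(|Δx|)/(0.6745·√2)` (Haar/MAD): state transitions occupy too
few difference pairs to move the median, and constants or slow drift
cancel in the differences.

## Idealization

*Change points.*  Recursive bisection: within each segment the split
maximizing `|mean_L − mean_R| / (σ√(1/n_L + 1/n_R))` is accepted while
it exceeds `t_crit` (default 4.5) and both children have ≥ `min_len`
(default 3) samples.  The threshold was calibrated so the false-split
rate on pure-noise windows of 10⁴ samples is < 1%
(`scripts/calibrate_t_crit.py` reproduces the calibration; at 4.5 the
measured rate is 0/200).

*Short-pulse rescue.*  The bisection statistic for an m-sample pulse
inside an n-sample dwell scales as Δ·m/(σ√n), so brief closures deep
inside long dwells are invisible to bisection at any reasonable
threshold, and their loss inflates both dwell constants.  After
bisection, windows of width 1–24 samples are slid over each segment and
tested against the rest of the segment with the same two-sample t
statistic and the same `t_crit`; significant, non-overlapping pulses
(strongest first) contribute boundary pairs.  This restores sensitivity
down to ~2 samples at the cost of a negligible false-pulse rate
(≲ 10⁻⁵ per sample at t_crit = 4.5).

*Correlated noise.*  Low-pass filtered data are oversampled relative to
their noise bandwidth: neighbouring samples are correlated, which (a)
shrinks the first-difference noise estimate by √(1−ρ₁), (b) inflates
mean-comparison t statistics, and (c) makes the iid-Gaussian MDL data
term overcount evidence.  For the known Gaussian kernel these effects
are analytic: ρ₁ = exp(−1/(4σ_s²)) and the variance of an n-sample mean
is σ²g/n with g = 2σ_s√π (σ_s = kernel width in samples).  The
idealizer therefore rescales the step-test σ by √(g/(1−ρ₁)) and scores
the MDL with N_eff = N/g effective samples.  For unfiltered data g = 1
and everything reduces to the plain iid formulas.  The filter corner is
read from the trace metadata (set by `lowpass_filter`) or passed
explicitly.

*State selection.*  Segment levels are merged agglomeratively; at each
step the pair of groups *adjacent in level* whose pooled, length-
weighted mean minimizes the residual-sum-of-squares increase
(ΔRSS = L_aL_b/(L_a+L_b)·(μ_a−μ_b)²) is fused, yielding one candidate
model per state count.  Restricting fusion to level-adjacent pairs makes
the sweep O(m²) and encodes that states are intervals in level space.
Each candidate is scored with the two-part code length

```
MDL = N_eff/2 · ln(RSS/N) + η/2 · ln(N_eff),   η = n_states + n_transitions
```

Counting transitions in η is what lets the criterion reject models that
chop dwells into many spurious levels.  On small segment sets the
selected model provably matches exhaustive enumeration of all set
partitions under the same score (tested against a brute-force oracle).

*Resolvability rule.*  Pure MDL happily splits one physical state into
noise-duplicate sub-levels a few hundredths of a nm apart, and
bandwidth-attenuated short dwells genuinely populate intermediate mean
levels.  Neither is a conformational state.  Selection therefore takes
the best-MDL candidate whose adjacent levels are all separated by at
least `min_level_sep` — the same 2.5 Å floor (half the expected 5 Å
step; 20 pA for 40 pA current traces) that the post-hoc QC gate
enforces, applied at selection time.  Windows whose selected model is
not two states with ≥ 2.5 Å separation are excluded from kinetics
(`qc_min_separation`).

*Alternative idealizer.*  `threshold_idealize` implements the classic
half-amplitude crossing with a hysteresis band of ±25% of the level
separation; on generated data its occupancy estimates agree with the
MDL idealizer to < 0.02.

## Dwell-time kinetics

Event lengths become dwell durations; the first and last event of every
window are flagged *censored* and excluded from distribution fits while
still counting toward occupancy time.  (For stationary exponential
dwells the boundary pieces are distributionally different from full
dwells; at the default window/τ ratios of 10²–10³ their treatment is
numerically immaterial, but the flagging keeps the estimators honest
when windows shrink.)

Fits are maximum likelihood on raw durations — histograms are
visualization only.  One component: τ̂ = sample mean (exact MLE).  Two
components: EM from a moments-based start (split at the geometric
mean), deterministic given the data; standard errors from a seeded
bootstrap (200 resamples).  The second component is kept only when the
likelihood-ratio statistic 2Δln L exceeds 6, mirroring the observation
that open dwells are single-exponential while closed dwells can be
bimodal (gating + flicker).

*Missed-event correction.*  An idealizer with time resolution t_d
misses events shorter than t_d; each missed closure concatenates the
flanking open dwells, so observed means obey approximately
`τ̂_o ≈ (τ_o + t_d)·exp(t_d/τ_c)` and symmetrically.  The model
pipeline inverts both relations by fixed-point iteration with
`t_d = max(2.5 samples, 0.34/f_c)` (the shortest detectable pulse and
the Gaussian rise time).  This is the standard first-order correction,
not a full missed-event likelihood; it is skipped automatically whenever
the correction would exceed the estimate, and the raw fitted components
are always reported alongside.  At the 100 kHz/20 kHz study conditions
it moves τ estimates from ≈ +9% to within ≈ ±5% of truth.

Log-binned histograms use edges at 10^(k/b) (b = 10 bins/decade) with a
√count ordinate, under which an exponential component appears as a peak
at its time constant.

## Movie analysis

Frames are drift-corrected by matching the central crop of frame 0
inside each frame (Pearson normalized cross-correlation, 3-point
parabolic sub-pixel refinement; exact-match peaks skip refinement so
integer drifts are recovered exactly).  Particle picking runs
`match_template` against the current reference, keeps local maxima
above the correlation threshold (default 0.7; the original acceptance
value is unpublished, so it is a flag) with non-maximum suppression
within one reference radius, and extracts odd-sized windows with cubic-
spline sub-pixel alignment.  Iterative averaging implements
seed → C2-symmetrize → pick → average → C2-symmetrize → re-pick →
final average + std map; the std map is the per-pixel population
standard deviation over the aligned stack and lights up mobile domains
(the toggling loop) while the rigid rim stays dark.  Symmetrization is
`(map + rot180(map))/2` about the center pixel; even window sizes are
rejected to keep the symmetry axis on a pixel.  No rotational search
beyond 180° is performed because crystal packing fixes the orientation.

## Problem sizes

The test suite and the acceptance script use 20 s traces at 100 kHz
(~1.7×10⁴ gating events) for full-pipeline recovery, 50 replicates of
10⁴-sample windows for selection rates, 100 replicates for change-point
localization, 10⁴ draws for mixture recovery, and 5–60-frame synthetic
movies (12–16 dimers per frame) for the imaging chain — sizes at which
the sampling error of every checked quantity is several times smaller
than its tolerance.

## Known limitations

* The idealizer assumes two (or few) well-separated levels; gradual
  amplitude changes within a window are handled only by windowing.
* The correlated-noise corrections are exact for the package's own
  Gaussian filter; externally filtered data need `bandwidth_hz` set to
  the true corner, and non-Gaussian anti-aliasing chains are
  approximated.
* The missed-event correction is first order; for τ within ~4× the
  time resolution a full missed-event likelihood (out of scope) would
  be required.
* Hidden-Markov idealization, multi-state kinetic-scheme fitting,
  voltage dependence, tip deconvolution and lattice unbending are out
  of scope.
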