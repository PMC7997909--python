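# Methods

`neuroloop` implements the analysis chain of a brain-controlled deep-brain
-stimulation (DBS) neuroprosthesis for locomotion: the intention to walk is
decoded from motor-cortex (MI) multiunit activity with an unsupervised,
rapidly calibrated algorithm, and used to gate stimulation of the midbrain
locomotor region (MLR) through a hysteresis controller. The package also
carries the surrounding population analyses (ensemble onset latencies,
speed encoding, gait-kinematics PCA, histology quantification) and a
synthetic-session generator that embodies the statistical structure these
analyses assume.

## Multiunit signal path (`mua`)

Multiunit activity (MUA) is deliberately unsorted: every threshold-crossing
event on a channel counts. Offline detection bandpasses raw voltage at
700–3000 Hz (4th-order Butterworth, zero-phase), z-scores per channel, and
takes negative-going crossings of −3 SD; the event time is the first
sub-threshold sample. The raw trace carries a filter transient of a few
milliseconds at each end; traces shorter than the transient are rejected.
No debounce rule is implied by a plain threshold detector, so a 1 ms
refractory period is applied (configurable) — at −3 SD on near-Gaussian
noise the false-event rate is the normal tail, ~1.35 per thousand samples,
and the refractory period keeps one biphasic waveform from registering
twice.

Counts are accumulated in half-open 10 ms bins, `[t, t+10)`, 0-based. The
decoding path smooths counts with a causal Gaussian FIR whose variance is
fixed by design: σ² = 8/ln 5 bins², so the kernel decays by exactly 80%
four bins (40 ms) from its peak. The kernel is truncated at 12 bins
(< 0.1% of the mass) and normalized to unit sum so that rates keep their
scale; the warm-up edge is renormalized by the kernel mass actually
applied, making a constant input an exact fixed point. Offline speed
analyses instead use a centered 200 ms moving average with shrinking
windows at the edges. The causal/centered split mirrors the online
(decoder) versus offline (analysis) uses of the two smoothers.

The *cumulative firing* of a unit set is the sum of its smoothed rates,
z-scored against a baseline window; it is invariant to channel order and
to uniform positive rescaling of the counts, and raises on zero baseline
variance rather than silently dividing by zero.

## Unsupervised walk/idle decoder (`state_decoder`)

Calibration needs one overground trial with an approximately even balance
of idle and walking time, and no labels:

1. **SOM.** A one-dimensional self-organizing map with four output nodes
   is trained on the per-bin smoothed population vectors. Training is
   online over 200 epochs in seeded random order; the learning rate
   shrinks linearly 0.5 → 0.01 and the Gaussian chain neighborhood
   1.0 → 0.05. Code vectors initialize from quantile bands of the samples
   ordered by population count, so the fit is deterministic given the
   seed. Empty nodes are legal (logged); with fewer distinct activity
   levels than nodes the extra nodes simply go unused.
2. **Cluster values.** Nodes are ranked by the mean population spike
   count of their assigned bins and valued 1, 2/3, 1/3, 0 in descending
   rank. Empty nodes rank last; ties break toward the lower node index.
   The map is always a bijection onto {0, 1/3, 2/3, 1}.
3. **Target vector.** The per-bin node values form Y (one value per bin),
   smoothed with a centered 500 ms boxcar. Centered (not causal) because
   Y is constructed offline; a boxcar because the smoother is a plain
   moving window, distinct from the Gaussian FIR of the signal path.
4. **Weights.** w is the minimum-norm least-squares solution of wN = Y,
   i.e. w = Y N⁺ with N the channels × bins matrix of smoothed counts —
   the Moore–Penrose pseudoinverse, computed via `lstsq`. A test holds it
   to the explicit normal-equations solution (N Nᵀ)⁻¹ N Y at 1e-8.
5. **Normalization.** The control variable y = w n is affinely rescaled
   so the 1st/99th percentiles of the calibration trace map to 0/1; the
   same affine map is applied online. This makes the hysteresis
   thresholds absolute: uniformly rescaling all counts leaves the
   normalized trace unchanged (asserted by test).

Accuracy is scored per bin: the decoded trace passes through the
hysteresis controller, the ON state counts as "walk", and walk/idle
accuracies are the fractions of true-walk/true-idle bins predicted
correctly. Evaluation is calibrate-on-one-trial, score-on-held-out-trials,
with no guard band around transitions; per-bin scoring is the stricter
choice since every transition bin a slow decoder misses counts against it.

## Hysteresis controller (`stim_controller`)

A two-threshold switch: OFF→ON when y exceeds θ_on (operating range
0.7–0.8, default the midpoint 0.75), ON→OFF when y falls below θ_off
(0.2–0.3, default 0.25), state held inside the dead band. Stimulation
parameters when emulating the experiments: 40 Hz trains of 200 µs
biphasic pulses at 50–250 µA. The controller runs at bin resolution
(10 ms), not the hard-real-time loop of the physical system; the
detection-to-stimulation latency contract is therefore ≤ 1 bin, with
identical switching logic.

The closed-loop simulation reproduces the initiation-latency
phenomenology of three modes. Latencies are log-normal with configured
mean ± SD: 23.9 ± 13.2 s without stimulation, 29.1 ± 12.2 s with
brain-controlled stimulation (both self-paced), 5.5 ± 2.6 s when the
experimenter forces stimulation at trial start. Log-normal is the
standard positive, right-skewed choice when only mean ± SD are known. In
brain-controlled mode each trial actually simulates the MI population and
gates stimulation through the controller, so ON events follow the decoded
intent and can never precede the MI ramp onset (audited per trial).

## Ensemble onset latency and speed encoding (`ensemble_analysis`)

*Locomotor-related* has no universal definition; the package uses: walk
mean rate above idle mean rate AND a one-sided rank-sum test at α = 0.05
on the per-bin counts. On long sessions this includes a doubled-rate
channel essentially always and a null channel at ~α.

Onset latency: the cumulative firing of the selected units is
re-referenced, for each gait initiation (the bout's first foot-off), to
the mean and SD of a baseline window −2500…−500 ms before the foot-off,
and the first upward crossing of +2 SD inside a −1000…+1000 ms search
window is reported, relative to the foot-off. Two estimator details
matter:

* the crossing time is linearly interpolated between the bracketing bin
  centers, so on a noiseless ramp of slope s the estimate is exactly
  onset + 2/s;
* a crossing must stay above threshold for 100 ms (configurable) to
  qualify. A z-threshold of 2 is crossed by baseline noise in ~2.3% of
  bins, so an unguarded "first crossing" in a 100-bin search window is
  dominated by noise; the sustained-crossing rule rejects those
  excursions while leaving a ramp's crossing time untouched.

Windows with no qualifying crossing are reported missing, not imputed.
The baseline is per-initiation (not per-session), which tolerates slow
nonstationarities; both windows are configurable.

Speed encoding: per channel, rate and speed are both smoothed with the
200 ms moving average and a simple linear regression is fit over walk
bins only; the per-channel R² and the fraction of channels with R² > 0.2
are reported. Simple regression (not rank correlation) matches the
"relative correlation (R²)" convention. Population comparisons (MI vs
MLR latency, paired by session/animal) use the one-tailed Wilcoxon
signed-rank test.

## Gait kinematics (`gait_kinematics`)

Cycle detection takes a toe-height trajectory sampled at ≥ 100 Hz:
foot-off is the upward crossing of a height threshold (default the
trajectory mid-range), foot-strike the subsequent downward return, with a
minimum swing of 50 ms. The per-cycle feature set has 15 named
parameters — step height (max toe elevation in swing above the stance
baseline), hip excursion (peak-to-peak hip joint angle), whole-limb and
per-segment oscillation amplitudes, joint ranges, stride length,
swing/stance/cycle durations, drag fraction, peak toe speed, hip height —
computed from the standard six-marker hindlimb set (iliac crest,
trochanter, condyle, malleolus, fifth metatarsal, toe). The set is
deliberately extensible; reproducing any particular published PC axis
built from a different (larger) feature list is not claimed.

Condition analysis z-scores the feature columns (constant columns are
dropped with a warning), fits a PCA, and compares conditions by centroid
Euclidean distance in the first k PCs (default k = 2, the plane usually
displayed; full-space distances, which equal standardized-feature-space
distances exactly, are available). PCA is fit on cycle-level rows.

Paired contrasts are one-tailed, with a Kolmogorov–Smirnov screen on the
standardized differences choosing between the paired t test and the
signed-rank test; zero-variance differences fall back to the exact sign
probability 1/2ⁿ. The power simulation draws per-animal means of
`cycles_per_animal` cycles per condition, adds an effect of
`effect_frac × spontaneous_range`, and applies the one-tailed exact
signed-rank test across animals (vectorized exact enumeration of the
null, cross-checked against `scipy.stats.wilcoxon`). Variance parameters
are user-specified — the design constants (effect +50% of the spontaneous
range, 20 cycles per animal, α = 0.05) are defaults, but no variance is
prescribed, so absolute power figures are exploratory. Per-animal
intercepts cancel in the paired difference, which the implementation
exploits; the `between_sd` argument is kept for interface completeness.
The simulation is exactly α-calibrated at zero effect (up to the
discreteness of the signed-rank null: the achievable size at n = 6 is
3/64 ≈ 0.047) and monotone in effect size and in n.

## Histology (`histo_quant`)

Spared tissue: sections are binarized at a fixed intensity threshold held
constant across sections (the threshold is an explicit parameter, stored
for provenance; ROI size likewise). The spared percentage is 100 × the
positive-pixel count at the epicenter over the mean positive count of the
adjacent intact sections. The measure is invariant to translation and to
monotone intensity rescalings that preserve the threshold's level set.

c-Fos profiles: spot-to-tip distances d = √(ΔX² + ΔY²) are counted in
half-open 250 µm bins (k·250, (k+1)·250]; the bin closest to the
electrode is excluded (tissue damage). Counts (not area-normalized
densities) are scaled per animal by the profile maximum, the scale floor
being the natural zero of a count — so a profile of counts (1, 2, 1)
normalizes to (0.5, 1, 0.5) and doubling all counts changes nothing. The
pooled ordinary-least-squares slope of normalized density on distance is
reported along with the long-format (animal, distance, density) table; a
mixed-effects fit with a per-animal intercept is the natural next step
and is left to general-purpose statistics packages.

## Synthetic sessions (`synthetic_data`)

The generator is the package's test bed and defines its study conditions.
What it emulates:

* **Behavior** — alternating idle/walk bouts, both uniform 5–10 s, giving
  the even idle/walk balance of an overground trial; per-bout trapezoidal
  speed (1 s acceleration/deceleration, 200 mm/s plateau); foot-offs
  every 700 ms with 250 ms swings. A trial is one idle+walk pair.
* **Neural counts** — 32 MI and 16 MLR channels of per-bin Poisson
  counts at a 20 Hz multiunit baseline. Locomotor channels (half of each
  array by default) ramp linearly over 50 ms to baseline + 8 baseline-SD
  and hold until the bout's last foot-strike. MI ramps start 147 ms
  before the first foot-off (intact) or 182 ms (SCI); MLR ramps 104 ms
  (intact) or 55 ms (SCI) after it. 53% of MLR channels additionally
  carry a rate term affine in speed, gated by the population's own
  activation profile so speed coupling does not fire ahead of the MLR
  onset. Per-bout, per-channel gain jitter has CV 0.1 (intact) or 0.3
  (SCI). The steep 8-SD/50 ms ramp makes the 2-SD crossing estimator's
  target well-posed: the crossing sits within ~1 bin of the ramp onset.
* **SCI** is emulated minimally — the shifted lead/lag, larger gain
  jitter, fewer speed-coupled channels — as phenomenology, not mechanism.
* **Kinematics** — per-cycle features from condition-dependent Gaussians
  with multiplicative condition effects on the means; graded DBS
  intensity uses the 0/33/66/100% grid. A sinusoidal marker-trajectory
  mode exists solely to exercise cycle detection.
* **Cohorts** — per-animal random effects on baseline rate and feature
  means (CVs 0.2 and 0.1 by default).

Firing-rate magnitudes, bout statistics, cadence and speed are package
choices at physiologically plausible rodent values; channel counts, the
lead/lag structure, the idle/walk balance, the speed-coupled fraction and
the condition grid are the study conditions. What the generator does
*not* emulate — electrode drift, correlated (non-Poisson) count noise,
bursting, behavioral mislabeling, imperfect gait-event detection — bounds
what passing tests show: they validate the algorithms against their own
assumptions, not decoder performance on real tissue.

Raw-trace synthesis (24 kHz Gaussian noise with −8 SD biphasic waveforms
inserted per count at jittered within-bin times) is a short-segment
(≤ 10 s) path for exercising the spike detector; full-session raw
synthesis is out of scope.

## Problem sizes and numerical choices

Default sessions are 240 s (24 000 bins), giving ~16 trials per session.
The reference protocols use 10 sessions for decoder accuracy (calibrate
on one trial, score 5 held-out trials each) and 20 sessions per condition
for the latency benchmarks; `scripts/acceptance.py` runs all of them in
about a minute on one core. Degenerate inputs raise rather than guess:
zero baseline variance, empty unit sets, single-state sessions,
zero-variance speed, all-blank intact sections. Ties in cluster ranking
break toward the lower node index; empty SOM clusters rank last. All
randomness flows through `numpy.random.default_rng` seeds; every
generator and the SOM are bit-reproducible given their seed.

## Known limitations

* The SOM hyperparameters (epochs, learning-rate and neighborhood
  schedules) are recorded defaults, not tuned optima; only the 4-node
  chain topology is structural.
* Per-bin accuracy, the per-initiation baseline, and the rank-sum
  locomotor criterion are reasonable but not unique conventions; all are
  parameterized.
* The closed-loop simulation samples initiation latencies from configured
  distributions — it reproduces latency phenomenology, it does not model
  the sensorimotor loop that produces it.
* Absolute power-simulation numbers depend on user-supplied variances and
  should be read comparatively (across n or effect), not as predictions.
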