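# Methods

This note documents the models, estimators and numerical choices behind
`lateralis`, and what the synthetic-data generator does and does not
emulate.

## Scientific setting

The package analyzes lateralized (turning) motor behavior in rodents and
the neural signals recorded alongside it. "Ipsilateral" and
"contralateral" are always defined relative to a declared hemisphere —
the side carrying the recording fiber/electrode or the optogenetic
implant. Five data streams are covered:

1. **Pose tracking** — per-frame x, y of four landmarks (nose, left ear,
   right ear, tail base), the output format of markerless trackers.
2. **Turn events** — time-stamped turn onsets with a direction label.
3. **Spike trains** — sorted single-unit spike times.
4. **Fiber photometry** — a raw fluorescence trace from a population
   calcium indicator.
5. **EMG and histology tables** — stimulus-locked muscle recordings and
   region/side fluorescence-density or labeled-cell-count tables.

## Kinematics

**Heading** is the orientation of the tail-base→nose vector
(`atan2`, degrees, range (−180, 180]). **Angular velocity** is the
wrapped frame-to-frame heading difference times the frame rate, signed so
that positive is ipsiversive: in a y-up coordinate frame an increasing
heading (counterclockwise) is a leftward turn, hence ipsiversive when the
declared hemisphere is `left`; the mapping flips for `right`. Image
coordinates (y down) mirror the visual rotation sense but require no code
change. All kinematic quantities are invariant under translation and
positive scaling of the coordinates, and mirror-imaging the coordinates
flips the velocity sign — these are tested properties.

**Noise propagation and smoothing.** Landmark jitter of standard
deviation σ on a body axis of length L contributes heading noise of about
√2·σ/L radians per frame, which frame-to-frame differencing amplifies by
the frame rate. At σ = 0.2 cm, L = 4.5 cm and 30 fps that is ~150 deg/s
per frame — far above any biological turning rate. `angular_velocity`
therefore accepts a moving-average heading smoother (`smooth_s`); with a
0.2 s window the per-frame noise drops ~6-fold and the *mean* over a bout
telescopes to an endpoint difference with sub-deg/s error. The default is
`smooth_s = 0` so that noiseless closed-form identities hold to machine
precision; 0.2 s is the recommended setting for tracked video at
~30 fps.

**Mean angular velocity** averages |velocity| over *active rotation*
frames: |v| ≥ an immobility threshold (default 20 deg/s) sustained for at
least 0.5 s. Both constants are configurable; no published value exists
for them, so they were fixed once at levels that separate locomotor
turning (≥45 deg/s in our synthetic regimes) from posture jitter. When
the series was smoothed, the moving average ramps the velocity across
each bout edge; those `smooth_frames` edge samples are trimmed from every
active run before averaging (bout eligibility is judged on the untrimmed
run). With no active frames the result is NaN with a warning — never a
silent zero.

**Rotation counting** integrates signed angular velocity and increments
the ipsi (contra) count each time the running angle reaches +360°
(−360°), carrying the overshoot out of the accumulator. The carry (rather
than a hard reset to zero) is what makes the count equal
floor(|ω|·T/360) for constant-rate rotation regardless of frame
quantization. The counter is verified against a brute-force step-by-step
integrator on random velocity profiles.

**Head–trunk angle** is the deflection between the head segment
(ear-midpoint→nose) and the trunk segment (tail-base→ear-midpoint),
computed as `atan2(|cross|, dot)` for conditioning near 0° and 180°. We
report deflection-from-straight (0° = aligned, range [0, 180]); an
"intersecting angle" convention with 180° = straight is the same number
reflected, and the deflection form was chosen for interpretability.

**Turn detection** marks contiguous same-sign stretches with
|v| ≥ 20 deg/s accumulating ≥ 60° (configurable) as events, onset at the
first suprathreshold frame. This replaces manual annotation and is
validated by recovering generator schedules within ±2 frames.

## Photometry

ΔF/F = (F − F₀)/F₀. Because no single F₀ definition is standard, two are
provided and the choice is recorded in output metadata: a **per-trial
pre-event mean** (F over [−2, −0.5] s before each turn onset; exactly
invariant under affine sensor rescaling F → aF) and a **session running
percentile** (10th percentile over a 60 s centered window; tracks slow
drift/bleaching). Per-trial is the default for event-aligned analyses.
F₀ ≤ 0 anywhere aborts with a diagnostic rather than producing silent
infinities.

Trials are aligned on turn onsets over a [−2, +5] s window (configurable)
by integer sample shifts — no interpolation, since a single uniformly
sampled trace is being sliced. Events whose window leaves the recording
are dropped and logged; rows + dropped = events always. Direction
comparison summarizes each trial by its mean ΔF/F in a [0, 2] s response
window and applies an unpaired t test by default (the trial-summary
distributions are near-Gaussian averages); a rank-sum alternative is
exposed. Degenerate zero-variance inputs are refused.

## Spike trains

The PSTH is pooled spike counts per bin divided by (n_trials ×
bin width); 50 ms bins by default (unreported upstream; 50 ms resolves a
0.5 s response window into 10 bins). The histogram satisfies the mass
identity Σrate·binwidth·n_trials = total in-window spikes by
construction, and this is property-tested.

Direction tuning uses mean firing rates in the 0–0.5 s post-onset window
(turn-locked spiking concentrates in the first 500 ms) and the
**modulation index** MI = (R_ipsi − R_contra)/(R_ipsi + R_contra),
bounded in [−1, 1], antisymmetric, undefined (NaN) only when both rates
are zero.

**Classification** is by permutation test: direction labels are shuffled
across trials (default 1000 permutations) and the add-one-smoothed
two-sided p-value is the fraction of permutations with |MI| at least the
observed. Units with p < α (default 0.05) take the sign of MI; others are
"none", as are units with fewer than 5 trials per direction or no spikes
at all (flagged). The permutation rule was chosen because a per-unit
significance criterion is needed but none is published for this analysis;
a Welch t test on per-trial rates is provided as an alternative
(`classify_unit_ttest`) and agrees in strong-tuning regimes. Calibration
is verified by simulation: untuned units are mislabeled at a rate bounded
by α + 1/n_perm.

Population percentages are rounded half-away-from-zero, which reproduces
51/33/16 from 66/43/21 of 130.

## EMG

Peak response amplitude is max |value − baseline median| over the
(onset, onset + 5 s] window, with the baseline median taken from the 1 s
before the onset. Rectifying around the baseline median (rather than
taking a raw maximum) makes the measure invariant to DC offset; the
choice is recorded in metadata. Truncated windows skip the onset with a
log entry. Latency is the first post-onset time where the rectified
signal exceeds k·SD of the baseline (k = 3) sustained for ≥ 10 ms — the
sustain requirement rejects single-sample noise, the 10 ms floor sets the
resolution. Aggregation expects at least five valid repetitions per
animal and warns below that. Side/frequency comparisons use Wilcoxon
tests (signed-rank when paired).

## Densitometry

The fluorescence density index divides every measurement of a region by
the mean *contralateral* density of that region, so the mean
contralateral index is exactly 1 by algebraic identity (property-tested)
and ipsilateral indices read as fold-change. Normalization pools animals
within a region by default; this matches the unpaired exact rank-sum
comparison used for side differences at small n (a paired signed-rank
test at n = 4 cannot reach p < 0.05, whereas the exact rank-sum can —
and published small-n side comparisons of this kind report exactly the
rank-sum's minimum attainable p). Per-animal normalization and a paired
signed-rank comparison remain available for designs with several samples
per animal.

Output proportions are per-animal labeled-cell fractions (summing to 1
per animal before any filtering; zero-total animals are excluded with a
log entry), averaged as mean ± SEM across animals, keeping regions with a
nonzero count in at least half of the animals.

## Synthetic data generator

The generator exists to give every estimator an input with known ground
truth; it is deliberately minimal.

* **Pose**: a rigid four-landmark body (nose 1.5 cm ahead of the ear
  midpoint, ears ±0.5 cm off-axis, tail base 3 cm behind) rotating about
  a fixed ear midpoint according to a non-overlapping bout schedule, with
  i.i.d. Gaussian landmark noise. The rigid geometry makes the head–trunk
  angle exactly 0, a useful null. Inter-bout intervals are immobile, with
  an optional slow-drift fraction below the immobility threshold. There
  is no translation, gait, or posture dynamics — passing kinematic tests
  shows estimator correctness, not robustness to real locomotion.
* **Spikes**: inhomogeneous Poisson with piecewise-constant rate —
  baseline multiplied by a direction gain inside each event's response
  window. Defaults (5 Hz baseline, gain 4, 0.5 s window) are stated
  assumptions chosen to make tuned units clearly separable at 30
  trials/side, not published values; no real firing statistics
  (refractoriness, bursting, drift) are modeled.
* **Photometry**: F = F₀·(1 + Σ gain·kernel(t − onset)) + Gaussian noise,
  with a difference-of-exponentials kernel normalized to a configurable
  peak (defaults rise 0.2 s, decay 1.5 s, amplitude 0.05 ΔF/F — the slow
  dynamics of common genetically encoded calcium indicators). No
  photobleaching, motion artifact, or hemodynamic contamination.
* **EMG**: Gaussian baseline noise plus, per stimulation onset, a burst
  of rectified smoothed noise under a fast-rise/slow-decay envelope,
  normalized so the burst peak equals amplitude × side gain × a
  frequency-gain map — the normalization is what makes amplitude closure
  exact. Default baseline noise is 1% of the default burst amplitude
  (0.02 mV vs 2 mV): the closure regime is "baseline ≪ burst", and at a
  few percent relative noise the extreme-value bias of a 5 s windowed
  maximum alone would dominate the amplitude error.
* **Density**: log-normal draws per side around stated means with a given
  coefficient of variation (cv = 0 degenerates to exact means).

All generators are driven by `numpy` Generators seeded explicitly;
identical seeds give bit-identical outputs (tested).

## Pipeline

`run_pipeline(config, seed, out_dir)` executes stages in dependency
order, writing CSV outputs plus a `summary.json` that echoes the full
config, the seed and package versions. Floats are serialized at 9
significant digits, making reruns with the same (config, seed)
byte-identical. Stage failures raise with partial outputs retained and a
nonzero CLI exit. Two-group comparisons route to Wilcoxon tests, k-group
comparisons to one-way ANOVA + Tukey HSD or Kruskal–Wallis + Dunn
(hand-implemented rank z with tie correction and Holm adjustment, as no
dependency provides Dunn's test); adjusted pairwise p-values are
reported with no extra false-discovery layer.

## Problem sizes and determinism of the validation suite

The validation experiments are sized for a laptop-class run: the
population-split experiment uses 130 units × 60 trials × 1000
permutations (seconds); classifier calibration uses 500 untuned units;
closure checks use 50 seeds each. Simulation-based assertions use
binomial confidence bounds rather than point equalities, and all
randomness is seeded, so the suite is deterministic.

## Known limitations

* Pose analysis is 2-D, single-animal, and assumes a (near-)rigid body
  axis; it does not handle occlusion beyond masking low-likelihood
  frames.
* The per-trial photometry baseline assumes ≥ 2 s of quiet signal before
  each event; closely spaced events contaminate each other's baselines.
* The permutation classifier assumes exchangeable trials; slow rate
  drift across a session violates this and inflates false positives.
* The density index is only as meaningful as the underlying ROI
  quantification, which is out of scope here (densities enter as
  tabulated measurements).
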